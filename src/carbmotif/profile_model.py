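"""Per-subgroup profile models: position-specific log-odds scoring in bits.

Every MDD subgroup trains one ungapped profile — per-position emission
probabilities with a pseudocount — and scores a fragment as the summed
log2 odds of its residues against a background distribution. Because all
fragments are fixed-length, gap-free windows, this is the degenerate form a
profile HMM takes on such data (match states only). A decision threshold is
calibrated on bit scores to balance sensitivity and specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, DUMMY
from .seq_windows import Fragment

UNIFORM_BACKGROUND = np.full(20, 1 / 20)


@dataclass
class ProfileModel:
    """Ungapped position-specific emission model with a bit-score threshold.

    ``emissions[p, a]`` is the probability of residue *a* at window position
    *p* (row index 0 = offset −n); ``background`` the null distribution; a
    fragment scores sum_p log2(emissions[p, aa_p] / background[aa_p]) over
    its non-dummy positions.
    """

    emissions: np.ndarray  # (2n+1, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    subgroup_id: str = ""
    bit_threshold: float = 0.0
    #: raw per-position residue counts (set by train_profile); needed only
    #: for exact leave-one-out scoring of training members
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 20:
            raise ValueError("emissions must have shape (window, 20)")
        if self.background.shape != (20,):
            raise ValueError("background must have 20 entries")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def window_length(self) -> int:
        return self.emissions.shape[0]

    def to_dict(self) -> dict:
        return {
            "subgroup_id": self.subgroup_id,
            "pseudocount": self.pseudocount,
            "bit_threshold": self.bit_threshold,
            "background": self.background.tolist(),
            "emissions": self.emissions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileModel":
        return cls(
            emissions=np.array(d["emissions"]),
            background=np.array(d["background"]),
            pseudocount=d["pseudocount"],
            subgroup_id=d["subgroup_id"],
            bit_threshold=d["bit_threshold"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ProfileModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_profile(
    members: Sequence[Fragment],
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    subgroup_id: str = "",
) -> ProfileModel:
    """Estimate per-position emissions from a subgroup's fragments.

    emissions[p][a] = (count(a at p) + pseudocount) /
    (non-dummy count at p + 20 * pseudocount). Dummy symbols never enter the
    counts; positions observed only as padding fall back to the pseudocount
    prior (uniform when pseudocount > 0).
    """
    if not members:
        raise ValueError("cannot train a profile on an empty subgroup")
    L = len(members[0].window)
    if any(len(m.window) != L for m in members):
        raise ValueError("subgroup fragments have unequal lengths")
    counts = np.zeros((L, 20))
    for frag in members:
        for p, aa in enumerate(frag.window):
            if aa != DUMMY:
                counts[p, AA_INDEX[aa]] += 1
    denom = counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    if pseudocount == 0 and (denom == 0).any():
        raise ValueError(
            "pseudocount 0 with an all-dummy position leaves emissions "
            "undefined"
        )
    emissions = (counts + pseudocount) / denom
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    return ProfileModel(
        emissions=emissions,
        background=bg,
        pseudocount=pseudocount,
        subgroup_id=subgroup_id,
        counts=counts,
    )


def bit_score(model: ProfileModel, fragment: Fragment) -> float:
    """Summed per-position log2 odds; dummy positions contribute 0 bits."""
    if len(fragment.window) != model.window_length:
        raise ValueError(
            f"fragment length {len(fragment.window)} != model window "
            f"{model.window_length}"
        )
    total = 0.0
    for p, aa in enumerate(fragment.window):
        if aa == DUMMY:
            continue
        a = AA_INDEX[aa]
        total += np.log2(model.emissions[p, a] / model.background[a])
    return float(total)


def bit_scores(model: ProfileModel, fragments: Sequence[Fragment]) -> np.ndarray:
    return np.array([bit_score(model, f) for f in fragments])


def bit_score_loo(model: ProfileModel, fragment: Fragment) -> float:
    """Bit score of a training member against the profile retrained without
    it (exact leave-one-out: the member's own counts are decremented).

    Scoring a member with the profile it helped train inflates the score —
    its residues are guaranteed to be in the emission counts — which biases
    any downstream learner fitted on training scores. For count-based
    profiles the unbiased score is available in closed form.
    """
    if model.counts is None:
        raise ValueError("model carries no raw counts; retrain with "
                         "train_profile to enable leave-one-out scoring")
    if len(fragment.window) != model.window_length:
        raise ValueError("fragment length does not match model window")
    pc = model.pseudocount
    total = 0.0
    for p, aa in enumerate(fragment.window):
        if aa == DUMMY:
            continue
        a = AA_INDEX[aa]
        c = model.counts[p, a] - 1
        if c < 0:
            raise ValueError(
                f"fragment {fragment.source} was not a training member "
                f"(no count for {aa!r} at row {p})"
            )
        denom = model.counts[p].sum() - 1 + 20 * pc
        emission = (c + pc) / denom
        if emission == 0:
            return -np.inf
        total += np.log2(emission / model.background[a])
    return float(total)


def sensitivity_specificity(
    threshold: float, pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, float]:
    """Sn/Sp under the strict decision rule ``score > threshold``."""
    sn = float((pos_scores > threshold).mean())
    sp = float((neg_scores <= threshold).mean())
    return sn, sp


def balanced_threshold(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Score cutoff balancing sensitivity and specificity.

    Candidates are the midpoints of consecutive distinct observed scores
    (plus sentinels half a unit beyond the extremes so the all-positive and
    all-negative rules are reachable). The winner minimises |Sn − Sp|, ties
    broken by larger accuracy, then by the smaller threshold.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("threshold calibration needs both classes")
    distinct = np.unique(np.concatenate([pos, neg]))
    if distinct.size == 1:
        candidates = np.array([distinct[0]])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2
        candidates = np.concatenate(
            [[distinct[0] - 0.5], mids, [distinct[-1] + 0.5]]
        )
    P, N = pos.size, neg.size
    best = None
    for t in candidates:
        sn, sp = sensitivity_specificity(t, pos, neg)
        acc = (sn * P + sp * N) / (P + N)
        key = (abs(sn - sp), -acc, t)
        if best is None or key < best[0]:
            best = (key, float(t))
    return best[1]


def calibrate_threshold(
    model: ProfileModel,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
) -> float:
    """Calibrate the model's bit-score cutoff on labelled fragments (see
    :func:`balanced_threshold`); the chosen value is stored on the model
    and returned."""
    t = balanced_threshold(
        bit_scores(model, positives), bit_scores(model, negatives)
    )
    model.bit_threshold = t
    return t
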
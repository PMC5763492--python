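"""Numeric feature encodings of sequence fragments.

Six schemes are provided, matching the usual repertoire for PTM-site
classifiers:

* ``AAC``  — amino-acid composition, 20 values summing to 1;
* ``AAPC`` — adjacent (overlapping) amino-acid-pair composition, 400 values;
* ``AA``   — orthogonal binary (one-hot) coding, (2n+1)x20 bits;
* ``PWM``  — per-position relative-frequency lookup against a positional
  weight matrix built from the positive training fragments, 2n+1 values;
* ``PSSM`` — a position-specific scoring matrix aggregated to 20x20 by
  summing rows with the same residue, divided by the window length and
  squashed through the logistic 1/(1+e^-x), 400 values;
* ``B62``  — per-position BLOSUM62 substitution-score rows, (2n+1)x20.

Dummy '-' positions contribute nothing to compositional counts, encode as
all-zero blocks in positional schemes, and 0 in the PWM lookup. All vectors
follow the alphabetical residue ordering of :mod:`carbmotif.alphabet`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AA_INDEX, AMINO_ACIDS, DUMMY
from .seq_windows import Fragment

SCHEMES = ("AAC", "AAPC", "AA", "PWM", "PSSM", "B62")

_BLOSUM62_RAW = substitution_matrices.load("BLOSUM62")
#: 20x20 BLOSUM62 scores in alphabetical residue order.
BLOSUM62 = np.array(
    [[_BLOSUM62_RAW[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS],
    dtype=float,
)


def scheme_dimension(scheme: str, n: int = 10) -> int:
    """Feature-vector length of *scheme* for window half-width *n*."""
    L = 2 * n + 1
    dims = {"AAC": 20, "AAPC": 400, "AA": L * 20, "PWM": L, "PSSM": 400,
            "B62": L * 20}
    try:
        return dims[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


# ---------------------------------------------------------------------------
# compositional encoders
# ---------------------------------------------------------------------------

def encode_aac(fragment: Fragment) -> np.ndarray:
    """Amino-acid composition over the whole window (dummies excluded)."""
    counts = np.zeros(20)
    for aa in fragment.window:
        if aa != DUMMY:
            counts[AA_INDEX[aa]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"fragment {fragment.source}: all-dummy window")
    return counts / total


def encode_aapc(fragment: Fragment) -> np.ndarray:
    """Overlapping adjacent-pair composition; 400 values summing to 1."""
    counts = np.zeros((20, 20))
    npairs = 0
    w = fragment.window
    for a, b in zip(w, w[1:]):
        if a == DUMMY or b == DUMMY:
            continue
        counts[AA_INDEX[a], AA_INDEX[b]] += 1
        npairs += 1
    if npairs == 0:
        raise ValueError(
            f"fragment {fragment.source}: no adjacent non-dummy pair"
        )
    return counts.ravel() / npairs


def encode_binary(fragment: Fragment) -> np.ndarray:
    """Orthogonal binary coding: one 20-bit one-hot block per position."""
    out = np.zeros((len(fragment.window), 20))
    for p, aa in enumerate(fragment.window):
        if aa != DUMMY:
            out[p, AA_INDEX[aa]] = 1.0
    return out.ravel()


def encode_blosum62(fragment: Fragment) -> np.ndarray:
    """Per-position BLOSUM62 score rows; dummy positions are zero blocks."""
    out = np.zeros((len(fragment.window), 20))
    for p, aa in enumerate(fragment.window):
        if aa != DUMMY:
            out[p] = BLOSUM62[AA_INDEX[aa]]
    return out.ravel()


# ---------------------------------------------------------------------------
# positional weight matrix
# ---------------------------------------------------------------------------

@dataclass
class PwmMatrix:
    """Relative frequencies of the 20 residues at each window position,
    estimated from positive training fragments."""

    freq: np.ndarray  # (2n+1, 20)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 20:
            raise ValueError("PWM must have shape (window, 20)")


def build_pwm(positives: Sequence[Fragment]) -> PwmMatrix:
    if not positives:
        raise ValueError("cannot build a PWM from an empty training set")
    L = len(positives[0].window)
    counts = np.zeros((L, 20))
    for frag in positives:
        if len(frag.window) != L:
            raise ValueError("mixed fragment lengths in PWM training set")
        for p, aa in enumerate(frag.window):
            if aa != DUMMY:
                counts[p, AA_INDEX[aa]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, totals, out=np.zeros_like(counts),
                     where=totals > 0)
    return PwmMatrix(freq=freq)


def encode_pwm(fragment: Fragment, pwm: PwmMatrix) -> np.ndarray:
    """One value per position: the PWM frequency of the observed residue
    (0 for dummies and residues unseen at that position)."""
    L = pwm.freq.shape[0]
    if len(fragment.window) != L:
        raise ValueError(
            f"fragment length {len(fragment.window)} != PWM window {L}"
        )
    out = np.zeros(L)
    for p, aa in enumerate(fragment.window):
        if aa != DUMMY:
            out[p] = pwm.freq[p, AA_INDEX[aa]]
    return out


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

@dataclass
class PssmProfile:
    """Per-row position-specific scores for one fragment.

    ``scores`` has one row per window position (2n+1 rows, 20 columns in
    alphabetical order); ``row_residues`` gives the fragment residue of each
    row ('-' for padding rows, which carry zero scores).
    """

    scores: np.ndarray  # (2n+1, 20)
    row_residues: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM must have shape (window, 20)")
        if len(self.row_residues) != self.scores.shape[0]:
            raise ValueError("row_residues length != number of rows")


# PSI-BLAST ASCII column order (differs from alphabetical).
_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSIBLAST_TO_ALPHA = [AA_INDEX[a] for a in _PSIBLAST_ORDER]


def load_pssm(path: str | Path, n: int = 10) -> PssmProfile:
    """Parse the PSI-BLAST ASCII PSSM dialect (header line naming the 20
    residue columns, then one row per position: index, residue, 20 integer
    log-odds). Raises with the offending line number on malformed input."""
    expected_rows = 2 * n + 1
    rows: list[np.ndarray] = []
    residues: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if not header_seen:
                if tokens[: len(_PSIBLAST_ORDER)] == list(_PSIBLAST_ORDER) or (
                    len(tokens) >= 20
                    and all(t in AMINO_ACIDS for t in tokens[:20])
                ):
                    header_seen = True
                continue
            if not tokens[0].isdigit():
                continue  # trailing K/lambda statistics block
            if len(tokens) < 22:
                raise ValueError(
                    f"{path}:{lineno}: PSSM row has {len(tokens)} fields, "
                    f"expected >= 22"
                )
            aa = tokens[1]
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{path}:{lineno}: bad residue {aa!r}")
            try:
                vals = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric PSSM score"
                ) from exc
            row = np.empty(20)
            row[_PSIBLAST_TO_ALPHA] = vals
            rows.append(row)
            residues.append(aa)
    if not header_seen:
        raise ValueError(f"{path}: no PSI-BLAST PSSM header found")
    if len(rows) != expected_rows:
        raise ValueError(
            f"{path}: expected {expected_rows} PSSM rows, found {len(rows)}"
        )
    return PssmProfile(scores=np.array(rows), row_residues="".join(residues))


def compute_pssm(
    fragment: Fragment,
    reference: Sequence[Fragment],
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
) -> PssmProfile:
    """Internal PSSM: per-position log-odds of the reference fragments
    against a background distribution, so the pipeline runs without
    PSI-BLAST. Padding rows of *fragment* get zero scores."""
    if not reference:
        raise ValueError("empty reference set for PSSM computation")
    L = len(fragment.window)
    if any(len(r.window) != L for r in reference):
        raise ValueError("reference fragment length mismatch")
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background)
    counts = np.zeros((L, 20))
    for ref in reference:
        for p, aa in enumerate(ref.window):
            if aa != DUMMY:
                counts[p, AA_INDEX[aa]] += 1
    probs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )
    logodds = np.log2(probs / bg)
    scores = np.zeros((L, 20))
    for p, aa in enumerate(fragment.window):
        if aa != DUMMY:
            scores[p] = logodds[p]
    return PssmProfile(scores=scores, row_residues=fragment.window)


def encode_pssm(profile: PssmProfile) -> np.ndarray:
    """Aggregate a (2n+1)x20 profile to 20x20 by summing rows sharing the
    same residue, divide by the window length, squash through the logistic
    function, and flatten row-major; 400 values in (0, 1)."""
    L = profile.scores.shape[0]
    agg = np.zeros((20, 20))
    for r, aa in enumerate(profile.row_residues):
        if aa != DUMMY:
            agg[AA_INDEX[aa]] += profile.scores[r]
    agg /= L
    return (1.0 / (1.0 + np.exp(-agg))).ravel()


# ---------------------------------------------------------------------------
# unified interface
# ---------------------------------------------------------------------------

class FeatureEncoder:
    """Fit-on-positives / transform-fragments interface over all schemes.

    ``PWM`` and ``PSSM`` need the positive training fragments (PWM for the
    frequency matrix; PSSM for the internal reference profile); the other
    schemes are stateless.
    """

    def __init__(self, scheme: str, n: int = 10, pseudocount: float = 1.0):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
        self.scheme = scheme
        self.n = n
        self.pseudocount = pseudocount
        self._pwm: Optional[PwmMatrix] = None
        self._reference: Optional[list[Fragment]] = None

    def fit(self, positives: Sequence[Fragment]) -> "FeatureEncoder":
        if self.scheme == "PWM":
            self._pwm = build_pwm(positives)
        elif self.scheme == "PSSM":
            self._reference = list(positives)
        return self

    def transform_one(self, fragment: Fragment) -> np.ndarray:
        if self.scheme == "AAC":
            return encode_aac(fragment)
        if self.scheme == "AAPC":
            return encode_aapc(fragment)
        if self.scheme == "AA":
            return encode_binary(fragment)
        if self.scheme == "B62":
            return encode_blosum62(fragment)
        if self.scheme == "PWM":
            if self._pwm is None:
                raise RuntimeError("PWM encoder not fitted")
            return encode_pwm(fragment, self._pwm)
        if self._reference is None:
            raise RuntimeError("PSSM encoder not fitted")
        profile = compute_pssm(fragment, self._reference, self.pseudocount)
        return encode_pssm(profile)

    def transform(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return np.array([self.transform_one(f) for f in fragments])
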
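"""Second-layer combinatorial model: an RBF-SVM over subgroup bit scores.

Each MDD leaf trains a profile model; a fragment becomes the ordered vector
of its bit scores against every leaf profile. The vectors are scaled to
[-1, 1] per dimension and classified by an RBF SVM whose cost/gamma are
grid-searched by internal stratified 5-fold CV accuracy (the classical
LIBSVM grid: c = 2^-5..2^15, gamma = 2^-15..2^3, consecutive points a
factor 2^2 apart). Single-feature SVM baselines share the same protocol.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .alphabet import TARGET_RESIDUES
from .encoders import FeatureEncoder
from .mdd import MddTree
from .profile_model import (
    ProfileModel,
    balanced_threshold,
    bit_score,
    bit_score_loo,
    bit_scores,
    calibrate_threshold,
    train_profile,
)
from .seq_windows import Fragment, ProteinRecord, extract_fragment

C_GRID_DEFAULT = tuple(2.0 ** e for e in range(-5, 16, 2))
GAMMA_GRID_DEFAULT = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass
class Scaler:
    """Per-dimension affine map of training min/max onto [-1, +1];
    constant dimensions map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = np.zeros_like(X, dtype=float)
        nz = span > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.lo[nz]) / span[nz] - 1.0
        return out


def grid_search_rbf(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] = C_GRID_DEFAULT,
    gamma_grid: Sequence[float] = GAMMA_GRID_DEFAULT,
    cv: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Return (best_c, best_gamma, best_cv_accuracy).

    Ties favour the smaller cost, then the smaller gamma, so the search is
    deterministic for a fixed fold assignment.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes")
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best: Optional[tuple] = None
    for c in c_grid:
        for g in gamma_grid:
            correct = 0
            for tr, va in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X[tr], y[tr])
                correct += int((clf.predict(X[va]) == y[va]).sum())
            acc = correct / len(y)
            key = (-acc, c, g)
            if best is None or key < best[0]:
                best = (key, c, g, acc)
    return best[1], best[2], best[3]


@dataclass
class ComboModel:
    """Per-residue-type bundle: ordered subgroup profiles + RBF-SVM stacker."""

    residue: str
    profiles: list[ProfileModel]
    svm: SVC
    scaler: Scaler
    best_c: float
    best_gamma: float
    cv_accuracy: float
    #: cutoff on the SVM decision value, calibrated on the (leave-one-out
    #: corrected) training scores to balance sensitivity and specificity
    decision_threshold: float = 0.0
    training_sources: frozenset = field(default_factory=frozenset)

    def bitscore_matrix(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return np.column_stack([bit_scores(p, fragments) for p in self.profiles])

    def decision_function(self, fragments: Sequence[Fragment]) -> np.ndarray:
        X = self.scaler.transform(self.bitscore_matrix(fragments))
        return self.svm.decision_function(X)

    def predict(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return self.decision_function(fragments) > self.decision_threshold

    def matched_subgroup(self, fragment: Fragment) -> str:
        scores = [bit_score(p, fragment) for p in self.profiles]
        return self.profiles[int(np.argmax(scores))].subgroup_id

    # -- persistence --------------------------------------------------------
    def save(self, bundle_dir: str | Path) -> None:
        d = Path(bundle_dir)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "residue": self.residue,
            "best_c": self.best_c,
            "best_gamma": self.best_gamma,
            "cv_accuracy": self.cv_accuracy,
            "decision_threshold": self.decision_threshold,
            "scaler_lo": self.scaler.lo.tolist(),
            "scaler_hi": self.scaler.hi.tolist(),
            "training_sources": sorted(map(list, self.training_sources)),
            "profiles": [p.to_dict() for p in self.profiles],
        }
        (d / "model.json").write_text(json.dumps(meta))
        with open(d / "svm.pkl", "wb") as fh:
            pickle.dump(self.svm, fh)

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "ComboModel":
        d = Path(bundle_dir)
        meta = json.loads((d / "model.json").read_text())
        with open(d / "svm.pkl", "rb") as fh:
            svm = pickle.load(fh)
        return cls(
            residue=meta["residue"],
            profiles=[ProfileModel.from_dict(p) for p in meta["profiles"]],
            svm=svm,
            scaler=Scaler(
                lo=np.array(meta["scaler_lo"]), hi=np.array(meta["scaler_hi"])
            ),
            best_c=meta["best_c"],
            best_gamma=meta["best_gamma"],
            cv_accuracy=meta["cv_accuracy"],
            decision_threshold=meta["decision_threshold"],
            training_sources=frozenset(
                (p, int(q)) for p, q in meta["training_sources"]
            ),
        )


def bitscore_vector(
    profiles: Sequence[ProfileModel], fragment: Fragment
) -> np.ndarray:
    """Ordered vector of bit scores of *fragment* against each profile."""
    return np.array([bit_score(p, fragment) for p in profiles])


def train_combo(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    mdd_tree: MddTree,
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    c_grid: Sequence[float] = C_GRID_DEFAULT,
    gamma_grid: Sequence[float] = GAMMA_GRID_DEFAULT,
    cv: int = 5,
    seed: int = 0,
) -> ComboModel:
    """Train the full two-layer model.

    One profile per MDD leaf (threshold calibrated on the leaf's members vs
    the negatives, kept for standalone reporting), then the RBF-SVM stacker
    on the scaled bit-score vectors of all training fragments.
    """
    if not positives or not negatives:
        raise ValueError("training needs both positive and negative fragments")
    leaves = mdd_tree.leaves
    profiles: list[ProfileModel] = []
    for leaf in leaves:
        prof = train_profile(
            leaf.members, pseudocount=pseudocount, background=background,
            subgroup_id=leaf.leaf_id or "",
        )
        calibrate_threshold(prof, leaf.members, negatives)
        profiles.append(prof)

    frags = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    X_raw = np.column_stack([bit_scores(p, frags) for p in profiles])
    # stacking-bias control: a positive's score on the profile of its own
    # leaf is replaced by the exact leave-one-out score, so the SVM sees the
    # score distribution that held-out fragments will produce
    leaf_of = {
        f.source: i for i, leaf in enumerate(leaves) for f in leaf.members
    }
    for row, f in enumerate(positives):
        li = leaf_of.get(f.source)
        if li is not None:
            X_raw[row, li] = bit_score_loo(profiles[li], f)
    scaler = Scaler.fit(X_raw)
    X = scaler.transform(X_raw)
    best_c, best_gamma, cv_acc = grid_search_rbf(
        X, y, c_grid, gamma_grid, cv=cv, seed=seed
    )
    svm = SVC(C=best_c, gamma=best_gamma, kernel="rbf")
    svm.fit(X, y)
    # operating point: balance Sn/Sp on the unbiased training decision
    # values, the same calibration rule the profile layer uses
    decisions = svm.decision_function(X)
    threshold = balanced_threshold(decisions[y == 1], decisions[y == 0])
    return ComboModel(
        residue=positives[0].center_residue,
        profiles=profiles,
        svm=svm,
        scaler=scaler,
        best_c=best_c,
        best_gamma=best_gamma,
        cv_accuracy=cv_acc,
        decision_threshold=threshold,
        training_sources=frozenset(f.source for f in frags),
    )


class SingleFeatureSvm:
    """RBF-SVM baseline over one fragment encoding (AAC/AAPC/AA/PWM/PSSM/B62),
    trained with the same grid-search protocol as the combo model."""

    def __init__(
        self,
        scheme: str,
        n: int = 10,
        c_grid: Sequence[float] = C_GRID_DEFAULT,
        gamma_grid: Sequence[float] = GAMMA_GRID_DEFAULT,
        cv: int = 5,
        seed: int = 0,
    ):
        self.encoder = FeatureEncoder(scheme, n=n)
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.seed = seed
        self.svm: Optional[SVC] = None
        self.scaler: Optional[Scaler] = None
        self.best_c = self.best_gamma = self.cv_accuracy = None
        self.training_sources: frozenset = frozenset()

    def fit(
        self, positives: Sequence[Fragment], negatives: Sequence[Fragment]
    ) -> "SingleFeatureSvm":
        self.encoder.fit(positives)
        frags = list(positives) + list(negatives)
        y = np.array([1] * len(positives) + [0] * len(negatives))
        X_raw = self.encoder.transform(frags)
        self.scaler = Scaler.fit(X_raw)
        X = self.scaler.transform(X_raw)
        self.best_c, self.best_gamma, self.cv_accuracy = grid_search_rbf(
            X, y, self.c_grid, self.gamma_grid, cv=self.cv, seed=self.seed
        )
        self.svm = SVC(C=self.best_c, gamma=self.best_gamma, kernel="rbf")
        self.svm.fit(X, y)
        self.training_sources = frozenset(f.source for f in frags)
        return self

    def _features(self, fragments: Sequence[Fragment]) -> np.ndarray:
        if self.svm is None:
            raise RuntimeError("SingleFeatureSvm not fitted")
        return self.scaler.transform(self.encoder.transform(fragments))

    def decision_function(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return self.svm.decision_function(self._features(fragments))

    def predict(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return self.svm.predict(self._features(fragments)).astype(bool)


class ProfileThresholdModel:
    """A single profile model used as a classifier via its calibrated
    bit-score threshold (the one-layer baseline)."""

    def __init__(self, profile: ProfileModel):
        self.profile = profile
        self.training_sources: frozenset = frozenset()

    def decision_function(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return bit_scores(self.profile, fragments)

    def predict(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return self.decision_function(fragments) > self.profile.bit_threshold


@dataclass(frozen=True)
class PredictionResult:
    protein_id: str
    position: int
    residue: str
    score: float
    label: str
    matched_subgroup: str


def predict_protein(
    models: dict[str, ComboModel], protein: ProteinRecord, n: int = 10
) -> list[PredictionResult]:
    """Score every K/R/T/P residue of *protein* with the matching residue
    model; residue types without a model are skipped."""
    results: list[PredictionResult] = []
    for pos, aa in enumerate(protein.sequence, start=1):
        if aa not in TARGET_RESIDUES or aa not in models:
            continue
        model = models[aa]
        frag = extract_fragment(protein, pos, n, label="negative")
        score = float(model.decision_function([frag])[0])
        positive = bool(model.predict([frag])[0])
        results.append(
            PredictionResult(
                protein_id=protein.id,
                position=pos,
                residue=aa,
                score=score,
                label="positive" if positive else "negative",
                matched_subgroup=model.matched_subgroup(frag),
            )
        )
    return results
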
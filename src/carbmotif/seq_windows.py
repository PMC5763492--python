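"""Sequence-window datasets for carbonylation-site modelling.

Candidate sites are the K/R/T/P residues of a protein. Each site is
represented by a fixed (2n+1)-mer fragment centred on the site, with '-'
padding where the window runs past a terminus. Annotated carbonylated sites
form the positive class; every other residue of the same type is a candidate
negative. Near-duplicate fragments are removed by greedy identity clustering
(a deterministic stand-in for CD-HIT at 50% identity), and negatives are
down-sampled to a fixed ratio against the positives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, DUMMY, TARGET_RESIDUES, validate_sequence

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence over the 20 standard amino acids."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context=f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled candidate site: 1-based position of a K/R/T/P residue."""

    protein_id: str
    position: int  # 1-based
    residue: str
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.residue not in TARGET_RESIDUES:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: residue "
                f"{self.residue!r} is not one of {TARGET_RESIDUES}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"invalid label {self.label!r}")
        if self.position < 1:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: positions are 1-based"
            )


@dataclass(frozen=True)
class Fragment:
    """A (2n+1)-mer window centred on a candidate site.

    ``window`` uses the 20 amino-acid letters plus '-' for positions beyond
    the protein termini; the dummy symbol may only appear as a contiguous
    prefix and/or suffix. ``source`` is (protein_id, 1-based position).
    """

    window: str
    center_residue: str
    label: str
    source: tuple[str, int]

    def __post_init__(self) -> None:
        L = len(self.window)
        if L % 2 != 1:
            raise ValueError(f"fragment window length {L} is not odd")
        n = L // 2
        if self.window[n] != self.center_residue:
            raise ValueError(
                f"fragment {self.source}: centre symbol {self.window[n]!r} "
                f"!= declared centre residue {self.center_residue!r}"
            )
        core = self.window.strip(DUMMY)
        if DUMMY in core:
            raise ValueError(
                f"fragment {self.source}: dummy '-' must be contiguous "
                f"terminus padding"
            )
        bad = set(core) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"fragment {self.source}: invalid symbols {sorted(bad)!r}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def half_width(self) -> int:
        return len(self.window) // 2


@dataclass
class Dataset:
    """Positive and negative fragments for one residue type."""

    residue: str
    positives: list[Fragment]
    negatives: list[Fragment]
    n: int = 10

    def __post_init__(self) -> None:
        for frag in self.positives + self.negatives:
            if frag.center_residue != self.residue:
                raise ValueError(
                    f"fragment {frag.source} centred on "
                    f"{frag.center_residue!r}, dataset residue {self.residue!r}"
                )
        pos_keys = {f.source for f in self.positives}
        neg_keys = {f.source for f in self.negatives}
        overlap = pos_keys & neg_keys
        if overlap:
            raise ValueError(
                f"positive/negative overlap at sites {sorted(overlap)[:5]}"
            )


# ---------------------------------------------------------------------------
# window extraction and candidate enumeration
# ---------------------------------------------------------------------------

def extract_fragment(
    protein: ProteinRecord, position: int, n: int, label: str = POSITIVE
) -> Fragment:
    """Extract the (2n+1)-mer window centred at 1-based *position*.

    Out-of-range flanks are padded with '-'. Raises if the position itself
    is outside the protein.
    """
    L = len(protein.sequence)
    if not 1 <= position <= L:
        raise ValueError(
            f"position {position} out of range 1..{L} for protein "
            f"{protein.id!r}"
        )
    i = position - 1
    lo, hi = i - n, i + n + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - L)
    window = (
        DUMMY * left_pad
        + protein.sequence[max(lo, 0) : min(hi, L)]
        + DUMMY * right_pad
    )
    return Fragment(
        window=window,
        center_residue=protein.sequence[i],
        label=label,
        source=(protein.id, position),
    )


def build_candidate_sites(
    proteins: Sequence[ProteinRecord],
    positives: Sequence[SiteAnnotation],
    residue: str,
    n: int = 10,
) -> Dataset:
    """Build a Dataset for one residue type.

    Negatives enumerate every occurrence of *residue* in *proteins* that is
    not annotated as positive. Every positive annotation is checked against
    its protein sequence.
    """
    by_id = {p.id: p for p in proteins}
    pos_sites: set[tuple[str, int]] = set()
    pos_frags: list[Fragment] = []
    for ann in positives:
        if ann.residue != residue:
            continue
        prot = by_id.get(ann.protein_id)
        if prot is None:
            raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
        if ann.position > len(prot.sequence):
            raise ValueError(
                f"annotation {ann.protein_id}:{ann.position} beyond sequence "
                f"length {len(prot.sequence)}"
            )
        observed = prot.sequence[ann.position - 1]
        if observed != ann.residue:
            raise ValueError(
                f"annotation {ann.protein_id}:{ann.position} declares residue "
                f"{ann.residue!r} but sequence has {observed!r}"
            )
        key = (ann.protein_id, ann.position)
        if key in pos_sites:
            continue
        pos_sites.add(key)
        pos_frags.append(extract_fragment(prot, ann.position, n, POSITIVE))

    neg_frags: list[Fragment] = []
    for prot in proteins:
        for i, aa in enumerate(prot.sequence, start=1):
            if aa == residue and (prot.id, i) not in pos_sites:
                neg_frags.append(extract_fragment(prot, i, n, NEGATIVE))
    return Dataset(residue=residue, positives=pos_frags, negatives=neg_frags, n=n)


# ---------------------------------------------------------------------------
# redundancy reduction and negative sampling
# ---------------------------------------------------------------------------

def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Ungapped positional identity over positions where both are non-dummy."""
    if len(a.window) != len(b.window):
        raise ValueError(
            f"fragment length mismatch: {len(a.window)} vs {len(b.window)}"
        )
    compared = matches = 0
    for x, y in zip(a.window, b.window):
        if x == DUMMY or y == DUMMY:
            continue
        compared += 1
        if x == y:
            matches += 1
    return matches / compared if compared else 0.0


def reduce_redundancy(
    fragments: Sequence[Fragment],
    identity_threshold: float = 0.5,
    reference: Optional[Sequence[Fragment]] = None,
) -> list[Fragment]:
    """Greedy redundancy filter in input order.

    A fragment is dropped when its identity with any already-retained
    fragment — or with any fragment of *reference* — reaches
    *identity_threshold*. Passing the positives as *reference* when filtering
    negatives removes negatives that look like positives.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    lengths = {len(f.window) for f in fragments} | {
        len(f.window) for f in (reference or [])
    }
    if len(lengths) > 1:
        raise ValueError(f"mixed fragment lengths {sorted(lengths)}")
    retained: list[Fragment] = []
    anchors: list[Fragment] = list(reference or [])
    for frag in fragments:
        if any(
            fragment_identity(frag, kept) >= identity_threshold
            for kept in anchors
        ):
            continue
        retained.append(frag)
        anchors.append(frag)
    return retained


def sample_negatives(dataset: Dataset, ratio: int = 2, seed: int = 0) -> Dataset:
    """Down-sample negatives to ratio × |positives|, uniformly without
    replacement; reproducible under *seed*."""
    need = ratio * len(dataset.positives)
    pool = dataset.negatives
    if len(pool) < need:
        raise ValueError(
            f"insufficient negatives: need {need}, pool has {len(pool)} "
            f"(short by {need - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=need, replace=False)
    sampled = [pool[i] for i in sorted(idx)]
    return Dataset(
        residue=dataset.residue,
        positives=list(dataset.positives),
        negatives=sampled,
        n=dataset.n,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA file."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def read_sites_tsv(path: str | Path) -> list[SiteAnnotation]:
    """Read site annotations: protein_id, position, residue, label columns;
    '#'-prefixed lines are comments. A header row is optional."""
    sites: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            if parts[0] == "protein_id":  # header
                continue
            pid, pos, res, label = parts[0], parts[1], parts[2], parts[3]
            try:
                position = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos!r}") from exc
            sites.append(
                SiteAnnotation(protein_id=pid, position=position, residue=res, label=label)
            )
    return sites


def write_sites_tsv(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "position", "residue", "label"])
        for s in sites:
            w.writerow([s.protein_id, s.position, s.residue, s.label])


def write_fragments_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["window", "label", "protein_id", "position"])
        for f in fragments:
            w.writerow([f.window, f.label, f.source[0], f.source[1]])


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    frags: list[Fragment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "window":
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            window, label, pid, pos = row[0], row[1], row[2], int(row[3])
            n = len(window) // 2
            frags.append(
                Fragment(window=window, center_residue=window[n], label=label,
                         source=(pid, pos))
            )
    return frags
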
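"""Maximal dependence decomposition (MDD) of site fragments into motif
subgroups.

The 20 amino acids are collapsed into five biochemical groups (polar,
acidic, basic, hydrophobic, aromatic) so that the dependence between two
window positions can be tested with a 5x5 Pearson chi-squared statistic at
16 degrees of freedom. The set of positive fragments is recursively
partitioned on the position pair with the strongest significant dependence:
fragments carrying the dominant group at that position form the in-group
child, the rest the out-group child. Recursion stops when a subgroup falls
below ``max_cluster_size`` or no pair exceeds the significance cutoff
(34.3, the upper 0.005 quantile at 16 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, DUMMY
from .seq_windows import Fragment

CHI2_THRESHOLD_DEFAULT = 34.3  # chi2 upper 0.005 quantile, 16 df, 1 decimal

GROUP_NAMES = ("polar", "acidic", "basic", "hydrophobic", "aromatic")

#: Default partition of the 20 residues into the five biochemical groups.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "polar": ("C", "G", "N", "Q", "S", "T", "Y"),
    "acidic": ("D", "E"),
    "basic": ("H", "K", "R"),
    "hydrophobic": ("A", "I", "L", "M", "P", "V"),
    "aromatic": ("F", "W"),
}


@dataclass(frozen=True)
class GroupMap:
    """Assignment of each amino acid to one of five biochemical groups.

    Group indices are 1-based (1..5); the dummy symbol maps to none and is
    excluded from all contingency counts.
    """

    mapping: dict[str, int]
    group_names: tuple[str, ...] = GROUP_NAMES

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.mapping)
        if missing:
            raise ValueError(f"group map misses residues {sorted(missing)}")
        extra = set(self.mapping) - set(AMINO_ACIDS)
        if extra:
            raise ValueError(f"group map has non-residue keys {sorted(extra)}")
        bad = {g for g in self.mapping.values() if not 1 <= g <= len(self.group_names)}
        if bad:
            raise ValueError(f"group indices out of range: {sorted(bad)}")

    @classmethod
    def from_groups(cls, groups: dict[str, Sequence[str]]) -> "GroupMap":
        names = tuple(groups)
        mapping: dict[str, int] = {}
        for gi, name in enumerate(names, start=1):
            for aa in groups[name]:
                if aa in mapping:
                    raise ValueError(f"residue {aa!r} assigned to two groups")
                mapping[aa] = gi
        return cls(mapping=mapping, group_names=names)

    def group_of(self, aa: str) -> int:
        return self.mapping[aa]

    def residues_of(self, group_index: int) -> tuple[str, ...]:
        return tuple(a for a in AMINO_ACIDS if self.mapping[a] == group_index)


def default_group_map() -> GroupMap:
    return GroupMap.from_groups(DEFAULT_GROUPS)


@dataclass(frozen=True)
class DependencyResult:
    """Chi-squared dependence between two window offsets (center excluded)."""

    position_i: int  # signed offset, -n..+n, never 0
    position_j: int
    chi2: float
    significant: bool
    dominant_group: int  # 1..5, maximal row contribution at position_i


@dataclass
class MddNode:
    members: list[Fragment]
    split_position: Optional[int] = None  # signed offset
    split_group: Optional[int] = None
    chi2: Optional[float] = None
    children: list["MddNode"] = field(default_factory=list)
    leaf_id: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MddTree:
    root: MddNode
    group_map: GroupMap
    threshold: float
    max_cluster_size: int

    @property
    def leaves(self) -> list[MddNode]:
        return [node for node in self._walk(self.root) if node.is_leaf]

    def _walk(self, node: MddNode) -> Iterator[MddNode]:
        yield node
        for child in node.children:
            yield from self._walk(child)

    def to_dict(self) -> dict:
        def node_dict(node: MddNode) -> dict:
            d: dict = {
                "size": len(node.members),
                "members": [list(f.source) for f in node.members],
            }
            if node.is_leaf:
                d["leaf_id"] = node.leaf_id
            else:
                d["split_position"] = node.split_position
                d["split_group"] = node.split_group
                d["split_group_name"] = self.group_map.group_names[
                    node.split_group - 1
                ]
                d["chi2"] = round(float(node.chi2), 6)
                d["children"] = [node_dict(c) for c in node.children]
            return d

        return {
            "threshold": self.threshold,
            "max_cluster_size": self.max_cluster_size,
            "root": node_dict(self.root),
        }


# ---------------------------------------------------------------------------
# chi-squared machinery
# ---------------------------------------------------------------------------

def chi_squared(table: np.ndarray) -> float:
    """Pearson chi-squared statistic of a contingency table.

    Cells whose expected count is zero (an all-zero row or column) are
    skipped, which equals collapsing the empty categories.
    """
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    mask = expected > 0
    return float((((t - expected) ** 2)[mask] / expected[mask]).sum())


def significance(chi2: float, threshold: float = CHI2_THRESHOLD_DEFAULT) -> bool:
    """Strict exceedance of the chi-squared cutoff (default 34.3: the upper
    0.005 quantile at (5-1)x(5-1) degrees of freedom, one decimal)."""
    if chi2 < 0:
        raise ValueError("chi-squared statistic cannot be negative")
    return chi2 > threshold


def _group_matrix(members: Sequence[Fragment], group_map: GroupMap) -> np.ndarray:
    """Members x window matrix of group indices 1..5, 0 for dummy."""
    lut = np.zeros(128, dtype=np.int8)
    for aa, g in group_map.mapping.items():
        lut[ord(aa)] = g
    return np.array(
        [lut[np.frombuffer(f.window.encode(), dtype=np.uint8)] for f in members]
    )


def _offsets(window_length: int) -> list[int]:
    n = window_length // 2
    return [o for o in range(-n, n + 1) if o != 0]


def _pair_table(G: np.ndarray, ci: int, cj: int) -> np.ndarray:
    """5x5 co-occurrence counts for matrix columns ci, cj, skipping rows with
    a dummy at either position."""
    gi, gj = G[:, ci], G[:, cj]
    valid = (gi > 0) & (gj > 0)
    flat = (gi[valid] - 1) * 5 + (gj[valid] - 1)
    return np.bincount(flat, minlength=25).reshape(5, 5).astype(float)


def _dominant_group(table: np.ndarray) -> int:
    """Consensus group at position i: the modal row of the table.

    This is the classic MDD consensus rule — the in-group child collects the
    sequences carrying the most frequent group at the split position, which
    is the group the dependence signal rides on (a motif present in most
    members makes its group modal there). Ranking rows by their chi-squared
    contribution instead would pick the *complement* whenever the motif
    group dominates the margin (its row then matches expectation almost
    exactly while the depleted rows deviate relatively strongly), splitting
    off background instead of motif. Ties resolve to the smallest group
    index.
    """
    return int(np.argmax(table.sum(axis=1))) + 1


def scan_dependencies(
    members: Sequence[Fragment],
    group_map: GroupMap,
    threshold: float = CHI2_THRESHOLD_DEFAULT,
) -> list[DependencyResult]:
    """Chi-squared dependence for every ordered pair of non-center offsets.

    Sequences with a dummy at either position of a pair are skipped for that
    pair. Pairs with no co-observed sequences score 0.
    """
    if len(members) < 2:
        raise ValueError("dependence scan needs at least 2 fragments")
    G = _group_matrix(members, group_map)
    L = G.shape[1]
    n = L // 2
    offsets = _offsets(L)
    # each unordered pair is evaluated once and reported in both
    # orientations with the identical statistic (chi2 is symmetric; reusing
    # the value keeps the mirror orientations exactly tied)
    by_pair: dict[tuple[int, int], DependencyResult] = {}
    for a in range(len(offsets)):
        for b in range(a + 1, len(offsets)):
            oi, oj = offsets[a], offsets[b]
            table = _pair_table(G, oi + n, oj + n)
            if table.sum() == 0:
                chi2, dom_i, dom_j = 0.0, 1, 1
            else:
                chi2 = chi_squared(table)
                dom_i = _dominant_group(table)
                dom_j = _dominant_group(table.T)
            sig = significance(chi2, threshold)
            by_pair[(oi, oj)] = DependencyResult(
                position_i=oi, position_j=oj, chi2=chi2,
                significant=sig, dominant_group=dom_i,
            )
            by_pair[(oj, oi)] = DependencyResult(
                position_i=oj, position_j=oi, chi2=chi2,
                significant=sig, dominant_group=dom_j,
            )
    return [
        by_pair[(oi, oj)]
        for oi in offsets for oj in offsets if oi != oj
    ]


# ---------------------------------------------------------------------------
# recursive partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    position: int
    group: int
    chi2: float
    in_members: tuple[Fragment, ...]
    out_members: tuple[Fragment, ...]


def _rank_key(r: DependencyResult) -> tuple:
    # max chi2 first; ties: smallest |i|, negative offset before positive,
    # smallest group index, then the partner position for full determinism
    return (
        -r.chi2,
        abs(r.position_i),
        0 if r.position_i < 0 else 1,
        r.dominant_group,
        abs(r.position_j),
        0 if r.position_j < 0 else 1,
    )


def split_node(
    members: Sequence[Fragment],
    group_map: GroupMap,
    threshold: float = CHI2_THRESHOLD_DEFAULT,
    criterion: str = "pair",
) -> Optional[Split]:
    """Find the best split of *members*, or None when no dependence is
    significant.

    ``criterion='pair'`` (default) splits at the first position of the
    maximal-chi2 pair; ``criterion='sum'`` ranks positions by the summed
    chi2 over all partners, requiring at least one significant pair at the
    chosen position.
    """
    results = scan_dependencies(members, group_map, threshold)
    if criterion == "pair":
        best = min(results, key=_rank_key)
        if not best.significant:
            return None
        position, group = best.position_i, best.dominant_group
        chi2 = best.chi2
    elif criterion == "sum":
        sums: dict[int, float] = {}
        for r in results:
            sums[r.position_i] = sums.get(r.position_i, 0.0) + r.chi2
        candidates = [r for r in results if r.significant]
        if not candidates:
            return None
        position = min(
            {r.position_i for r in candidates},
            key=lambda p: (-sums[p], abs(p), 0 if p < 0 else 1),
        )
        best = min(
            (r for r in candidates if r.position_i == position), key=_rank_key
        )
        group, chi2 = best.dominant_group, best.chi2
    else:
        raise ValueError(f"unknown split criterion {criterion!r}")

    n = len(members[0].window) // 2
    col = position + n
    in_m, out_m = [], []
    for f in members:
        aa = f.window[col]
        if aa != DUMMY and group_map.group_of(aa) == group:
            in_m.append(f)
        else:
            out_m.append(f)
    if not in_m or not out_m:
        return None  # degenerate split carries no information
    return Split(
        position=position,
        group=group,
        chi2=chi2,
        in_members=tuple(in_m),
        out_members=tuple(out_m),
    )


def mdd_cluster(
    positives: Sequence[Fragment],
    group_map: Optional[GroupMap] = None,
    threshold: float = CHI2_THRESHOLD_DEFAULT,
    max_cluster_size: int = 30,
    prefix: Optional[str] = None,
    criterion: str = "pair",
    split_mode: str = "binary",
) -> MddTree:
    """Recursively partition positive fragments into motif subgroups.

    A node is split only while its size is at least ``max_cluster_size`` and
    a significant dependence exists. ``split_mode='binary'`` separates the
    dominant group from the rest; ``split_mode='five_way'`` makes one child
    per biochemical group observed at the split position (dummies join the
    out-group/rest child). Leaves are numbered depth-first, in-group child
    first, as ``<prefix>_1``, ``<prefix>_2``, ...
    """
    if not positives:
        raise ValueError("cannot cluster an empty positive set")
    if split_mode not in ("binary", "five_way"):
        raise ValueError(f"unknown split_mode {split_mode!r}")
    gmap = group_map or default_group_map()
    if prefix is None:
        prefix = positives[0].center_residue

    def build(members: list[Fragment]) -> MddNode:
        node = MddNode(members=members)
        if len(members) < max_cluster_size:
            return node
        split = split_node(members, gmap, threshold, criterion)
        if split is None:
            return node
        node.split_position = split.position
        node.split_group = split.group
        node.chi2 = split.chi2
        if split_mode == "binary":
            children = [list(split.in_members), list(split.out_members)]
        else:
            n = len(members[0].window) // 2
            col = split.position + n
            by_group: dict[int, list[Fragment]] = {}
            rest: list[Fragment] = []
            for f in members:
                aa = f.window[col]
                if aa == DUMMY:
                    rest.append(f)
                else:
                    by_group.setdefault(gmap.group_of(aa), []).append(f)
            # dominant group first, then remaining groups by index
            order = [split.group] + [
                g for g in sorted(by_group) if g != split.group
            ]
            children = [by_group[g] for g in order if g in by_group]
            if rest:
                children.append(rest)
            if len(children) < 2:
                node.split_position = node.split_group = node.chi2 = None
                return node
        node.children = [build(c) for c in children]
        return node

    root = build(list(positives))
    counter = 0
    def number(node: MddNode) -> None:
        nonlocal counter
        if node.is_leaf:
            counter += 1
            node.leaf_id = f"{prefix}_{counter}"
        else:
            for child in node.children:
                number(child)

    number(root)
    return MddTree(
        root=root, group_map=gmap, threshold=threshold,
        max_cluster_size=max_cluster_size,
    )


# ---------------------------------------------------------------------------
# logo export
# ---------------------------------------------------------------------------

def export_logo_counts(node: MddNode):
    """Position x residue count matrix of a node's members (dummies
    excluded), suitable for sequence-logo tools. Rows are signed offsets,
    columns the 20 residues."""
    import pandas as pd

    if not node.members:
        raise ValueError("empty node")
    L = len(node.members[0].window)
    n = L // 2
    counts = np.zeros((L, 20), dtype=int)
    for frag in node.members:
        for p, aa in enumerate(frag.window):
            if aa != DUMMY:
                counts[p, AA_INDEX[aa]] += 1
    return pd.DataFrame(
        counts, index=list(range(-n, n + 1)), columns=list(AMINO_ACIDS)
    )
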
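"""Amino-acid alphabet constants shared across the package.

All matrices and feature vectors use the alphabetical one-letter ordering
A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y. Terminus padding inside a sequence
window is written as the dummy symbol '-'.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
DUMMY: str = "-"

#: Residue types subject to carbonylation (direct ROS oxidation).
TARGET_RESIDUES: tuple[str, ...] = ("K", "R", "T", "P")


def validate_sequence(seq: str, *, context: str = "sequence") -> None:
    """Raise ValueError if *seq* is empty or contains non-standard letters."""
    if not seq:
        raise ValueError(f"{context}: empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"{context}: invalid amino-acid code(s) {sorted(bad)!r}; "
            f"only the 20 standard one-letter codes are accepted"
        )
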
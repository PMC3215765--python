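"""Protein pair sequence divergence.

Identity is the fraction of identical residues among aligned (non-gap)
columns of a pairwise alignment; the p-distance is its complement.  For use
as an evolutionary timescale, p-distances are converted to expected
substitutions per site with the Jukes-Cantor correction for amino acids,

    d_JC = -(19/20) * ln(1 - (20/19) * d),

which diverges at the saturation point d = 19/20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAP_CHARS",
    "DivergenceRecord",
    "p_distance",
    "jukes_cantor",
    "divergence_record",
]

GAP_CHARS = frozenset("-.")
JC_SATURATION = 19.0 / 20.0


@dataclass(frozen=True)
class DivergenceRecord:
    protein_1: str
    protein_2: str
    identity: float
    p_distance: float
    jc_distance: float


def p_distance(
    aligned_seq1: str, aligned_seq2: str, *, ambiguous_uncounted: bool = False
) -> tuple[float, float]:
    """(identity, p-distance) of two rows of a pairwise alignment.

    Columns where either row carries a gap are excluded.  Comparison is
    case-insensitive.  'X' counts as a difference by default; with
    ``ambiguous_uncounted=True`` columns containing 'X' are excluded
    instead.
    """
    if len(aligned_seq1) != len(aligned_seq2):
        raise ValueError(
            f"aligned sequences differ in length: {len(aligned_seq1)} vs {len(aligned_seq2)}"
        )
    counted = same = 0
    for c1, c2 in zip(aligned_seq1.upper(), aligned_seq2.upper()):
        if c1 in GAP_CHARS or c2 in GAP_CHARS:
            continue
        if ambiguous_uncounted and "X" in (c1, c2):
            continue
        counted += 1
        if c1 == c2:
            same += 1
    if counted == 0:
        raise ValueError("no columns with residues on both rows")
    identity = same / counted
    return identity, 1.0 - identity


def jukes_cantor(d: float) -> float:
    """Jukes-Cantor-corrected amino acid distance for p-distance ``d``."""
    if not 0.0 <= d < JC_SATURATION:
        raise ValueError(f"p-distance {d} outside [0, 19/20): correction undefined (saturation)")
    return -JC_SATURATION * math.log(1.0 - d / JC_SATURATION)


def divergence_record(
    protein_1: str, protein_2: str, aligned_seq1: str, aligned_seq2: str, **kwargs
) -> DivergenceRecord:
    identity, d = p_distance(aligned_seq1, aligned_seq2, **kwargs)
    return DivergenceRecord(protein_1, protein_2, identity, d, jukes_cantor(d))
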
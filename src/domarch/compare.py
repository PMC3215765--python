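"""DA-score and the four-way architecture similarity classification.

The DA-score of an aligned protein pair is

    DA(p1, p2) = a12 / (n1 + n2)

where n1 and n2 are the domain counts of the two proteins and a12 is the
number of domains, summed over both proteins, aligned against an identical
domain or one from the same Pfam clan.  It ranges from 0 (disjoint domain
sets) to 1 (identical architectures).

Pairs are further placed in one of four similarity classes:

* ``Identical`` — equal label sequences;
* ``SameContentNotAligned`` — equal label *sets* but different sequences
  (different order, possibly different copy numbers per type);
* ``DiffContent`` — overlapping but unequal label sets;
* ``NoShared`` — disjoint label sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import ArchAlignment, CostScheme, align_architectures
from .model import Architecture

__all__ = ["SimilarityClass", "DAResult", "da_score", "similarity_class", "compare_pair"]


class SimilarityClass(str, Enum):
    IDENTICAL = "Identical"
    SAME_CONTENT_NOT_ALIGNED = "SameContentNotAligned"
    DIFF_CONTENT = "DiffContent"
    NO_SHARED = "NoShared"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class DAResult:
    protein_1: str
    protein_2: str
    n1: int
    n2: int
    a12: int
    da_score: float
    similarity_class: SimilarityClass


def da_score(al: ArchAlignment) -> float:
    """a12 / (n1 + n2), in [0, 1]."""
    return al.a12 / (al.n1 + al.n2)


def similarity_class(
    a1: Architecture, a2: Architecture, al: ArchAlignment | None = None
) -> SimilarityClass:
    """Classify a pair by label sequence/set relations.

    The alignment argument is accepted for interface symmetry but the
    classification depends only on the two label sequences.
    """
    if a1.labels == a2.labels:
        return SimilarityClass.IDENTICAL
    if a1.label_set == a2.label_set:
        return SimilarityClass.SAME_CONTENT_NOT_ALIGNED
    if a1.label_set & a2.label_set:
        return SimilarityClass.DIFF_CONTENT
    return SimilarityClass.NO_SHARED


def compare_pair(
    a1: Architecture, a2: Architecture, costs: CostScheme | None = None
) -> tuple[DAResult, ArchAlignment]:
    """Align two architectures and package score plus class."""
    al = align_architectures(a1, a2, costs)
    return (
        DAResult(
            a1.protein_id,
            a2.protein_id,
            al.n1,
            al.n2,
            al.a12,
            da_score(al),
            similarity_class(a1, a2, al),
        ),
        al,
    )
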
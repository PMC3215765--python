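"""Global alignment of two domain architectures.

A Needleman-Wunsch variant over domain-label strings with linear (non-affine)
gap costs.  The penalty scheme — match 0, gap 3, mismatch 10 — deliberately
makes a mismatch dearer than two gaps, so optimal alignments never pair two
different domains; the mismatch state exists only for non-default schemes.
Costs are minimized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .model import Architecture

__all__ = ["GAP", "CostScheme", "ArchAlignment", "align_architectures", "matched_pairs"]

#: Sentinel marking a gap on one side of an alignment column.
GAP = None

TieBreak = Literal["diag_up_left", "diag_left_up"]


@dataclass(frozen=True)
class CostScheme:
    """Edit penalties for architecture alignment (lower is better)."""

    match_cost: float = 0.0
    gap_cost: float = 3.0
    mismatch_cost: float = 10.0

    def __post_init__(self) -> None:
        if min(self.match_cost, self.gap_cost, self.mismatch_cost) < 0:
            raise ValueError("costs must be non-negative")
        if self.mismatch_cost <= 2 * self.gap_cost:
            warnings.warn(
                "mismatch_cost <= 2*gap_cost: optimal alignments may pair "
                "different domains, so matched units no longer imply identity",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ArchAlignment:
    """A minimum-cost global alignment of two architectures.

    ``columns`` pairs unit indices of the two architectures; ``GAP`` (None)
    on either side marks an indel column.  ``a12`` is the number of domains
    summed over *both* proteins that sit in match columns, i.e. twice the
    match-column count — the numerator of the DA-score.
    """

    columns: tuple[tuple[int | None, int | None], ...]
    total_cost: float
    n1: int
    n2: int
    labels1: tuple[str, ...]
    labels2: tuple[str, ...]

    @property
    def match_columns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (i, j)
            for i, j in self.columns
            if i is not None and j is not None and self.labels1[i] == self.labels2[j]
        )

    @property
    def a12(self) -> int:
        return 2 * len(self.match_columns)

    def aligned_indices(self, side: int) -> frozenset[int]:
        """Indices of units of architecture 1 or 2 sitting in match columns."""
        if side not in (1, 2):
            raise ValueError("side must be 1 or 2")
        return frozenset(col[side - 1] for col in self.match_columns)

    def render(self) -> str:
        """Two-row debug view with '-' for gaps plus a cost line."""
        row1, row2 = [], []
        for i, j in self.columns:
            a = self.labels1[i] if i is not None else "-"
            b = self.labels2[j] if j is not None else "-"
            w = max(len(a), len(b))
            row1.append(a.ljust(w))
            row2.append(b.ljust(w))
        return " ".join(row1) + "\n" + " ".join(row2) + f"\ncost={self.total_cost:g}"


def align_architectures(
    a1: Architecture,
    a2: Architecture,
    costs: CostScheme | None = None,
    *,
    tie_break: TieBreak = "diag_up_left",
) -> ArchAlignment:
    """Minimum-cost global alignment of two architectures.

    "Match" means equal effective labels (clan equivalence is already folded
    into the labels).  Traceback is deterministic: on cost ties the default
    order prefers a diagonal step, then a gap in architecture 2, then a gap
    in architecture 1, evaluated from the terminal cell; ``tie_break=
    "diag_left_up"`` swaps the two gap preferences.  End gaps are charged
    like internal gaps.
    """
    costs = costs or CostScheme()
    s1, s2 = a1.labels, a2.labels
    n, m = len(s1), len(s2)
    if n == 0 or m == 0:
        raise ValueError("cannot align an empty architecture")

    g, mm, mc = costs.gap_cost, costs.mismatch_cost, costs.match_cost
    # D[i][j] = min cost aligning s1[:i] with s2[:j]
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i * g
    for j in range(1, m + 1):
        D[0][j] = j * g
    for i in range(1, n + 1):
        row, prev = D[i], D[i - 1]
        c1 = s1[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (mc if c1 == s2[j - 1] else mm)
            row[j] = min(sub, prev[j] + g, row[j - 1] + g)

    # traceback from the terminal cell
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        diag = up = left = False
        if i > 0 and j > 0:
            step = mc if s1[i - 1] == s2[j - 1] else mm
            diag = D[i][j] == D[i - 1][j - 1] + step
        if i > 0:
            up = D[i][j] == D[i - 1][j] + g  # consume from a1, gap in a2
        if j > 0:
            left = D[i][j] == D[i][j - 1] + g  # gap in a1, consume from a2
        order = ("diag", "up", "left") if tie_break == "diag_up_left" else ("diag", "left", "up")
        for move in order:
            if move == "diag" and diag:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                break
            if move == "up" and up:
                cols.append((i - 1, GAP))
                i -= 1
                break
            if move == "left" and left:
                cols.append((GAP, j - 1))
                j -= 1
                break
    cols.reverse()
    return ArchAlignment(tuple(cols), D[n][m], n, m, s1, s2)


def matched_pairs(al: ArchAlignment) -> int:
    """Number of match columns (a12 is twice this)."""
    return len(al.match_columns)
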
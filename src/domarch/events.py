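"""Annotation of domain-swapping events on aligned architecture pairs.

For a pair whose architectures share at least one domain but are not
identical, every unaligned unit is explained by exactly one of five event
categories, tested in a fixed order of priority (easier evolutionary events
take precedence only in the sense that earlier rules mask later ones):

1. **Segment duplication/deletion** — the unit belongs to a maximal
   unaligned segment of >= 2 units with >= 2 distinct labels that sits next
   to an identical aligned segment; the unaligned segment may be a
   whole-number tandem repeat of the aligned one.
2. **Repetition difference** — the unit is immediately adjacent, within its
   own protein, to an *aligned* unit of the same label (copy-number change).
3. **Insertion/deletion of a new domain** — the other protein has no unit
   of this label at all.
4. **Insertion/deletion of an existing domain** — the other protein has an
   aligned unit of this label (and rule 2 failed).
5. **Domain shuffling** — everything left; the label is then necessarily
   unaligned in both proteins, indicating order rearrangement.

Insertion and deletion cannot be told apart from a pair alone, so the
categories are direction-agnostic.  An event's position along the protein is
N-terminal, middle, or C-terminal depending on which sides of it aligned
units remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .align import ArchAlignment
from .compare import SimilarityClass, similarity_class
from .model import Architecture

__all__ = [
    "EventCategory",
    "Position",
    "EventAnnotation",
    "ChangeEvent",
    "annotate_events",
    "classify_position",
    "group_into_events",
    "position_bias_summary",
]


class EventCategory(str, Enum):
    SEGMENT_DUP_DEL = "SegmentDupDel"
    REPETITION_DIFFERENCE = "RepetitionDifference"
    INSDEL_NEW_DOMAIN = "InsDelNewDomain"
    INSDEL_EXISTING_DOMAIN = "InsDelExistingDomain"
    DOMAIN_SHUFFLING = "DomainShuffling"

    def __str__(self) -> str:
        return self.value


class Position(str, Enum):
    N_TERMINAL = "N_terminal"
    MIDDLE = "Middle"
    C_TERMINAL = "C_terminal"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class EventAnnotation:
    """One unaligned unit's explanation."""

    protein: int  # 1 or 2
    unit_index: int
    label: str
    category: EventCategory
    position: Position


@dataclass(frozen=True)
class ChangeEvent:
    """A maximal run of same-category unaligned units, tallied as one event."""

    protein: int
    unit_indices: tuple[int, ...]
    label_seq: tuple[str, ...]
    category: EventCategory
    position: Position


def _unaligned_runs(n: int, aligned: frozenset[int]) -> list[tuple[int, int]]:
    """Maximal [start, end] runs of unaligned indices."""
    runs, start = [], None
    for i in range(n):
        if i not in aligned:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    return runs


def _flank(labels: Sequence[str], aligned: frozenset[int], pos: int, step: int) -> list[str]:
    """Labels of the maximal aligned run adjacent to ``pos`` going ``step``-ward."""
    out, i = [], pos
    while 0 <= i < len(labels) and i in aligned:
        out.append(labels[i])
        i += step
    if step < 0:
        out.reverse()
    return out


def _tandem_prefix_len(seq: Sequence[str], motif: Sequence[str]) -> int:
    """Length of the longest prefix of ``seq`` made of whole copies of ``motif``."""
    L, k = len(motif), 0
    while (k + 1) * L <= len(seq) and tuple(seq[k * L : (k + 1) * L]) == tuple(motif):
        k += 1
    return k * L


def _segment_dup_units(
    labels: Sequence[str], aligned: frozenset[int], run: tuple[int, int]
) -> set[int]:
    """Indices within an unaligned run explained as segment duplication/deletion.

    The run (or a tandem-whole prefix/suffix of it) must equal whole copies
    of a >=2-long, >=2-distinct-label segment that ends (left flank) or
    starts (right flank) the adjacent aligned run.  Excess units fall
    through to later rules.
    """
    start, end = run
    seg = labels[start : end + 1]
    best: set[int] = set()
    left = _flank(labels, aligned, start - 1, -1)
    right = _flank(labels, aligned, end + 1, +1)
    for flank_labels, from_left in ((left, True), (right, False)):
        for L in range(2, min(len(flank_labels), len(seg)) + 1):
            motif = flank_labels[-L:] if from_left else flank_labels[:L]
            if len(set(motif)) < 2:
                continue
            if from_left:
                covered = _tandem_prefix_len(seg, motif)
                idx = set(range(start, start + covered))
            else:
                covered = _tandem_prefix_len(list(reversed(seg)), list(reversed(motif)))
                idx = set(range(end - covered + 1, end + 1))
            if len(idx) > len(best):
                best = idx
    return best


def classify_position(al: ArchAlignment, protein: int, unit_index: int) -> Position:
    """Position of an unaligned unit relative to aligned units in its protein."""
    aligned = al.aligned_indices(protein)
    if unit_index in aligned:
        raise ValueError(f"unit {unit_index} of protein {protein} is aligned")
    has_n = any(i < unit_index for i in aligned)
    has_c = any(i > unit_index for i in aligned)
    if has_n and has_c:
        return Position.MIDDLE
    if has_n:
        return Position.C_TERMINAL
    if has_c:
        return Position.N_TERMINAL
    raise ValueError("no aligned units on either side; pair should not be annotated")


def annotate_events(
    a1: Architecture, a2: Architecture, al: ArchAlignment
) -> list[EventAnnotation]:
    """Assign each unaligned unit of the pair its highest-priority category.

    Only pairs that are neither ``Identical`` nor ``NoShared`` may be
    annotated.
    """
    cls = similarity_class(a1, a2, al)
    if cls in (SimilarityClass.IDENTICAL, SimilarityClass.NO_SHARED):
        raise ValueError(f"pair of class {cls} is not annotated")

    sides = {1: a1.labels, 2: a2.labels}
    aligned = {p: al.aligned_indices(p) for p in (1, 2)}
    out: list[EventAnnotation] = []
    for p in (1, 2):
        labels = sides[p]
        other_labels = set(sides[3 - p])
        other_aligned_labels = {sides[3 - p][i] for i in aligned[3 - p]}
        category: dict[int, EventCategory] = {}

        for run in _unaligned_runs(len(labels), aligned[p]):
            for i in _segment_dup_units(labels, aligned[p], run):
                category[i] = EventCategory.SEGMENT_DUP_DEL
            for i in range(run[0], run[1] + 1):
                if i in category:
                    continue
                lab = labels[i]
                if any(
                    0 <= j < len(labels) and j in aligned[p] and labels[j] == lab
                    for j in (i - 1, i + 1)
                ):
                    category[i] = EventCategory.REPETITION_DIFFERENCE
                elif lab not in other_labels:
                    category[i] = EventCategory.INSDEL_NEW_DOMAIN
                elif lab in other_aligned_labels:
                    category[i] = EventCategory.INSDEL_EXISTING_DOMAIN
                else:
                    category[i] = EventCategory.DOMAIN_SHUFFLING

        for i in sorted(category):
            out.append(
                EventAnnotation(p, i, labels[i], category[i], classify_position(al, p, i))
            )
    return out


def group_into_events(annotations: Iterable[EventAnnotation]) -> list[ChangeEvent]:
    """Collapse maximal same-protein, same-category runs of consecutive
    unaligned units into single change events for tallying."""
    anns = sorted(annotations, key=lambda a: (a.protein, a.unit_index))
    events: list[ChangeEvent] = []
    buf: list[EventAnnotation] = []

    def flush() -> None:
        if buf:
            events.append(
                ChangeEvent(
                    buf[0].protein,
                    tuple(a.unit_index for a in buf),
                    tuple(a.label for a in buf),
                    buf[0].category,
                    buf[0].position,
                )
            )
            buf.clear()

    for a in anns:
        if buf and (
            a.protein != buf[-1].protein
            or a.category != buf[-1].category
            or a.unit_index != buf[-1].unit_index + 1
        ):
            flush()
        buf.append(a)
    flush()
    return events


def position_bias_summary(
    events_by_cluster: Mapping[str, Sequence[ChangeEvent]],
) -> dict[str, float]:
    """Mean over clusters of the within-cluster position fractions.

    Clusters with no events are excluded; the three fractions sum to 1 both
    per cluster and in the mean.  Returns an empty dict when no cluster has
    events.
    """
    per_cluster: list[tuple[float, float, float]] = []
    for events in events_by_cluster.values():
        if not events:
            continue
        n = len(events)
        counts = {pos: 0 for pos in Position}
        for ev in events:
            counts[ev.position] += 1
        per_cluster.append(
            (
                counts[Position.N_TERMINAL] / n,
                counts[Position.MIDDLE] / n,
                counts[Position.C_TERMINAL] / n,
            )
        )
    if not per_cluster:
        return {}
    k = len(per_cluster)
    return {
        str(Position.N_TERMINAL): sum(f[0] for f in per_cluster) / k,
        str(Position.MIDDLE): sum(f[1] for f in per_cluster) / k,
        str(Position.C_TERMINAL): sum(f[2] for f in per_cluster) / k,
    }
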
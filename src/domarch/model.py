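"""Domain architecture construction.

A protein's domain architecture is the N- to C-terminal ordered sequence of
its Pfam-A domains.  Two preprocessing steps make architectures comparable
across homologs:

* **Repeat/Motif collapsing** — runs of consecutive hits of the same
  Repeat- or Motif-type family are collapsed into a single pseudo-domain,
  because copy number in such stretches drifts far more easily than the
  rest of the architecture.  Family/Domain-type stretches are kept as-is.
* **Clan equivalence** — Pfam families that belong to the same clan are
  treated as identical.  Every unit therefore carries an *effective label*
  (the clan accession when the family has one, the family accession
  otherwise) and all downstream identity checks compare effective labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TYPE_CLASSES",
    "DomainHit",
    "ClanMap",
    "ArchUnit",
    "Architecture",
    "ClanMapError",
    "load_clan_map",
    "effective_label",
    "build_architecture",
    "build_architectures",
]

#: Pfam type classes.  Only Repeat and Motif participate in collapsing.
TYPE_CLASSES = frozenset({"Family", "Domain", "Repeat", "Motif"})
COLLAPSIBLE = frozenset({"Repeat", "Motif"})


class ClanMapError(ValueError):
    """Raised on malformed or self-contradictory clan mapping input."""


@dataclass(frozen=True)
class DomainHit:
    """One raw domain assignment on a protein (1-based inclusive coords)."""

    protein_id: str
    accession: str
    start: int
    end: int
    type_class: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.accession}: start {self.start} > end {self.end}"
            )
        if self.type_class not in TYPE_CLASSES:
            raise ValueError(
                f"unknown type class {self.type_class!r}; expected one of {sorted(TYPE_CLASSES)}"
            )


class ClanMap:
    """Accession -> clan lookup; unmapped accessions are clanless."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = dict(mapping or {})

    def clan_of(self, accession: str) -> str | None:
        return self._map.get(accession)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ClanMap) and self._map == other._map

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)


@dataclass(frozen=True)
class ArchUnit:
    """One effective unit of an architecture.

    ``label`` is the identity used by every comparison downstream: the clan
    accession when the family is in a clan, else the family accession.
    ``run_length`` records how many raw consecutive Repeat/Motif hits were
    collapsed into this unit; it is metadata only — a collapsed unit counts
    as exactly one domain everywhere.
    """

    label: str
    accession: str
    type_class: str
    run_length: int = 1

    def __post_init__(self) -> None:
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.run_length > 1 and self.type_class not in COLLAPSIBLE:
            raise ValueError("only Repeat/Motif units may have run_length > 1")


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    units: tuple[ArchUnit, ...]

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"{self.protein_id}: architecture must be non-empty")

    def __len__(self) -> int:
        return len(self.units)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(u.label for u in self.units)

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(u.label for u in self.units)


def load_clan_map(path) -> ClanMap:
    """Read a two-plus-column TSV of accession -> clan.

    Follows the Pfam-A clans flat-file convention: first column is the
    family accession, second the clan accession; an empty clan field means
    the family is clanless.  Lines starting with ``#`` and blank lines are
    skipped.  Conflicting duplicate rows are an error.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ClanMapError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            acc, clan = parts[0].strip(), parts[1].strip()
            if not acc:
                raise ClanMapError(f"{path}:{lineno}: empty accession")
            if acc == "accession":  # optional header row
                continue
            if not clan:
                continue  # clanless family
            if acc in mapping and mapping[acc] != clan:
                raise ClanMapError(
                    f"{path}:{lineno}: accession {acc} mapped to both {mapping[acc]} and {clan}"
                )
            mapping[acc] = clan
    return ClanMap(mapping)


def effective_label(accession: str, clans: ClanMap) -> str:
    """The identity used in all architecture comparisons."""
    clan = clans.clan_of(accession)
    return clan if clan is not None else accession


def build_architecture(
    hits: Iterable[DomainHit],
    clans: ClanMap | None = None,
    *,
    overlap_tolerance: int = 0,
    strict: bool = False,
) -> Architecture:
    """Order hits along the sequence and collapse Repeat/Motif runs.

    Hits are sorted by start coordinate (ties by end, then accession).  A
    maximal run of consecutive hits that share the same effective label and
    are all Repeat/Motif-type becomes one pseudo-domain unit whose
    ``run_length`` is the run size.  Every other hit becomes a unit of its
    own.  Clan mapping is applied *before* collapsing, so two Repeat
    families of the same clan in a run collapse together.

    Overlapping hits (beyond ``overlap_tolerance`` residues) draw a warning,
    or an error under ``strict=True``; ordering by start is kept either way.
    """
    clans = clans or ClanMap()
    hits = list(hits)
    if not hits:
        raise ValueError("no-domain protein must be filtered upstream")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    protein_id = hits[0].protein_id

    hits.sort(key=lambda h: (h.start, h.end, h.accession))
    for prev, cur in zip(hits, hits[1:]):
        if cur.start <= prev.end - overlap_tolerance:
            msg = (
                f"{protein_id}: hits {prev.accession}@{prev.start}-{prev.end} and "
                f"{cur.accession}@{cur.start}-{cur.end} overlap"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    units: list[ArchUnit] = []
    for h in hits:
        label = effective_label(h.accession, clans)
        if (
            units
            and units[-1].type_class in COLLAPSIBLE
            and h.type_class in COLLAPSIBLE
            and units[-1].label == label
        ):
            last = units[-1]
            units[-1] = ArchUnit(last.label, last.accession, last.type_class, last.run_length + 1)
        else:
            units.append(ArchUnit(label, h.accession, h.type_class, 1))
    return Architecture(protein_id, tuple(units))


def build_architectures(
    hits_by_protein: Mapping[str, Iterable[DomainHit]],
    clans: ClanMap | None = None,
    **kwargs,
) -> dict[str, Architecture]:
    """Build an architecture per protein; proteins with no hits are absent."""
    out = {}
    for pid, hits in hits_by_protein.items():
        hits = list(hits)
        if hits:
            out[pid] = build_architecture(hits, clans, **kwargs)
    return out
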
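"""Ortholog clusters, homolog pair enumeration, and cluster-weighted means.

An ortholog cluster holds all genes of two species descending from one gene
in their last common ancestor.  Four pair categories are drawn from the
clusters:

* ``O``   — ortholog pairs: cross-species pairs within one cluster;
* ``iP``  — inparalog pairs: same-species pairs within one cluster;
* ``oPx`` — closest cross-species outparalog: a cluster member paired with
  the highest-bit-score protein of the *other* species outside the cluster;
* ``oPs`` — closest same-species outparalog, defined analogously within the
  member's own species.

Aggregate similarity scores are means of per-cluster means, so every
cluster contributes equally regardless of size.  A pair whose two proteins
sit in different clusters and are mutually each other's closest
non-clustermate homolog contributes to both clusters' means.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PairType",
    "OrthologCluster",
    "ScoreTable",
    "OutparalogCutoffs",
    "HomologPair",
    "ClusterTableError",
    "parse_clusters",
    "enumerate_within_cluster_pairs",
    "closest_outparalogs",
    "all_pairs",
    "split_one_to_one",
    "mean_of_cluster_means",
]

logger = logging.getLogger(__name__)

PAIR_TYPES = ("O", "iP", "oPx", "oPs")
PairType = str


class ClusterTableError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: tuple[tuple[str, str], ...]  # (protein_id, species)
    seed_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        species = {sp for _, sp in self.members}
        if len(species) != 2:
            raise ClusterTableError(
                f"cluster {self.cluster_id} spans {len(species)} species; exactly 2 required"
            )

    @property
    def species(self) -> tuple[str, str]:
        return tuple(sorted({sp for _, sp in self.members}))

    def members_of(self, species: str) -> list[str]:
        return [p for p, sp in self.members if sp == species]

    @property
    def is_one_to_one(self) -> bool:
        a, b = self.species
        return len(self.members_of(a)) == 1 and len(self.members_of(b)) == 1


@dataclass(frozen=True)
class OutparalogCutoffs:
    """InParanoid-style match acceptance cutoffs."""

    bit_score: float = 40.0
    overlap: float = 0.50
    segment: float = 0.25


class ScoreTable:
    """Pairwise bit scores with optional coverage fields.

    Lookup takes the maximum over the two BLAST directions when both are
    present.  Missing entries mean "no hit".
    """

    def __init__(self) -> None:
        self._scores: dict[tuple[str, str], float] = {}
        self._coverage: dict[tuple[str, str], tuple[float | None, float | None]] = {}

    def add(
        self,
        query: str,
        subject: str,
        bits: float,
        overlap_frac: float | None = None,
        segment_frac: float | None = None,
    ) -> None:
        if bits < 0:
            raise ValueError("bit scores must be >= 0")
        self._scores[(query, subject)] = bits
        self._coverage[(query, subject)] = (overlap_frac, segment_frac)

    def bits(self, a: str, b: str) -> float | None:
        s1 = self._scores.get((a, b))
        s2 = self._scores.get((b, a))
        if s1 is None and s2 is None:
            return None
        return max(s for s in (s1, s2) if s is not None)

    def passes(self, a: str, b: str, cutoffs: OutparalogCutoffs) -> bool:
        """True when the pair has a hit meeting the bit-score cutoff and,
        where coverage fields exist, the overlap and segment cutoffs."""
        bits = self.bits(a, b)
        if bits is None or bits < cutoffs.bit_score:
            return False
        for key in ((a, b), (b, a)):
            cov = self._coverage.get(key)
            if cov is None:
                continue
            overlap, segment = cov
            if overlap is not None and overlap < cutoffs.overlap:
                return False
            if segment is not None and segment < cutoffs.segment:
                return False
        return True

    def partners_of(self, protein: str) -> set[str]:
        out = set()
        for q, s in self._scores:
            if q == protein:
                out.add(s)
            elif s == protein:
                out.add(q)
        return out

    def __len__(self) -> int:
        return len(self._scores)


@dataclass(frozen=True)
class HomologPair:
    protein_1: str
    protein_2: str
    pair_type: PairType
    cluster_ids: tuple[str, ...]
    da_score: float | None = None
    similarity_class: str | None = None
    divergence: float | None = None

    def with_scores(self, **kwargs) -> "HomologPair":
        return replace(self, **kwargs)

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.protein_1, self.protein_2)))


def parse_clusters(path) -> list[OrthologCluster]:
    """Read a clusters TSV (cluster_id, species, protein_id, is_seed).

    Validates the two-species invariant and that no protein appears in more
    than one cluster of the comparison.
    """
    rows: dict[str, list[tuple[str, str, bool]]] = defaultdict(list)
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                expected = ["cluster_id", "species", "protein_id", "is_seed"]
                if [c.strip() for c in header[:4]] != expected:
                    raise ClusterTableError(
                        f"{path}:{lineno}: expected header {expected}, got {header[:4]}"
                    )
                continue
            if len(parts) < 4:
                raise ClusterTableError(f"{path}:{lineno}: expected 4 columns")
            cid, species, pid, seed = (p.strip() for p in parts[:4])
            rows[cid].append((pid, species, seed == "1"))

    seen: dict[str, str] = {}
    clusters = []
    for cid in sorted(rows):
        members = tuple((pid, sp) for pid, sp, _ in rows[cid])
        for pid, _, _ in rows[cid]:
            if pid in seen:
                raise ClusterTableError(
                    f"protein {pid} appears in clusters {seen[pid]} and {cid}"
                )
            seen[pid] = cid
        seeds = [pid for pid, _, is_seed in rows[cid] if is_seed]
        seed_pair = tuple(sorted(seeds)) if len(seeds) == 2 else None
        clusters.append(OrthologCluster(cid, members, seed_pair))
    return clusters


def enumerate_within_cluster_pairs(
    cluster: OrthologCluster,
) -> tuple[list[HomologPair], list[HomologPair]]:
    """All ortholog (cross-species) and inparalog (same-species) pairs."""
    sp_a, sp_b = cluster.species
    mem_a = sorted(cluster.members_of(sp_a))
    mem_b = sorted(cluster.members_of(sp_b))
    orthologs = [
        HomologPair(p, q, "O", (cluster.cluster_id,)) for p in mem_a for q in mem_b
    ]
    inparalogs = []
    for group in (mem_a, mem_b):
        for i, p in enumerate(group):
            for q in group[i + 1 :]:
                inparalogs.append(HomologPair(p, q, "iP", (cluster.cluster_id,)))
    return orthologs, inparalogs


def _cluster_index(clusters: Sequence[OrthologCluster]) -> dict[str, str]:
    return {pid: c.cluster_id for c in clusters for pid, _ in c.members}


def closest_outparalogs(
    clusters: Sequence[OrthologCluster],
    scores: ScoreTable,
    species_of: Mapping[str, str],
    cutoffs: OutparalogCutoffs | None = None,
) -> tuple[list[HomologPair], list[HomologPair]]:
    """oPs and oPx pairs for every cluster member.

    The closest same-species (cross-species) outparalog of a member is the
    highest-bit-score protein of that species (the other species) outside
    the member's cluster that passes the cutoffs; bit-score ties break on
    lexicographic protein id.  Members with no qualifying match yield no
    pair.  Mutually-closest partners sitting in two different clusters
    produce a single pair credited to both clusters.
    """
    cutoffs = cutoffs or OutparalogCutoffs()
    cluster_of = _cluster_index(clusters)
    # pair key -> (type, set of contributing cluster ids)
    chosen: dict[tuple[tuple[str, str], PairType], set[str]] = defaultdict(set)

    for cluster in clusters:
        sp_a, sp_b = cluster.species
        for member, msp in cluster.members:
            other_sp = sp_b if msp == sp_a else sp_a
            best: dict[str, tuple[float, str]] = {}
            for cand in scores.partners_of(member):
                if cand == member or cluster_of.get(cand) == cluster.cluster_id:
                    continue
                csp = species_of.get(cand)
                if csp not in (msp, other_sp):
                    continue
                if not scores.passes(member, cand, cutoffs):
                    continue
                bits = scores.bits(member, cand)
                cur = best.get(csp)
                # higher bits wins; ties break toward the smaller id
                if cur is None or bits > cur[0] or (bits == cur[0] and cand < cur[1]):
                    best[csp] = (bits, cand)
            for csp, (bits, partner) in best.items():
                ptype: PairType = "oPs" if csp == msp else "oPx"
                key = tuple(sorted((member, partner)))
                chosen[(key, ptype)].add(cluster.cluster_id)

    ops: list[HomologPair] = []
    opx: list[HomologPair] = []
    for (key, ptype), cids in sorted(chosen.items()):
        pair = HomologPair(key[0], key[1], ptype, tuple(sorted(cids)))
        (ops if ptype == "oPs" else opx).append(pair)
    return ops, opx


def all_pairs(
    clusters: Sequence[OrthologCluster],
    scores: ScoreTable | None = None,
    species_of: Mapping[str, str] | None = None,
    cutoffs: OutparalogCutoffs | None = None,
) -> dict[PairType, list[HomologPair]]:
    """Enumerate every pair of all four categories."""
    out: dict[PairType, list[HomologPair]] = {t: [] for t in PAIR_TYPES}
    for c in clusters:
        orth, inp = enumerate_within_cluster_pairs(c)
        out["O"].extend(orth)
        out["iP"].extend(inp)
    if scores is not None:
        if species_of is None:
            species_of = {pid: sp for c in clusters for pid, sp in c.members}
        ops, opx = closest_outparalogs(clusters, scores, species_of, cutoffs)
        out["oPs"] = ops
        out["oPx"] = opx
    return out


def split_one_to_one(
    clusters: Iterable[OrthologCluster],
) -> tuple[list[OrthologCluster], list[OrthologCluster]]:
    """Partition clusters into (1-1, duplicated)."""
    ones, dups = [], []
    for c in clusters:
        (ones if c.is_one_to_one else dups).append(c)
    return ones, dups


def mean_of_cluster_means(
    pairs: Iterable[HomologPair],
    value=lambda p: p.da_score,
) -> tuple[float | None, dict[str, float]]:
    """Unweighted mean over clusters of the per-cluster mean pair value.

    A pair listed under two clusters enters both cluster means.  Pairs with
    a missing value are dropped with a logged count.  Returns
    ``(aggregate, per_cluster_means)``; the aggregate is None when no
    cluster has a scored pair.
    """
    by_cluster: dict[str, list[float]] = defaultdict(list)
    dropped = 0
    for pair in pairs:
        v = value(pair)
        if v is None:
            dropped += 1
            continue
        for cid in pair.cluster_ids:
            by_cluster[cid].append(float(v))
    if dropped:
        logger.info("dropped %d pairs with missing values", dropped)
    cluster_means = {cid: sum(vs) / len(vs) for cid, vs in by_cluster.items()}
    if not cluster_means:
        return None, {}
    return sum(cluster_means.values()) / len(cluster_means), cluster_means
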
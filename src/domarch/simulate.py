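"""Synthetic architecture-evolution generator with known ground truth.

Emulates the statistical structure the analysis assumes: two species, a set
of ortholog clusters, and for every cluster a known gene tree along whose
branches domain-architecture events and sequence divergence accumulate.
Duplication (inparalog) branches and pre-speciation (outparalog) branches
carry elevated event rates, so architecture conservation relaxes after
duplication — the property the downstream comparison is built to detect.

Clusters are generated in sister pairs descending from a common
pre-speciation family ancestor, which provides every cluster member with
candidate outparalogs (the members of the sister cluster) and exercises
closest-outparalog selection, including the mutual-closest two-cluster
contribution rule.

Residue-level evolution is emulated only at the aligned-pair level: for
every emitted pair an ungapped alignment of the configured length is drawn
with a Binomial(length, d) number of differing sites, where d is the summed
branch p-distance of the pair's path (capped below the Jukes-Cantor
saturation point).  Bit scores are a decreasing function of d plus noise —
only their ordering matters, for partner selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import EventAnnotation, EventCategory
from .model import DomainHit
from .pairs import OrthologCluster

__all__ = [
    "EventRates",
    "SimulationConfig",
    "TrueEvent",
    "GroundTruth",
    "SimulatedDataset",
    "simulate",
    "recovery_report",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
JC_CAP = 0.88  # keep pair p-distances clear of the Jukes-Cantor singularity


@dataclass(frozen=True)
class EventRates:
    """Per-branch probability of each architecture event category."""

    segment_dup: float = 0.0
    repetition: float = 0.0
    insdel_new: float = 0.0
    insdel_existing: float = 0.0
    shuffle: float = 0.0

    def items(self):
        return (
            (EventCategory.SEGMENT_DUP_DEL, self.segment_dup),
            (EventCategory.REPETITION_DIFFERENCE, self.repetition),
            (EventCategory.INSDEL_NEW_DOMAIN, self.insdel_new),
            (EventCategory.INSDEL_EXISTING_DOMAIN, self.insdel_existing),
            (EventCategory.DOMAIN_SHUFFLING, self.shuffle),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic two-species comparison.

    Event rates reflect the empirically dominant event spectrum — mostly
    new-domain insertion/deletion and repetition differences, with segment
    duplication and shuffling rare — and are three-fold elevated on
    post-duplication and pre-speciation branches relative to speciation
    branches.
    """

    seed: int = 0
    n_clusters: int = 150  # rounded down to an even sister-pair count
    species: tuple[str, str] = ("speciesA", "speciesB")
    duplication_prob: float = 0.3
    ortholog_rates: EventRates = field(
        default_factory=lambda: EventRates(0.01, 0.06, 0.08, 0.02, 0.01)
    )
    paralog_rates: EventRates = field(
        default_factory=lambda: EventRates(0.03, 0.18, 0.24, 0.06, 0.03)
    )
    alphabet_size: int = 40
    n_clans: int = 8
    clan_density: float = 0.2
    repeat_fraction: float = 0.25
    arch_length_mean: float = 1.5  # ancestral units = 2 + Poisson(mean)
    cluster_age_range: tuple[float, float] = (0.05, 0.40)
    dup_divergence_range: tuple[float, float] = (0.02, 0.12)
    outparalog_divergence_range: tuple[float, float] = (0.08, 0.30)
    seq_length: int = 300
    #: cap on events per cluster; 1 gives non-confounding single-event
    #: histories where annotation recovery can be checked cleanly
    max_events_per_cluster: int | None = None

    def __post_init__(self) -> None:
        for _, r in itertools.chain(self.ortholog_rates.items(), self.paralog_rates.items()):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        if not 0 <= self.duplication_prob <= 1:
            raise ValueError("duplication_prob must be in [0, 1]")
        if self.alphabet_size < 2:
            raise ValueError("alphabet must have >= 2 families")


@dataclass(frozen=True)
class _Unit:
    uid: int
    label: str
    accession: str
    type_class: str
    run_length: int = 1


@dataclass(frozen=True)
class TrueEvent:
    cluster_id: str
    branch_id: str
    category: EventCategory
    affected_uids: frozenset[int]


@dataclass
class GroundTruth:
    proteins: dict[str, list[_Unit]] = field(default_factory=dict)
    events: list[TrueEvent] = field(default_factory=list)
    pair_branches: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    pair_p_distance: dict[tuple[str, str], float] = field(default_factory=dict)

    def uid_index(self, protein_id: str) -> dict[int, int]:
        return {u.uid: i for i, u in enumerate(self.proteins[protein_id])}

    def events_for_pair(self, p1: str, p2: str) -> list[TrueEvent]:
        branches = set(self.pair_branches.get(tuple(sorted((p1, p2))), ()))
        return [e for e in self.events if e.branch_id in branches]


class _Sim:
    """One simulation run; deterministic for a given config."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self._uid = itertools.count()
        self._fresh_acc = itertools.count(90000)
        # global family alphabet: accession -> (type_class, clan or None)
        self.accessions = [f"PF{i + 1:05d}" for i in range(config.alphabet_size)]
        self.type_of = {
            acc: ("Repeat" if self.rng.random() < config.repeat_fraction else "Family")
            for acc in self.accessions
        }
        self.clan_map = {
            acc: f"CL{int(self.rng.integers(1, config.n_clans + 1)):04d}"
            for acc in self.accessions
            if self.rng.random() < config.clan_density
        }

    def label_of(self, acc: str) -> str:
        return self.clan_map.get(acc, acc)

    # ---- architecture machinery -------------------------------------

    def ancestral_architecture(self) -> list[_Unit]:
        n = 2 + int(self.rng.poisson(self.cfg.arch_length_mean))
        units: list[_Unit] = []
        used_labels: set[str] = set()
        tries = 0
        while len(units) < n and tries < 20 * n:
            tries += 1
            acc = str(self.rng.choice(self.accessions))
            label = self.label_of(acc)
            if label in used_labels:  # distinct labels keep events separable
                continue
            used_labels.add(label)
            tc = self.type_of[acc]
            run = int(self.rng.integers(2, 5)) if tc == "Repeat" else 1
            units.append(_Unit(next(self._uid), label, acc, tc, run))
        return units

    def _clone(self, u: _Unit) -> _Unit:
        return _Unit(next(self._uid), u.label, u.accession, u.type_class, u.run_length)

    def apply_event(
        self, units: list[_Unit], category: EventCategory
    ) -> tuple[list[_Unit], frozenset[int]] | None:
        """Apply one event; None when it is impossible on this architecture."""
        rng = self.rng
        labels = [u.label for u in units]
        if category is EventCategory.SEGMENT_DUP_DEL:
            cand = [i for i in range(len(units) - 1) if labels[i] != labels[i + 1]]
            if not cand:
                return None
            i = int(rng.choice(cand))
            c1, c2 = self._clone(units[i]), self._clone(units[i + 1])
            new = units[: i + 2] + [c1, c2] + units[i + 2 :]
            return new, frozenset({units[i].uid, units[i + 1].uid, c1.uid, c2.uid})
        if category is EventCategory.REPETITION_DIFFERENCE:
            cand = [i for i, u in enumerate(units) if u.type_class in ("Family", "Domain")]
            if not cand:
                return None
            i = int(rng.choice(cand))
            copy = self._clone(units[i])
            new = units[: i + 1] + [copy] + units[i + 1 :]
            return new, frozenset({units[i].uid, copy.uid})
        if category is EventCategory.INSDEL_NEW_DOMAIN:
            acc = f"PF{next(self._fresh_acc):05d}"
            unit = _Unit(next(self._uid), acc, acc, "Family", 1)
            p = int(rng.integers(0, len(units) + 1))
            return units[:p] + [unit] + units[p:], frozenset({unit.uid})
        if category is EventCategory.INSDEL_EXISTING_DOMAIN:
            src = units[int(rng.integers(0, len(units)))]
            positions = [
                p
                for p in range(len(units) + 1)
                if (p == 0 or labels[p - 1] != src.label)
                and (p == len(units) or labels[p] != src.label)
            ]
            if not positions:
                return None
            p = int(rng.choice(positions))
            copy = self._clone(src)
            affected = {copy.uid} | {u.uid for u in units if u.label == src.label}
            return units[:p] + [copy] + units[p:], frozenset(affected)
        if category is EventCategory.DOMAIN_SHUFFLING:
            cand = [i for i in range(len(units) - 1) if labels[i] != labels[i + 1]]
            if not cand:
                return None
            i = int(rng.choice(cand))
            new = list(units)
            new[i], new[i + 1] = new[i + 1], new[i]
            return new, frozenset({units[i].uid, units[i + 1].uid})
        raise ValueError(category)

    def evolve_branch(
        self, units: list[_Unit], rates: EventRates, cluster_id: str, branch_id: str,
        truth: GroundTruth,
    ) -> list[_Unit]:
        categories = [c for c, r in rates.items() if self.rng.random() < r]
        cap = self.cfg.max_events_per_cluster
        for category in categories:
            if cap is not None:
                applied = sum(1 for e in truth.events if e.cluster_id == cluster_id)
                if applied >= cap:
                    break
            result = self.apply_event(units, category)
            if result is None:
                logger.debug("%s: %s impossible on %d-unit architecture; skipped",
                             branch_id, category, len(units))
                continue
            units, affected = result
            truth.events.append(TrueEvent(cluster_id, branch_id, category, affected))
        return units

    # ---- sequence / score emulation ---------------------------------

    def aligned_pair(self, d: float) -> tuple[str, str]:
        L = self.cfg.seq_length
        s1 = self.rng.choice(AMINO_ACIDS, size=L)
        s2 = s1.copy()
        n_diff = int(self.rng.binomial(L, d))
        pos = self.rng.choice(L, size=n_diff, replace=False)
        for p in pos:
            choices = AMINO_ACIDS[AMINO_ACIDS != s1[p]]
            s2[p] = self.rng.choice(choices)
        return "".join(s1), "".join(s2)

    def bits_for(self, d: float) -> float:
        return float(max(25.0, round(600.0 * (1.0 - d) + self.rng.normal(0.0, 15.0), 1)))


def simulate(config: SimulationConfig) -> "SimulatedDataset":
    """Generate one synthetic two-species dataset with ground truth."""
    sim = _Sim(config)
    rng = sim.rng
    cfg = config
    truth = GroundTruth()
    sp_a, sp_b = cfg.species

    clusters: list[OrthologCluster] = []
    cluster_proteins: dict[str, dict[str, list[str]]] = {}
    sister_of: dict[str, str] = {}
    protein_units: dict[str, list[_Unit]] = {}
    dup_branch: dict[str, str | None] = {}  # protein -> its duplication branch id
    spec_branch: dict[str, str] = {}  # protein -> its speciation branch id
    out_branch: dict[str, str] = {}  # protein -> its pre-speciation branch id
    branch_d: dict[str, float] = {}

    n_families = cfg.n_clusters // 2
    cluster_counter = itertools.count(1)
    for fam in range(n_families):
        fam_anc = sim.ancestral_architecture()
        fam_age = rng.uniform(*cfg.cluster_age_range)
        cids = [f"C{next(cluster_counter):04d}" for _ in range(2)]
        sister_of[cids[0]], sister_of[cids[1]] = cids[1], cids[0]
        for cid in cids:
            ob = f"{cid}:outparalog"
            branch_d[ob] = rng.uniform(*cfg.outparalog_divergence_range)
            gene_anc = sim.evolve_branch(list(fam_anc), cfg.paralog_rates, cid, ob, truth)
            members: dict[str, list[str]] = {sp_a: [], sp_b: []}
            for sp in (sp_a, sp_b):
                sb = f"{cid}:{sp}:speciation"
                branch_d[sb] = fam_age * rng.uniform(0.8, 1.2)
                sp_anc = sim.evolve_branch(list(gene_anc), cfg.ortholog_rates, cid, sb, truth)
                n_copies = 2 if rng.random() < cfg.duplication_prob else 1
                for k in range(1, n_copies + 1):
                    pid = f"{cid}_{sp}_{k}"
                    if n_copies == 1:
                        units, db = list(sp_anc), None
                    else:
                        db = f"{cid}:{sp}:dup{k}"
                        branch_d[db] = rng.uniform(*cfg.dup_divergence_range)
                        units = sim.evolve_branch(list(sp_anc), cfg.paralog_rates, cid, db, truth)
                    protein_units[pid] = units
                    dup_branch[pid] = db
                    spec_branch[pid] = sb
                    out_branch[pid] = ob
                    members[sp].append(pid)
            seed_pair = tuple(sorted((members[sp_a][0], members[sp_b][0])))
            clusters.append(
                OrthologCluster(
                    cid,
                    tuple((p, sp) for sp in (sp_a, sp_b) for p in members[sp]),
                    seed_pair,
                )
            )
            cluster_proteins[cid] = members

    truth.proteins = protein_units

    # pairs needing sequences/scores: within-cluster pairs plus all pairs
    # between sister-cluster members (the outparalog candidate pool)
    def path(p1: str, p2: str) -> tuple[str, ...]:
        same_cluster = p1.split("_")[0] == p2.split("_")[0]
        branches: list[str] = []
        for p in (p1, p2):
            if dup_branch[p]:
                branches.append(dup_branch[p])
        if p1.split("_")[1] != p2.split("_")[1] or not same_cluster:
            branches.append(spec_branch[p1])
            branches.append(spec_branch[p2])
        if not same_cluster:
            branches.append(out_branch[p1])
            branches.append(out_branch[p2])
        # same species, same cluster: only the duplication branches differ
        if p1.split("_")[1] == p2.split("_")[1] and same_cluster:
            branches = [b for b in (dup_branch[p1], dup_branch[p2]) if b]
        return tuple(dict.fromkeys(branches))

    wanted_pairs: set[tuple[str, str]] = set()
    for c in clusters:
        members = [p for p, _ in c.members]
        for p1, p2 in itertools.combinations(sorted(members), 2):
            wanted_pairs.add((p1, p2))
        sister = cluster_proteins[sister_of[c.cluster_id]]
        own = cluster_proteins[c.cluster_id]
        for p1 in own[sp_a] + own[sp_b]:
            for p2 in sister[sp_a] + sister[sp_b]:
                wanted_pairs.add(tuple(sorted((p1, p2))))

    aligned_pairs: list[tuple[str, str, str, str]] = []
    score_entries: list[tuple[str, str, float]] = []
    for p1, p2 in sorted(wanted_pairs):
        branches = path(p1, p2)
        d = min(JC_CAP, sum(branch_d[b] for b in branches))
        truth.pair_branches[(p1, p2)] = branches
        s1, s2 = sim.aligned_pair(d)
        truth.pair_p_distance[(p1, p2)] = d
        aligned_pairs.append((p1, s1, p2, s2))
        score_entries.append((p1, p2, sim.bits_for(d)))

    hits = _emit_hits(protein_units)
    return SimulatedDataset(
        config=config,
        hits=hits,
        clan_map=dict(sim.clan_map),
        clusters=clusters,
        score_entries=score_entries,
        aligned_pairs=aligned_pairs,
        truth=truth,
    )


def _emit_hits(protein_units: dict[str, list[_Unit]]) -> list[DomainHit]:
    """Expand units into raw domain hits; collapsed Repeat/Motif units emit
    ``run_length`` consecutive hits so architecture building round-trips."""
    hits: list[DomainHit] = []
    for pid in sorted(protein_units):
        pos = 1
        for unit in protein_units[pid]:
            for _ in range(unit.run_length):
                start, end = pos, pos + 79
                hits.append(DomainHit(pid, unit.accession, start, end, unit.type_class))
                pos = end + 6
        # intervening linker before next protein irrelevant; coordinates are per protein
    return hits


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    hits: list[DomainHit]
    clan_map: dict[str, str]
    clusters: list[OrthologCluster]
    score_entries: list[tuple[str, str, float]]
    aligned_pairs: list[tuple[str, str, str, str]]
    truth: GroundTruth

    @property
    def species_of(self) -> dict[str, str]:
        return {pid: sp for c in self.clusters for pid, sp in c.members}

    def write(self, outdir) -> dict[str, Path]:
        """Write the five input files; returns their paths."""
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hits": outdir / "hits.tsv",
            "clans": outdir / "clans.tsv",
            "clusters": outdir / "clusters.tsv",
            "scores": outdir / "scores.tsv",
            "alignments": outdir / "aligned_pairs.fasta",
        }
        io.write_hits(paths["hits"], self.hits)
        io.write_clan_map(paths["clans"], self.clan_map)
        io.write_clusters(paths["clusters"], self.clusters)
        io.write_scores(paths["scores"], self.score_entries)
        io.write_aligned_pairs(paths["alignments"], self.aligned_pairs)
        return paths


def recovery_report(
    truth: GroundTruth,
    annotations_by_pair: dict[tuple[str, str], list[EventAnnotation]],
) -> dict[EventCategory, float]:
    """Fraction of introduced events recovered with their true category.

    An event counts as recovered for a pair when at least one of its
    affected units (located by unit identity in either protein of the pair)
    carries an annotation of the true category.
    """
    totals: dict[EventCategory, int] = {}
    hits: dict[EventCategory, int] = {}
    for (p1, p2), annotations in annotations_by_pair.items():
        if p1 not in truth.proteins or p2 not in truth.proteins:
            raise ValueError(f"unknown proteins in pair ({p1}, {p2})")
        idx = {1: truth.uid_index(p1), 2: truth.uid_index(p2)}
        ann_at = {(a.protein, a.unit_index): a.category for a in annotations}
        for event in truth.events_for_pair(p1, p2):
            totals[event.category] = totals.get(event.category, 0) + 1
            recovered = any(
                ann_at.get((side, idx[side][uid])) == event.category
                for side in (1, 2)
                for uid in event.affected_uids
                if uid in idx[side]
            )
            if recovered:
                hits[event.category] = hits.get(event.category, 0) + 1
    return {cat: hits.get(cat, 0) / n for cat, n in totals.items()}
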
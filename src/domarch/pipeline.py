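"""End-to-end orchestration: score, annotate, and compare stages.

The comparison stage reproduces the study design at whatever scale the
inputs provide: enumerate the four homolog pair categories from ortholog
clusters, score every pair's architecture conservation (DA-score) and
sequence divergence (Jukes-Cantor distance), aggregate as means of
per-cluster means, annotate domain-swapping events, and contrast pair
categories within divergence bins using permutation tests.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import CostScheme
from .binstats import BinComparison, BinningConfig, ChiSquareResult, binned_comparison, chi2_homogeneity
from .compare import SimilarityClass, compare_pair
from .divergence import jukes_cantor, p_distance
from .events import ChangeEvent, EventCategory, annotate_events, group_into_events, position_bias_summary
from .model import Architecture, ClanMap, build_architectures
from .pairs import (
    HomologPair,
    OrthologCluster,
    OutparalogCutoffs,
    ScoreTable,
    all_pairs,
    mean_of_cluster_means,
    split_one_to_one,
)

__all__ = ["RunConfig", "ComparisonResult", "score_pairs", "annotate_pairs", "run_comparison"]

logger = logging.getLogger(__name__)

#: Event rows kept in the chi-square homogeneity test; segment duplication
#: and shuffling are too rare for reliable expected counts.
CHI2_EVENT_ROWS = (
    str(EventCategory.REPETITION_DIFFERENCE),
    str(EventCategory.INSDEL_NEW_DOMAIN),
    str(EventCategory.INSDEL_EXISTING_DOMAIN),
)
CHI2_CLASS_ROWS = (
    str(SimilarityClass.IDENTICAL),
    str(SimilarityClass.SAME_CONTENT_NOT_ALIGNED),
    str(SimilarityClass.DIFF_CONTENT),
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline defaults mirror the published analysis parameters."""

    costs: CostScheme = field(default_factory=CostScheme)
    cutoffs: OutparalogCutoffs = field(default_factory=OutparalogCutoffs)
    n_bins: int = 10
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0


def divergences_from_alignments(
    aligned_pairs: list[tuple[str, str, str, str]],
) -> dict[tuple[str, str], float]:
    """Jukes-Cantor distance per pair from pairwise aligned sequences."""
    out = {}
    for id1, seq1, id2, seq2 in aligned_pairs:
        _, d = p_distance(seq1, seq2)
        out[tuple(sorted((id1, id2)))] = jukes_cantor(d)
    return out


def score_pairs(
    architectures: dict[str, Architecture],
    pairs: list[tuple[str, str]],
    costs: CostScheme | None = None,
) -> pd.DataFrame:
    """Pair report: one row per scorable pair (both proteins must have
    at least one domain; others are skipped with a logged count)."""
    rows, skipped = [], 0
    for p1, p2 in pairs:
        if p1 not in architectures or p2 not in architectures:
            skipped += 1
            continue
        result, _ = compare_pair(architectures[p1], architectures[p2], costs)
        rows.append(
            (p1, p2, result.n1, result.n2, result.a12, result.da_score,
             str(result.similarity_class))
        )
    if skipped:
        logger.info("skipped %d pairs with zero-domain proteins", skipped)
    return pd.DataFrame(
        rows,
        columns=["protein_1", "protein_2", "n1", "n2", "a12", "da_score", "similarity_class"],
    )


def annotate_pairs(
    architectures: dict[str, Architecture],
    pairs: list[tuple[str, str]],
    costs: CostScheme | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list]]:
    """Events TSV rows for all annotatable pairs.

    Identical and NoShared pairs are silently skipped — they carry no
    unaligned shared-content differences to explain.
    """
    rows = []
    by_pair: dict[tuple[str, str], list] = {}
    for p1, p2 in pairs:
        if p1 not in architectures or p2 not in architectures:
            continue
        result, al = compare_pair(architectures[p1], architectures[p2], costs)
        if result.similarity_class in (SimilarityClass.IDENTICAL, SimilarityClass.NO_SHARED):
            continue
        anns = annotate_events(architectures[p1], architectures[p2], al)
        by_pair[tuple(sorted((p1, p2)))] = anns
        for a in anns:
            rows.append(
                (p1, p2, a.protein, a.unit_index, a.label, str(a.category), str(a.position))
            )
    df = pd.DataFrame(
        rows,
        columns=["protein_1", "protein_2", "protein", "unit_index", "label", "category", "position"],
    )
    return df, by_pair


@dataclass
class ComparisonResult:
    pair_table: pd.DataFrame  # one row per scored pair, all categories
    type_means: dict[str, float]  # mean-of-cluster-means DA per pair type
    one_to_one: dict[str, dict[str, float]]  # O pairs split 1-1 vs duplicated
    class_counts: pd.DataFrame  # similarity class x pair type
    event_counts: pd.DataFrame  # event category x pair type
    class_chi2: ChiSquareResult | None
    event_chi2: ChiSquareResult | None
    position_bias: dict[str, dict[str, float]]  # per pair type
    bin_comparisons: dict[str, BinComparison]  # e.g. "O_vs_oPx"

    def bin_report(self, key: str) -> pd.DataFrame:
        cat_a, cat_b = key.split("_vs_")
        bc = self.bin_comparisons[key]
        return pd.DataFrame(
            [
                {
                    "bin": b.index,
                    "lower": b.lower,
                    "upper": b.upper,
                    f"n_clusters_{cat_a}": b.count_a,
                    f"n_clusters_{cat_b}": b.count_b,
                    f"mean_djc_{cat_a}": b.mean_binvar_a,
                    f"mean_djc_{cat_b}": b.mean_binvar_b,
                    f"mean_da_{cat_a}": b.mean_score_a,
                    f"mean_da_{cat_b}": b.mean_score_b,
                    "raw_p": b.raw_p,
                    "significant": b.significant,
                    "skipped": b.skipped,
                }
                for b in bc.bins
            ]
        )

    def write(self, outdir) -> dict[str, Path]:
        from .io import write_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["pairs"] = outdir / "pair_report.tsv"
        write_tsv(paths["pairs"], self.pair_table)
        paths["type_means"] = outdir / "type_means.tsv"
        write_tsv(
            paths["type_means"],
            pd.DataFrame(
                sorted(self.type_means.items()), columns=["pair_type", "mean_da_score"]
            ),
        )
        paths["classes"] = outdir / "class_counts.tsv"
        write_tsv(paths["classes"], self.class_counts.reset_index())
        paths["events"] = outdir / "event_counts.tsv"
        write_tsv(paths["events"], self.event_counts.reset_index())
        pos_rows = [
            {"pair_type": t, **fractions} for t, fractions in self.position_bias.items()
        ]
        paths["position_bias"] = outdir / "position_bias.tsv"
        write_tsv(paths["position_bias"], pd.DataFrame(pos_rows))
        for key in self.bin_comparisons:
            paths[f"bins_{key}"] = outdir / f"bin_report_{key}.tsv"
            write_tsv(paths[f"bins_{key}"], self.bin_report(key))
        return paths


def _cluster_points(
    pairs: list[HomologPair],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster (mean divergence, mean DA) points for one pair type."""
    div: dict[str, list[float]] = defaultdict(list)
    da: dict[str, list[float]] = defaultdict(list)
    for p in pairs:
        if p.da_score is None or p.divergence is None:
            continue
        for cid in p.cluster_ids:
            div[cid].append(p.divergence)
            da[cid].append(p.da_score)
    cids = sorted(div)
    return (
        np.array([np.mean(div[c]) for c in cids]),
        np.array([np.mean(da[c]) for c in cids]),
    )


def run_comparison(
    architectures: dict[str, Architecture],
    clusters: list[OrthologCluster],
    scores: ScoreTable,
    divergences: dict[tuple[str, str], float],
    config: RunConfig | None = None,
    species_of: dict[str, str] | None = None,
) -> ComparisonResult:
    """Full pair-category comparison on one two-species dataset."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    pairs_by_type = all_pairs(clusters, scores, species_of, config.cutoffs)

    # score, classify and attach divergence to every pair
    scored: dict[str, list[HomologPair]] = {}
    rows = []
    missing_div = 0
    for ptype, pairs in pairs_by_type.items():
        kept = []
        for pair in pairs:
            a1 = architectures.get(pair.protein_1)
            a2 = architectures.get(pair.protein_2)
            if a1 is None or a2 is None:
                continue
            result, _ = compare_pair(a1, a2, config.costs)
            div = divergences.get(pair.key)
            if div is None:
                missing_div += 1
            pair = pair.with_scores(
                da_score=result.da_score,
                similarity_class=str(result.similarity_class),
                divergence=div,
            )
            kept.append(pair)
            rows.append(
                (pair.protein_1, pair.protein_2, ptype, ";".join(pair.cluster_ids),
                 result.n1, result.n2, result.a12, result.da_score,
                 str(result.similarity_class), div)
            )
        scored[ptype] = kept
    if missing_div:
        logger.info("%d pairs lack divergence values; excluded from binning", missing_div)
    pair_table = pd.DataFrame(
        rows,
        columns=["protein_1", "protein_2", "pair_type", "cluster_ids", "n1", "n2",
                 "a12", "da_score", "similarity_class", "divergence"],
    )

    # aggregate DA as mean of cluster means
    type_means = {}
    for ptype, pairs in scored.items():
        agg, _ = mean_of_cluster_means(pairs)
        if agg is not None:
            type_means[ptype] = agg

    # O pairs from 1-1 vs duplicated clusters
    ones, _ = split_one_to_one(clusters)
    one_ids = {c.cluster_id for c in ones}
    one_to_one = {}
    for name in ("1-1", "duplicated"):
        subset = [
            p
            for p in scored["O"]
            if (p.cluster_ids[0] in one_ids) == (name == "1-1")
        ]
        agg, _ = mean_of_cluster_means(subset)
        if agg is None:
            continue
        ident = [p for p in subset if p.similarity_class == str(SimilarityClass.IDENTICAL)]
        one_to_one[name] = {
            "mean_da_score": agg,
            "fraction_identical": len(ident) / len(subset),
            "n_pairs": len(subset),
        }

    # similarity class distribution per pair type
    class_counts = pd.DataFrame(
        {
            ptype: pair_table[pair_table.pair_type == ptype]
            .similarity_class.value_counts()
            for ptype in scored
        }
    ).reindex([str(c) for c in SimilarityClass]).fillna(0).astype(int)
    class_counts.index.name = "similarity_class"

    # event annotation for annotatable pairs, per pair type
    event_rows: dict[str, dict[str, int]] = {}
    events_by_type_cluster: dict[str, dict[str, list[ChangeEvent]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for ptype, pairs in scored.items():
        counts: dict[str, int] = defaultdict(int)
        for pair in pairs:
            if pair.similarity_class in (
                str(SimilarityClass.IDENTICAL),
                str(SimilarityClass.NO_SHARED),
            ):
                continue
            a1 = architectures[pair.protein_1]
            a2 = architectures[pair.protein_2]
            _, al = compare_pair(a1, a2, config.costs)
            events = group_into_events(annotate_events(a1, a2, al))
            for ev in events:
                counts[str(ev.category)] += 1
                for cid in pair.cluster_ids:
                    events_by_type_cluster[ptype][cid].append(ev)
        event_rows[ptype] = dict(counts)
    event_counts = pd.DataFrame(event_rows).reindex(
        [str(c) for c in EventCategory]
    ).fillna(0).astype(int)
    event_counts.index.name = "category"

    # chi-square homogeneity O vs oPx, sparse rows excluded
    class_chi2 = event_chi2 = None
    if {"O", "oPx"} <= set(class_counts.columns):
        table = class_counts.loc[list(CHI2_CLASS_ROWS), ["O", "oPx"]]
        if (table.sum(axis=0) > 0).all():
            class_chi2 = chi2_homogeneity(table.to_numpy())
        etable = event_counts.loc[list(CHI2_EVENT_ROWS), ["O", "oPx"]]
        if (etable.sum(axis=0) > 0).all():
            event_chi2 = chi2_homogeneity(etable.to_numpy())

    position_bias = {
        ptype: position_bias_summary(by_cluster)
        for ptype, by_cluster in events_by_type_cluster.items()
    }

    # divergence-binned comparisons on per-cluster mean points
    bin_cfg = BinningConfig(n_bins=config.n_bins)
    bin_comparisons: dict[str, BinComparison] = {}
    for cat_a, cat_b in (("O", "oPx"), ("iP", "oPs"), ("O", "iP")):
        va, sa = _cluster_points(scored.get(cat_a, []))
        vb, sb = _cluster_points(scored.get(cat_b, []))
        if len(va) < config.n_bins or len(vb) < config.n_bins:
            continue
        bin_comparisons[f"{cat_a}_vs_{cat_b}"] = binned_comparison(
            va, sa, vb, sb, bin_cfg, n_perm=config.n_perm, alpha=config.alpha, rng=rng
        )

    return ComparisonResult(
        pair_table=pair_table,
        type_means=type_means,
        one_to_one=one_to_one,
        class_counts=class_counts,
        event_counts=event_counts,
        class_chi2=class_chi2,
        event_chi2=event_chi2,
        position_bias=position_bias,
        bin_comparisons=bin_comparisons,
    )


def run_comparison_from_files(
    hits_path, clans_path, clusters_path, scores_path, alignments_path,
    config: RunConfig | None = None,
) -> ComparisonResult:
    """File-level entry point used by the command-line interface."""
    from . import io
    from .model import load_clan_map
    from .pairs import parse_clusters

    clans = load_clan_map(clans_path)
    hits = io.read_hits(hits_path)
    architectures = build_architectures(hits, clans)
    clusters = parse_clusters(clusters_path)
    scores = io.read_scores(scores_path)
    divergences = divergences_from_alignments(io.read_aligned_pairs(alignments_path))
    return run_comparison(architectures, clusters, scores, divergences, config)
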
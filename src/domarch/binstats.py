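"""Divergence-binned statistical comparison of two pair categories.

Implements the adaptive equal-count binning over a continuous variable
(Jukes-Cantor distance in the pipeline), a randomized permutation test for
the difference in mean score between two categories within each bin with
Bonferroni correction across bins, and a chi-square homogeneity variant for
comparing class/event count distributions between two pair types.

Binning procedure: each category is sorted on the binning variable and cut
into N consecutive equal-count bins; the two categories' threshold sets are
averaged.  Thresholds are then refined iteratively: the smallest
bin-by-category cell is found and its thresholds are shifted to equalize it
with its neighbor bins, approximating each bin as having uniform point
density; a shift is kept only if it strictly grows the then-smallest cell.
Refinement stops on a rejected shift, or once the smallest cell holds at
least ``min_fill_fraction`` of all points, or at the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BinningConfig",
    "BinResult",
    "BinComparison",
    "ChiSquareResult",
    "adaptive_bins",
    "bin_counts",
    "permutation_test",
    "bonferroni_flags",
    "chi2_homogeneity",
    "binned_comparison",
]


@dataclass(frozen=True)
class BinningConfig:
    n_bins: int = 10
    min_fill_fraction: float = 0.01
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not 0.0 < self.min_fill_fraction < 1.0:
            raise ValueError("min_fill_fraction must be in (0, 1)")


def _equal_count_thresholds(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior thresholds cutting sorted values into equal-count bins."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < n_bins:
        raise ValueError(f"category has {n} points, fewer than {n_bins} bins")
    cuts = np.array([round(j * n / n_bins) for j in range(1, n_bins)], dtype=int)
    cuts = np.clip(cuts, 1, n - 1)
    return (x[cuts - 1] + x[cuts]) / 2.0


def bin_counts(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Per-bin counts; bin i is (t[i-1], t[i]] with open outer edges."""
    idx = np.searchsorted(thresholds, np.asarray(values, dtype=float), side="left")
    return np.bincount(idx, minlength=len(thresholds) + 1)


def _bin_widths(thresholds: np.ndarray, lo: float, hi: float) -> np.ndarray:
    edges = np.concatenate(([lo], thresholds, [hi]))
    return np.diff(edges)


def adaptive_bins(
    values_a: Sequence[float], values_b: Sequence[float], cfg: BinningConfig
) -> np.ndarray:
    """Interior bin thresholds (length ``n_bins - 1``, non-decreasing)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_bins = cfg.n_bins
    thresholds = (_equal_count_thresholds(a, n_bins) + _equal_count_thresholds(b, n_bins)) / 2.0
    total = len(a) + len(b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())

    counts = np.vstack([bin_counts(a, thresholds), bin_counts(b, thresholds)])
    for _ in range(cfg.max_iterations):
        smallest = counts.min()
        if smallest >= cfg.min_fill_fraction * total:
            break
        cat, i = np.unravel_index(np.argmin(counts), counts.shape)
        widths = _bin_widths(thresholds, lo, hi)
        row = counts[cat].astype(float)
        proposal = thresholds.copy()

        def density(j: int) -> float:
            return row[j] / widths[j] if widths[j] > 0 else 0.0

        feasible = True
        if 0 < i < n_bins - 1:
            target = (row[i - 1] + row[i] + row[i + 1]) / 3.0
            dl, dr = density(i - 1), density(i + 1)
            if dl <= 0 or dr <= 0:
                feasible = False
            else:
                proposal[i - 1] -= max(0.0, row[i - 1] - target) / dl
                proposal[i] += max(0.0, row[i + 1] - target) / dr
        elif i == 0:
            target = (row[0] + row[1]) / 2.0
            d = density(1)
            if d <= 0:
                feasible = False
            else:
                proposal[0] += max(0.0, row[1] - target) / d
        else:
            target = (row[i - 1] + row[i]) / 2.0
            d = density(i - 1)
            if d <= 0:
                feasible = False
            else:
                proposal[i - 1] -= max(0.0, row[i - 1] - target) / d
        if not feasible:
            break
        proposal = np.maximum.accumulate(np.clip(proposal, lo, hi))
        new_counts = np.vstack([bin_counts(a, proposal), bin_counts(b, proposal)])
        if new_counts.min() > smallest:  # strict improvement; ties reject
            thresholds, counts = proposal, new_counts
        else:
            break
    return thresholds


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    *,
    plus_one: bool = False,
) -> float:
    """Randomized permutation test for a difference in means.

    Both groups are pooled; ``n_perm`` relabelings with the original group
    sizes are drawn without replacement, and the p-value is the fraction of
    relabelings whose absolute mean difference is at least as large as the
    observed one.  ``plus_one`` switches to the (count+1)/(n_perm+1)
    estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    # chunk to bound memory for large n_perm * n
    count = 0
    chunk = max(1, min(n_perm, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        mat = rng.permuted(np.broadcast_to(pooled, (k, n)).copy(), axis=1)
        diffs = np.abs(mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1))
        count += int((diffs >= observed - 1e-12).sum())
        done += k
    if plus_one:
        return (count + 1) / (n_perm + 1)
    return count / n_perm


def bonferroni_flags(
    raw_p: Sequence[float], alpha: float = 0.05, n_tests: int | None = None
) -> list[bool]:
    """Significance flags at the Bonferroni-corrected threshold alpha/N."""
    n = n_tests if n_tests is not None else len(raw_p)
    if n < 1:
        raise ValueError("n_tests must be >= 1")
    return [p < alpha / n for p in raw_p]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    low_expected_warning: bool


def chi2_homogeneity(counts, row_names: Sequence[str] | None = None,
                     exclude_rows: Sequence[str] = ()) -> ChiSquareResult:
    """Pearson chi-square homogeneity test on an M x N count table.

    Expected counts come from the pooled marginal distribution; degrees of
    freedom are (M-1)(N-1).  ``exclude_rows`` drops named rows (by
    ``row_names``) before testing — used for sparse categories whose
    expected counts would undermine the test.  The result flags (rather
    than fails) any remaining expected cell below 5.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if exclude_rows:
        if row_names is None:
            raise ValueError("row_names required to exclude rows")
        keep = [i for i, name in enumerate(row_names) if name not in set(exclude_rows)]
        table = table[keep]
    grand = table.sum()
    if grand == 0:
        raise ValueError("zero grand total")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a column has zero total")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    statistic = float(terms.sum())
    m, k = table.shape
    dof = (m - 1) * (k - 1)
    p = float(stats.chi2.sf(statistic, dof)) if dof > 0 else 1.0
    return ChiSquareResult(statistic, dof, p, bool((expected < 5).any()))


@dataclass(frozen=True)
class BinResult:
    index: int
    lower: float
    upper: float
    count_a: int
    count_b: int
    mean_binvar_a: float
    mean_binvar_b: float
    mean_score_a: float
    mean_score_b: float
    raw_p: float
    significant: bool
    skipped: bool


@dataclass(frozen=True)
class BinComparison:
    thresholds: np.ndarray
    bins: list[BinResult] = field(default_factory=list)


def binned_comparison(
    binvar_a: Sequence[float],
    score_a: Sequence[float],
    binvar_b: Sequence[float],
    score_b: Sequence[float],
    cfg: BinningConfig | None = None,
    *,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> BinComparison:
    """Bin two categories on a shared variable and test per-bin mean scores.

    Bins where either category is empty are flagged skipped and carry no
    test.  Significance uses the Bonferroni threshold alpha / n_bins.
    """
    cfg = cfg or BinningConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    va = np.asarray(binvar_a, dtype=float)
    vb = np.asarray(binvar_b, dtype=float)
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    thresholds = adaptive_bins(va, vb, cfg)
    lo = float(min(va.min(), vb.min()))
    hi = float(max(va.max(), vb.max()))
    edges = np.concatenate(([lo], thresholds, [hi]))
    ia = np.searchsorted(thresholds, va, side="left")
    ib = np.searchsorted(thresholds, vb, side="left")
    out = BinComparison(thresholds)
    for i in range(cfg.n_bins):
        in_a, in_b = ia == i, ib == i
        ca, cb = int(in_a.sum()), int(in_b.sum())
        if ca == 0 or cb == 0:
            out.bins.append(
                BinResult(i, float(edges[i]), float(edges[i + 1]), ca, cb,
                          float(va[in_a].mean()) if ca else float("nan"),
                          float(vb[in_b].mean()) if cb else float("nan"),
                          float(sa[in_a].mean()) if ca else float("nan"),
                          float(sb[in_b].mean()) if cb else float("nan"),
                          float("nan"), False, True)
            )
            continue
        p = permutation_test(sa[in_a], sb[in_b], n_perm=n_perm, rng=rng)
        out.bins.append(
            BinResult(i, float(edges[i]), float(edges[i + 1]), ca, cb,
                      float(va[in_a].mean()), float(vb[in_b].mean()),
                      float(sa[in_a].mean()), float(sb[in_b].mean()),
                      p, p < alpha / cfg.n_bins, False)
        )
    return out
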
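"""Two-class unpaired SAM: moderated d-statistic, fudge factor, permutation FDR.

Significance Analysis of Microarrays scores each gene with a regularized
t-like statistic

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the pooled two-sample standard error of the difference and
``s0`` (the "fudge factor") is a small constant, shared across genes, that
keeps low-variance genes from dominating.  Significance is assessed against a
permutation null: group labels are permuted, the d-statistics are recomputed
and sorted, and each observed order statistic d_(i) is compared with the mean
of the corresponding permuted order statistics (the expected null quantile).
Genes whose deviation |d_(i) - dbar_(i)| exceeds a threshold delta are called;
the false discovery rate at each delta is the median number of permuted genes
exceeding the induced score cutoffs divided by the number called.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr_damage import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Fudge-factor search grid: percentiles of the per-gene standard errors.
S0_PERCENTILE_GRID: tuple[float, ...] = tuple(range(0, 101, 5))


@dataclass
class SamScores:
    """Per-gene SAM statistics plus the shared fudge factor."""

    gene_ids: list[str]
    d: np.ndarray
    numerator: np.ndarray
    s: np.ndarray
    s0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d": self.d, "numerator": self.numerator, "s": self.s, "s0": self.s0},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def _group_arrays(matrix: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.loc[matrix.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DataError(f"need exactly 2 groups, got {list(groups)}")
    # The affected/contrast group is group 2 (its mean enters the numerator
    # positively): "case" or "high" when present, else the second sorted label.
    group2 = next((g for g in ("case", "high") if g in groups), groups[1])
    mask2 = (labels == group2).to_numpy()
    return matrix.to_numpy(dtype=float), mask2


def _sam_d(
    x: np.ndarray, mask2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized numerator, pooled standard error, and d for a label assignment."""
    x2 = x[:, mask2]
    x1 = x[:, ~mask2]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError(f"each group needs >= 2 samples, got {n1} and {n2}")
    numer = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    d = np.where(s + s0 > 0, numer / np.where(s + s0 > 0, s + s0, 1.0), 0.0)
    return numer, s, d


def sam_statistic(matrix: pd.DataFrame, labels: pd.Series, s0: float) -> SamScores:
    """Compute SAM d-statistics for a two-group log-ratio matrix.

    ``labels`` maps sample id to one of two group names; the numerator is
    mean(second group in sorted label order) - mean(first), so with labels
    ``case``/``control`` positive d means higher in cases.
    """
    if s0 < 0:
        raise ConfigurationError(f"s0 must be >= 0, got {s0}")
    x, mask2 = _group_arrays(matrix, labels)
    numer, s, d = _sam_d(x, mask2, s0)
    return SamScores(list(matrix.index), d, numer, s, float(s0))


def estimate_s0(
    s: np.ndarray,
    numerators: np.ndarray,
    percentile_grid: tuple[float, ...] = S0_PERCENTILE_GRID,
    n_windows: int = 10,
) -> float:
    """Select the fudge factor minimizing the spread of d's scale across s strata.

    For each candidate s0 (a percentile of the s distribution), genes are
    binned into ``n_windows`` quantile windows of s, the median absolute
    deviation of d = numerator / (s + s0) is computed within each window, and
    the candidate minimizing the coefficient of variation of those MADs is
    chosen.  A well-chosen s0 makes the scale of d independent of s.
    """
    s = np.asarray(s, dtype=float)
    numerators = np.asarray(numerators, dtype=float)
    if s.size < 10:
        raise DataError(f"need >= 10 genes to estimate s0, got {s.size}")
    if np.all(s == 0):
        logger.warning("all per-gene standard errors are zero; s0 set to 0")
        return 0.0

    order = np.argsort(s, kind="stable")
    bounds = np.linspace(0, s.size, n_windows + 1).astype(int)
    windows = [order[bounds[i]:bounds[i + 1]] for i in range(n_windows)
               if bounds[i + 1] > bounds[i]]

    best_s0, best_cv = 0.0, math.inf
    for pct in percentile_grid:
        s0 = float(np.percentile(s, pct))
        d = numerators / (s + s0) if s0 > 0 else np.where(s > 0, numerators / np.maximum(s, 1e-300), 0.0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows])
        mean_mad = mads.mean()
        cv = mads.std(ddof=0) / mean_mad if mean_mad > 0 else math.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def _label_permutations(
    n: int, n_group2: int, n_perm: int, seed: int
) -> list[np.ndarray]:
    """Distinct group-2 index masks: exhaustive when feasible, else seeded draws."""
    total = math.comb(n, n_group2)
    if total <= n_perm:
        return [
            np.isin(np.arange(n), combo)
            for combo in itertools.combinations(range(n), n_group2)
        ]
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_group2, replace=False)
        masks.append(np.isin(np.arange(n), idx))
    return masks


@dataclass
class FdrTable:
    """SAM delta-threshold table: calls, median false positives, and FDR per delta."""

    table: pd.DataFrame  # columns: delta, n_called, median_false, fdr (fraction)
    expected_order_stats: np.ndarray
    sorted_d: np.ndarray
    sort_index: np.ndarray  # gene order of sorted_d within the score vector

    def fdr_percent(self) -> pd.DataFrame:
        out = self.table.copy()
        out["fdr_percent"] = out["fdr"] * 100.0
        return out


def permutation_fdr(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_perm: int,
    seed: int,
    s0: float | None = None,
    deltas: np.ndarray | None = None,
) -> FdrTable:
    """SAM permutation FDR table over a grid of delta thresholds.

    All distinct label permutations are used when their count is at most
    ``n_perm``; otherwise ``n_perm`` uniform seeded draws.  For each delta the
    called set is { genes with |d_(i) - dbar_(i)| >= delta } on the observed
    quantile-quantile ordering; the induced score cutoffs (smallest called
    d above the null expectation, largest called d below it) are applied to
    every permutation's d-statistics and the median count of exceedances is
    the estimated number of false calls.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    x, mask2 = _group_arrays(matrix, labels)
    numer, s, _ = _sam_d(x, mask2, 0.0)
    if s0 is None:
        s0 = estimate_s0(s, numer)
    _, _, d_obs = _sam_d(x, mask2, s0)

    masks = _label_permutations(x.shape[1], int(mask2.sum()), n_perm, seed)
    perm_d = np.empty((len(masks), x.shape[0]))
    for p, mask in enumerate(masks):
        _, _, dp = _sam_d(x, mask, s0)
        perm_d[p] = dp
    perm_sorted = np.sort(perm_d, axis=1)
    expected = perm_sorted.mean(axis=0)

    sort_index = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[sort_index]
    dev = d_sorted - expected

    if deltas is None:
        max_dev = float(np.max(np.abs(dev))) if dev.size else 0.0
        deltas = np.unique(np.concatenate([[0.0], np.abs(dev), [max_dev + 1e-6]]))

    rows = []
    for delta in np.asarray(deltas, dtype=float):
        called = np.abs(dev) >= delta
        n_called = int(called.sum())
        if n_called == 0:
            rows.append({"delta": delta, "n_called": 0, "median_false": 0.0, "fdr": 0.0})
            continue
        up = called & (dev > 0)
        down = called & (dev < 0)
        zero = called & (dev == 0)  # only at delta == 0
        cut_up = float(d_sorted[up | zero].min()) if (up | zero).any() else math.inf
        cut_low = float(d_sorted[down | zero].max()) if (down | zero).any() else -math.inf
        false_counts = ((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1)
        median_false = float(np.median(false_counts))
        rows.append({
            "delta": float(delta),
            "n_called": n_called,
            "median_false": median_false,
            "fdr": median_false / n_called,
        })
    table = pd.DataFrame(rows)
    return FdrTable(table, expected, d_sorted, sort_index)


def call_genes(
    scores: SamScores, fdr_table: FdrTable, fdr_threshold_percent: float
) -> pd.DataFrame:
    """Call differentially expressed genes at the smallest delta meeting the FDR.

    Returns a DataFrame (gene_id index) with columns ``d`` and ``direction``
    (``up``/``down`` from the sign of d); empty when no delta achieves the
    threshold.
    """
    tab = fdr_table.table
    if tab.empty:
        raise DataError("empty FDR table")
    ok = tab[tab["fdr"] * 100.0 <= fdr_threshold_percent]
    ok = ok[ok["n_called"] > 0]
    if ok.empty:
        logger.info("no delta achieves FDR <= %s%%; calling no genes", fdr_threshold_percent)
        return pd.DataFrame(columns=["d", "direction"]).rename_axis("gene_id")
    delta = float(ok["delta"].min())
    dev = fdr_table.sorted_d - fdr_table.expected_order_stats
    called_sorted = np.abs(dev) >= delta
    gene_idx = fdr_table.sort_index[called_sorted]
    gene_ids = [scores.gene_ids[i] for i in gene_idx]
    d_vals = scores.d[gene_idx]
    direction = np.where(d_vals >= 0, "up", "down")
    out = pd.DataFrame({"d": d_vals, "direction": direction},
                       index=pd.Index(gene_ids, name="gene_id"))
    return out.sort_values("d", key=np.abs, ascending=False)
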
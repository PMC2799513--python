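"""Frataxin relative quantification and clinical-covariate association.

Frataxin mRNA is quantified by TaqMan real-time PCR with the threshold-cycle
(Ct) method: each sample's delta-Ct (frataxin Ct minus reference-gene Ct) is
expressed relative to the mean delta-Ct of the control group,

    ddCt = mean(control dCt) - sample dCt,        fold = 2 ** ddCt,

so a negative ddCt means lower expression (later threshold crossing).  Patient
ddCt distributions are bimodal; a threshold (default -2.5) splits them into
high- and low-frataxin expressers.

The remaining operations relate expression and damage to clinical covariates:
ordinary least-squares univariate fits (slope p from the t-distribution on
n-2 df), Benjamini-Hochberg q-values, supervised per-gene Pearson correlation
against a covariate with a p cutoff, and a median-age dichotomization t-test
used to rule out age effects in the control group.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qpcr_damage import DataError

logger = logging.getLogger(__name__)

#: ddCt threshold separating high- from low-frataxin expressers.
EXPRESSER_THRESHOLD_DDCT = -2.5


def relative_expression(
    sample_dct: Sequence[float], control_dct: Sequence[float]
) -> pd.DataFrame:
    """ddCt and fold change of each sample relative to the control-group mean dCt.

    Returns a DataFrame with columns ``ddct`` and ``fold`` (fold = 2**ddct);
    negative ddct = lower expression than controls.
    """
    controls = np.asarray(control_dct, dtype=float)
    if controls.size == 0:
        raise DataError("control group is empty; cannot form a dCt reference")
    samples = np.asarray(sample_dct, dtype=float)
    ddct = controls.mean() - samples
    return pd.DataFrame({"ddct": ddct, "fold": np.exp2(ddct)})


def ddct_from_fold(fold: float) -> float:
    """Inverse of the fold computation: ddct = log2(fold)."""
    if fold <= 0:
        raise DataError(f"fold change must be > 0, got {fold}")
    return math.log2(fold)


def stratify_expressers(
    ddct: Sequence[float], threshold: float = EXPRESSER_THRESHOLD_DDCT
) -> np.ndarray:
    """Label samples ``high``/``low`` expresser at the ddCt threshold (ties -> low)."""
    vals = np.asarray(ddct, dtype=float)
    if not np.isfinite(vals).all():
        raise DataError("non-finite ddCt values")
    return np.where(vals > threshold, "high", "low")


def univariate_fit(x: Sequence[float], y: Sequence[float]) -> dict:
    """Ordinary least-squares fit of y on x with pairwise missing-value removal.

    Returns slope, intercept, r_squared (squared Pearson r), two-sided p for
    slope != 0, and n (pairs used).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise DataError("x and y lengths differ")
    keep = np.isfinite(xa) & np.isfinite(ya)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("univariate_fit: dropped %d incomplete pairs", dropped)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise DataError(f"need >= 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0:
        raise DataError("constant predictor: fit undefined")
    res = stats.linregress(xa, ya)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue) ** 2,
        "p": float(res.pvalue),
        "n": int(xa.size),
    }


def qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank, q >= p)."""
    pa = np.asarray(p, dtype=float)
    if pa.size == 0:
        return pa.copy()
    if np.any((pa < 0) | (pa > 1)) or not np.isfinite(pa).all():
        raise DataError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pa, method="fdr_bh")
    return q


def supervised_correlation(
    matrix: pd.DataFrame, covariate: Sequence[float], p_threshold: float = 0.01
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a covariate; return genes passing the p cutoff.

    Zero-variance gene rows are skipped with a log entry.  Returns a DataFrame
    indexed by gene id with columns ``r``, ``p``, ``direction`` (sign of r),
    restricted to p <= ``p_threshold`` and sorted by p.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.size != matrix.shape[1]:
        raise DataError("covariate must cover every sample")
    if np.ptp(cov) == 0:
        raise DataError("constant covariate")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    skip = sd == 0
    if skip.any():
        logger.info("supervised_correlation: skipped %d zero-variance genes", skip.sum())
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    cz = (cov - cov.mean()) / cov.std()
    n = cov.size
    r = xs @ cz / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame(
        {"r": r, "p": p, "direction": np.where(r >= 0, "up", "down")},
        index=matrix.index.rename("gene_id"),
    )
    out = out[~skip]
    return out[out["p"] <= p_threshold].sort_values("p")


def dichotomize_by_median_age(ages: Sequence[float]) -> np.ndarray:
    """Boolean mask of the upper age stratum; samples at the median go to the lower one."""
    a = np.asarray(ages, dtype=float)
    upper = a > np.median(a)
    if upper.all() or not upper.any():
        raise DataError("median-age split puts every sample in one stratum")
    return upper


def dichotomized_age_test(values: Sequence[float], ages: Sequence[float]) -> tuple[float, float]:
    """Equal-variance two-sample t-test of a variable across a median-age split.

    Used to check a variable (e.g. a lesion load) for age dependence within a
    group; returns ``(t, two-sided p)``.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape:
        raise DataError("values and ages lengths differ")
    upper = dichotomize_by_median_age(a)
    hi, lo = v[upper], v[~upper]
    t, p = stats.ttest_ind(hi, lo, equal_var=True)
    if math.isnan(t):  # identical constant strata
        return 0.0, 1.0
    return float(t), float(p)
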
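"""Co-expression pattern extraction by iterative profile filtering (EPIG).

Every gene profile starts as a pattern candidate.  Candidates are filtered by:

1. **Local cluster size** — the number of other profiles whose Pearson
   correlation with the candidate exceeds ``r_t``; candidates with fewer than
   ``m_t`` neighbours are dropped.
2. **Pairwise pruning** — when two surviving candidates are themselves
   correlated above ``r_t``, the one with the smaller local cluster is dropped
   (candidates are processed in descending cluster-size order, ties by gene
   id, so the larger cluster always survives).
3. **Representative profiles** — each surviving candidate is replaced by the
   standardized centroid of its local cluster.
4. **Signal quality** — representatives whose signal-to-noise ratio or
   magnitude fall below ``snr_t`` / ``magnitude_t`` are dropped.

The survivors are the extracted patterns.  Every gene is then assigned to the
pattern with which its profile correlates most strongly, or flagged an
*orphan* when that best correlation is below the assignment threshold
``r_assign``.  Patterns (or their member genes) can finally be correlated with
clinical covariates.

SNR here is the standard deviation of the group means (case/control) divided
by the pooled within-group standard deviation — a between/within contrast
measure on the representative profile.  Magnitude is the largest absolute
log2-ratio of the unstandardized centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_damage import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Sentinel SNR reported when the pooled within-group variance is exactly zero.
SNR_SENTINEL = 1e12


@dataclass(frozen=True)
class EpigParams:
    """Thresholds of the pattern-extraction filter (artifact defaults, tunable)."""

    r_t: float = 0.7          # pairwise-correlation threshold for local clustering
    m_t: int = 10             # minimum local cluster size
    snr_t: float = 1.0        # minimum signal-to-noise ratio of a representative
    magnitude_t: float = 0.5  # minimum |log2 ratio| magnitude of a representative
    r_assign: float = 0.64    # gene-to-pattern assignment threshold R

    def __post_init__(self) -> None:
        if not 0 < self.r_t < 1:
            raise ConfigurationError(f"r_t must be in (0,1), got {self.r_t}")
        if not 0 < self.r_assign < 1:
            raise ConfigurationError(f"r_assign must be in (0,1), got {self.r_assign}")
        if self.m_t < 1:
            raise ConfigurationError(f"m_t must be >= 1, got {self.m_t}")
        if self.snr_t < 0 or self.magnitude_t < 0:
            raise ConfigurationError("snr_t and magnitude_t must be >= 0")


@dataclass
class Pattern:
    """An extracted co-expression pattern."""

    id: str
    representative_profile: np.ndarray  # standardized centroid, one value per sample
    seed_gene: str
    member_seed_profiles: list[str]     # genes of the seed's local cluster
    local_cluster_size: int
    snr: float
    magnitude: float


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between rows; zero-variance rows give 0."""
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance profiles: correlations set to 0", degenerate.sum())
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    xs[degenerate] = 0.0
    corr = xs @ xs.T / x.shape[1]
    np.fill_diagonal(corr, 1.0)
    return corr


def local_cluster_size(profile: np.ndarray, all_profiles: np.ndarray, r_t: float) -> int:
    """Number of profiles correlating with ``profile`` above ``r_t`` (itself excluded)."""
    if all_profiles.shape[0] < 2:
        raise DataError("need at least 2 profiles")
    if profile.std() == 0:
        logger.warning("zero-variance profile: local cluster size counted as 0")
        return 0
    p = (profile - profile.mean()) / profile.std()
    sd = all_profiles.std(axis=1)
    xs = (all_profiles - all_profiles.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    xs[sd == 0] = 0.0
    r = xs @ p / profile.size
    # The profile itself is assumed to be one of the rows; exclude that one copy.
    is_self = (np.abs(all_profiles - profile).max(axis=1) == 0).any()
    return int((r > r_t).sum()) - (1 if is_self else 0)


def snr(profile: np.ndarray, labels: pd.Series | np.ndarray) -> float:
    """Between-group / within-group contrast of a profile.

    Standard deviation (ddof=1) of the per-group means divided by the pooled
    within-group standard deviation.  With a single group, falls back to
    |mean| / sd of the profile.  A zero within-group variance yields a large
    sentinel value with a warning.
    """
    labels = np.asarray(labels)
    profile = np.asarray(profile, dtype=float)
    groups = np.unique(labels)
    if len(groups) < 2:
        logger.warning("single group: SNR falls back to |mean|/sd of the profile")
        sd_all = profile.std(ddof=1)
        return abs(profile.mean()) / sd_all if sd_all > 0 else SNR_SENTINEL
    means, ss, dof = [], 0.0, 0
    for g in groups:
        vals = profile[labels == g]
        if vals.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
        means.append(vals.mean())
        ss += ((vals - vals.mean()) ** 2).sum()
        dof += vals.size - 1
    sd_means = float(np.std(means, ddof=1))
    within = math.sqrt(ss / dof)
    if within == 0:
        logger.warning("zero within-group variance: SNR reported as sentinel %g", SNR_SENTINEL)
        return SNR_SENTINEL if sd_means > 0 else 0.0
    return sd_means / within


def extract_patterns(
    matrix: pd.DataFrame, params: EpigParams, labels: pd.Series
) -> list[Pattern]:
    """Run the full candidate-filtering cascade and return the extracted patterns."""
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < params.m_t:
        raise DataError(f"matrix has {x.shape[0]} profiles, fewer than m_t={params.m_t}")
    gene_ids = list(matrix.index)
    labels = labels.loc[matrix.columns]

    corr = _correlation_matrix(x)
    neighbour = corr > params.r_t
    np.fill_diagonal(neighbour, False)
    sizes = neighbour.sum(axis=1)

    # Filter 1: minimum local cluster size.
    candidates = np.flatnonzero(sizes >= params.m_t)
    # Filter 2: greedy pairwise pruning, largest cluster first (ties by gene id).
    order = sorted(candidates, key=lambda i: (-sizes[i], gene_ids[i]))
    leaders: list[int] = []
    for i in order:
        if all(not neighbour[i, j] for j in leaders):
            leaders.append(i)

    patterns: list[Pattern] = []
    for i in leaders:
        cluster = np.flatnonzero(neighbour[i] | (np.arange(len(gene_ids)) == i))
        centroid = x[cluster].mean(axis=0)
        magnitude = float(np.abs(centroid).max())
        sd = centroid.std()
        rep = (centroid - centroid.mean()) / sd if sd > 0 else centroid - centroid.mean()
        pattern_snr = snr(centroid, labels)
        if pattern_snr < params.snr_t or magnitude < params.magnitude_t:
            continue
        patterns.append(Pattern(
            id=f"P{len(patterns)+1}",
            representative_profile=rep,
            seed_gene=gene_ids[i],
            member_seed_profiles=[gene_ids[j] for j in cluster],
            local_cluster_size=int(sizes[i]),
            snr=pattern_snr,
            magnitude=magnitude,
        ))
    if not patterns:
        logger.info("no patterns survive the filtering cascade")
    return patterns


def assign_genes(
    matrix: pd.DataFrame, patterns: list[Pattern], r_assign: float
) -> pd.DataFrame:
    """Assign each gene to its best-correlated pattern; orphan below ``r_assign``.

    Ties between patterns break to the lowest pattern id.  Returns a DataFrame
    indexed by gene id with columns ``pattern`` (pattern id or ``"orphan"``)
    and ``r`` (the best correlation).
    """
    if not patterns:
        raise DataError("no patterns to assign genes to")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    xs[sd == 0] = 0.0
    reps = np.stack([p.representative_profile for p in patterns])
    rsd = reps.std(axis=1)
    reps_s = (reps - reps.mean(axis=1, keepdims=True)) / np.where(rsd > 0, rsd, 1.0)[:, None]
    r = xs @ reps_s.T / x.shape[1]  # genes x patterns

    best = r.argmax(axis=1)  # argmax takes the first (lowest pattern id) on ties
    best_r = r[np.arange(r.shape[0]), best]
    assigned = np.where(best_r >= r_assign, [patterns[j].id for j in best], "orphan")
    return pd.DataFrame(
        {"pattern": assigned, "r": best_r},
        index=pd.Index(matrix.index, name="gene_id"),
    )


def correlate_pattern_covariate(
    profile: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a pattern profile with a clinical covariate.

    Returns ``(r, p)`` with the two-sided p from the t-distribution on n-2
    degrees of freedom.
    """
    profile = np.asarray(profile, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if profile.shape != covariate.shape:
        raise DataError("profile and covariate lengths differ")
    if np.ptp(covariate) == 0:
        raise DataError("constant covariate: correlation undefined")
    if np.ptp(profile) == 0:
        raise DataError("constant profile: correlation undefined")
    r, p = stats.pearsonr(profile, covariate)
    return float(r), float(p)
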
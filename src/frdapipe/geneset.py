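"""Gene-set scoring, enrichment, and consensus-signature construction.

Gene Set Analysis (GSA) scores a set with the **maxmean** statistic: split the
member genes' scores into positive and negative parts, average each over the
whole set, and keep whichever average is larger in absolute value (signed).
The observed maxmean is *restandardized* — centered and scaled by the mean and
standard deviation of maxmean over random gene sets of the same size drawn
from all genes (row randomization) — and compared with the same quantity
computed under sample-label permutations to yield a p-value.  Restandardization
protects against catalogs whose genes are globally shifted.

Around GSA this module provides: the upper-tail hypergeometric probability for
cross-cohort overlap tests, the right-tailed Fisher's exact test for set
enrichment in a hit list, the direction-matched intersection of two signed
gene lists, and the consensus signature — genes present in at least a fixed
fraction (default 25%) of a collection of significant sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import _group_arrays, _sam_d, estimate_s0, _label_permutations
from .qpcr_damage import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Named gene sets over a common gene universe."""

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = sorted({g for genes in self.sets.values() for g in genes})

    def restrict(self, genes: Sequence[str]) -> "GeneSetCatalog":
        """Drop genes absent from ``genes``; sets left empty are removed with a warning."""
        keep = set(genes)
        restricted = {}
        for name, members in self.sets.items():
            inside = [g for g in members if g in keep]
            if inside:
                restricted[name] = inside
            else:
                logger.warning("gene set %r empty after restriction; skipped", name)
        return GeneSetCatalog(restricted, universe=[g for g in self.universe if g in keep])


def maxmean(scores: np.ndarray) -> float:
    """Signed maxmean of a set's per-gene scores.

    s+ = mean over the set of max(z, 0); s- = mean of max(-z, 0); returns s+
    when s+ >= s-, else -s-.
    """
    z = np.asarray(scores, dtype=float)
    if z.size == 0:
        raise DataError("maxmean of an empty gene set")
    s_pos = float(np.maximum(z, 0.0).mean())
    s_neg = float(np.maximum(-z, 0.0).mean())
    return s_pos if s_pos >= s_neg else -s_neg


def _random_set_moments(
    z: np.ndarray, size: int, n_random: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and sd of maxmean over random same-size gene sets (row randomization)."""
    idx = np.stack([rng.choice(z.size, size=size, replace=False) for _ in range(n_random)])
    vals = z[idx]
    s_pos = np.maximum(vals, 0.0).mean(axis=1)
    s_neg = np.maximum(-vals, 0.0).mean(axis=1)
    mm = np.where(s_pos >= s_neg, s_pos, -s_neg)
    sd = float(mm.std(ddof=1))
    return float(mm.mean()), sd if sd > 0 else 1.0


def gsa(
    catalog: GeneSetCatalog,
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
    n_random_sets: int = 1000,
    p_significant: float = 0.01,
    s0: float | None = None,
) -> pd.DataFrame:
    """Score every catalog set against a two-group expression matrix.

    Per-gene scores are the SAM d-statistics.  Each set's maxmean is
    restandardized against random same-size gene sets, the label-permutation
    null (each permutation restandardized against random sets drawn from its
    own permuted scores) yields the two-sided p-value, and the FDR is the
    permutation ratio: the mean number of null sets at least as extreme as a
    set's standardized score, divided by the observed count at least as
    extreme.  Sets with p < ``p_significant`` are flagged.

    Returns a DataFrame indexed by set name with columns ``score`` (signed
    maxmean), ``standardized``, ``p``, ``fdr``, ``significant``, ``n_genes``.
    """
    if n_perm < 50:
        logger.warning("n_perm=%d < 50: GSA p-values will be unstable", n_perm)
    catalog = catalog.restrict(matrix.index)
    if not catalog.sets:
        raise DataError("no gene sets remain after restriction to the matrix genes")

    x, mask2 = _group_arrays(matrix, labels)
    numer, s, _ = _sam_d(x, mask2, 0.0)
    if s0 is None:
        s0 = estimate_s0(s, numer)
    _, _, z_obs = _sam_d(x, mask2, s0)

    gene_pos = {g: i for i, g in enumerate(matrix.index)}
    set_names = list(catalog.sets)
    set_idx = [np.array([gene_pos[g] for g in catalog.sets[name]]) for name in set_names]
    sizes = sorted({idx.size for idx in set_idx})

    rng = np.random.default_rng(seed)
    obs_moments = {m: _random_set_moments(z_obs, m, n_random_sets, rng) for m in sizes}
    obs_raw = np.array([maxmean(z_obs[idx]) for idx in set_idx])
    obs_std = np.array([
        (raw - obs_moments[idx.size][0]) / obs_moments[idx.size][1]
        for raw, idx in zip(obs_raw, set_idx)
    ])

    masks = _label_permutations(x.shape[1], int(mask2.sum()), n_perm, int(rng.integers(2**31)))
    # Restandardize each permutation against random sets drawn from its own
    # permuted scores; fewer random sets per permutation keep this tractable.
    n_rand_perm = max(50, n_random_sets // 10)
    perm_std = np.empty((len(masks), len(set_names)))
    for p, mask in enumerate(masks):
        _, _, zp = _sam_d(x, mask, s0)
        moments = {m: _random_set_moments(zp, m, n_rand_perm, rng) for m in sizes}
        for j, idx in enumerate(set_idx):
            mu, sd = moments[idx.size]
            perm_std[p, j] = (maxmean(zp[idx]) - mu) / sd

    abs_obs = np.abs(obs_std)
    # Two-sided p with the observed instance counted in the null (plug-in).
    exceed = (np.abs(perm_std) >= abs_obs[None, :] - 1e-12).sum(axis=0)
    pvals = (exceed + 1) / (len(masks) + 1)

    # Permutation-ratio FDR over the standardized-score ranking.
    all_null = np.abs(perm_std).ravel()
    n_sets = len(set_names)
    fdr = np.empty(n_sets)
    for j in range(n_sets):
        null_rate = (all_null >= abs_obs[j] - 1e-12).mean() * n_sets
        obs_count = int((abs_obs >= abs_obs[j] - 1e-12).sum())
        fdr[j] = min(null_rate / obs_count, 1.0) if obs_count else 0.0

    out = pd.DataFrame({
        "score": obs_raw,
        "standardized": obs_std,
        "p": pvals,
        "fdr": fdr,
        "significant": pvals < p_significant,
        "n_genes": [idx.size for idx in set_idx],
    }, index=pd.Index(set_names, name="set_name"))
    return out.sort_values("p")


def consensus_min_count(min_fraction: float, n_sets: int) -> int:
    """Smallest integer c with c >= min_fraction * n_sets (float-noise tolerant)."""
    if not 0 < min_fraction <= 1:
        raise ConfigurationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if n_sets < 1:
        raise ConfigurationError("need at least one gene set")
    return max(1, math.ceil(min_fraction * n_sets - 1e-9))


def consensus_signature(
    sets: Mapping[str, Sequence[str]], min_fraction: float = 0.25
) -> pd.DataFrame:
    """Genes recurring across a collection of significant gene sets.

    A gene belongs to the consensus signature when it appears in at least
    ``ceil(min_fraction * n_sets)`` of the sets (e.g. 25% of 23 sets -> at
    least 6).  Returns a DataFrame indexed by gene id with the membership
    count, sorted by descending count.
    """
    n_sets = len(sets)
    min_count = consensus_min_count(min_fraction, n_sets)
    counts: dict[str, int] = {}
    for members in sets.values():
        for g in set(members):
            counts[g] = counts.get(g, 0) + 1
    rows = {g: c for g, c in counts.items() if c >= min_count}
    out = pd.DataFrame({"n_sets": pd.Series(rows, dtype=int)}).rename_axis("gene_id")
    out.attrs["min_count"] = min_count
    out.attrs["n_sets_total"] = n_sets
    return out.sort_values("n_sets", ascending=False)


def directional_overlap(
    list_a: Mapping[str, str], list_b: Mapping[str, str]
) -> list[str]:
    """Genes present in both signed DE lists with matching direction.

    Inputs map gene id to ``"up"`` or ``"down"``.
    """
    for name, lst in (("a", list_a), ("b", list_b)):
        bad = {d for d in lst.values()} - {"up", "down"}
        if bad:
            raise DataError(f"list {name} has invalid directions: {sorted(bad)}")
    return sorted(g for g, d in list_a.items() if list_b.get(g) == d)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` items are drawn without replacement from a
    universe of ``N`` containing ``K`` marked items.
    """
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise DataError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_test(
    list_a: Mapping[str, str], list_b: Mapping[str, str], n_universe: int
) -> dict:
    """Direction-matched overlap of two signed DE lists with a hypergeometric p.

    The null treats list b's direction-matched genes as a random draw of
    ``size_b`` from the universe; the p-value is the upper tail of observing at
    least the matched intersection against list a.
    """
    matched = directional_overlap(list_a, list_b)
    size_a, size_b = len(list_a), len(list_b)
    if n_universe < max(size_a, size_b):
        raise DataError(f"universe {n_universe} smaller than a list ({size_a}, {size_b})")
    p = hypergeom_tail(n_universe, size_a, size_b, len(matched))
    return {
        "n_universe": n_universe,
        "size_a": size_a,
        "size_b": size_b,
        "k_observed": len(matched),
        "matched_genes": matched,
        "p_hypergeom": p,
    }


def fisher_enrichment(
    hits: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Right-tailed Fisher's exact test of a gene set's enrichment in a hit list.

    Returns ``(odds_ratio, p)``.  The odds ratio gets a 0.5 continuity
    correction only when a cell of the 2x2 table is zero.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    h = set(hits) & uni
    s = set(gene_set) & uni
    if set(hits) - uni or set(gene_set) - uni:
        raise DataError("hits and gene set must be subsets of the universe")
    a = len(h & s)
    b = len(h - s)
    c = len(s - h)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    return (a_ * d_) / (b_ * c_), float(p)
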
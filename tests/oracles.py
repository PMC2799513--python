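"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected values by enumeration or direct formulas using plain
Python loops, never the package's own code paths, so that tests compare two
independent routes to the same quantity.
"""

import itertools
import math
from statistics import mean, median


def sam_d_oracle(values_by_gene, group2_mask, s0):
    """d, numerator, s per gene via the textbook pooled-SE formula, loop form."""
    out = []
    for vals in values_by_gene:
        g1 = [v for v, m in zip(vals, group2_mask) if not m]
        g2 = [v for v, m in zip(vals, group2_mask) if m]
        n1, n2 = len(g1), len(g2)
        numer = mean(g2) - mean(g1)
        ss = sum((v - mean(g1)) ** 2 for v in g1) + sum((v - mean(g2)) ** 2 for v in g2)
        s = math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        d = numer / (s + s0) if (s + s0) > 0 else 0.0
        out.append((d, numer, s))
    return out


def sam_fdr_oracle(values_by_gene, group2_mask, s0, deltas):
    """Exhaustive-permutation SAM FDR table for tiny instances.

    Enumerates every distinct assignment of the group-2 label set, builds the
    expected order statistics, and for each delta applies the called-set /
    cutoff / median-false-count definition directly.
    """
    n = len(group2_mask)
    n2 = sum(group2_mask)
    d_obs = [d for d, _, _ in sam_d_oracle(values_by_gene, group2_mask, s0)]

    perm_ds = []
    for combo in itertools.combinations(range(n), n2):
        mask = [i in combo for i in range(n)]
        perm_ds.append([d for d, _, _ in sam_d_oracle(values_by_gene, mask, s0)])

    order = sorted(range(len(d_obs)), key=lambda i: d_obs[i])
    d_sorted = [d_obs[i] for i in order]
    expected = [mean(sorted(pd_)[i] for pd_ in perm_ds) for i in range(len(d_obs))]
    dev = [a - b for a, b in zip(d_sorted, expected)]

    tol = 1e-9  # absorbs float noise between the loop and vector arithmetic routes
    rows = []
    for delta in deltas:
        called = [abs(v) >= delta - tol for v in dev]
        n_called = sum(called)
        if n_called == 0:
            rows.append((delta, 0, 0.0, 0.0))
            continue
        ups = [d_sorted[i] for i in range(len(dev)) if called[i] and dev[i] >= 0]
        downs = [d_sorted[i] for i in range(len(dev)) if called[i] and dev[i] <= 0]
        cut_up = min(ups) if ups else math.inf
        cut_low = max(downs) if downs else -math.inf
        false_counts = [
            sum(1 for d in pd_ if d >= cut_up - tol or d <= cut_low + tol)
            for pd_ in perm_ds
        ]
        med = median(false_counts)
        rows.append((delta, n_called, med, med / n_called))
    return rows


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by direct summation of hypergeometric point masses."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def maxmean_oracle(scores):
    pos = [max(z, 0.0) for z in scores]
    neg = [max(-z, 0.0) for z in scores]
    s_pos = sum(pos) / len(scores)
    s_neg = sum(neg) / len(scores)
    return s_pos if s_pos >= s_neg else -s_neg


def bh_qvalues_oracle(pvals):
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all labelings (tie-free)."""
    nx, ny = len(x), len(y)
    combined = list(x) + list(y)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = nx * ny / 2
    us = []
    for combo in itertools.combinations(range(nx + ny), nx):
        xs = [combined[i] for i in combo]
        ys = [combined[i] for i in range(nx + ny) if i not in combo]
        us.append(u_stat(xs, ys))
    # two-sided: deviation from the null mean at least as large
    dev = abs(u_obs - mu)
    p = sum(1 for u in us if abs(u - mu) >= dev) / len(us)
    return u_obs, p
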
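"""Independent brute-force oracles for the gait-characteristic estimators.

These deliberately avoid the package's vectorized code paths (no cdist, no
polyfit): template counting is done row by row, nearest-neighbour search by
explicit loops, and the line fit by the closed-form covariance/variance
ratio, so agreement with the package is a real cross-check.
"""

import math

import numpy as np


def sampen_naive(x, m, r_factor):
    """Sample entropy by explicit template-pair counting.

    Row-by-row: for each template i, Chebyshev distances to every other
    template are formed directly from the shifted signal, one lag at a time.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0 if r_factor > 0 else math.nan
    r = r_factor * sd
    ntpl = n - m
    A = B = 0
    for i in range(ntpl):
        d_m = np.zeros(ntpl)
        for k in range(m):
            np.maximum(d_m, np.abs(x[i + k] - x[k : k + ntpl]), out=d_m)
        d_m1 = np.maximum(d_m, np.abs(x[i + m] - x[m : m + ntpl]))
        B += int(np.sum(d_m <= r)) - 1  # remove the i == j self-match
        A += int(np.sum(d_m1 <= r)) - 1
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def logdiv_naive(x, stride_time, fs, cfg):
    """Rosenstein divergence rate by exhaustive neighbour search, no index."""
    x = np.asarray(x, dtype=float)
    m, tau = cfg.embed_dim, cfg.embed_delay
    n = len(x) - (m - 1) * tau
    emb = np.array([[x[i + k * tau] for k in range(m)] for i in range(n)])
    min_sep = round(stride_time * fs)
    K = round(cfg.fit_stride_fraction * stride_time * fs)
    usable = n - K
    if usable <= min_sep + 1 or K < 2:
        return math.nan
    pairs = []
    for i in range(usable):
        best, bj = math.inf, -1
        for j in range(usable):
            if abs(i - j) <= min_sep:
                continue
            d = math.sqrt(sum((emb[i, c] - emb[j, c]) ** 2 for c in range(m)))
            if d < best:
                best, bj = d, j
        if bj >= 0:
            pairs.append((i, bj))
    if len(pairs) < cfg.min_neighbor_pairs:
        return math.nan
    curve = []
    for k in range(K + 1):
        s = 0.0
        for i, j in pairs:
            d = math.sqrt(sum((emb[i + k, c] - emb[j + k, c]) ** 2 for c in range(m)))
            s += math.log(max(d, 1e-12))
        curve.append(s / len(pairs))
    ks = np.arange(K + 1, dtype=float)
    kc = ks - ks.mean()
    cc = np.array(curve) - np.mean(curve)
    slope = float(np.dot(kc, cc) / np.dot(kc, kc))
    return slope * fs * stride_time


def autocorr_naive(x, lag):
    """Biased autocorrelation at one lag by a shifted dot product."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    num = sum(x[i] * x[i + lag] for i in range(len(x) - lag))
    den = sum(v * v for v in x)
    return num / den


def chi2_permutation_p(positives, totals, n_perm, seed):
    """Permutation p-value for association between group and a binary
    outcome, using the chi-square statistic on the 4x2 table."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(len(totals)), totals)
    outcome = np.concatenate(
        [np.r_[np.ones(p), np.zeros(t - p)] for p, t in zip(positives, totals)]
    )

    def stat(g, o):
        chi2 = 0.0
        n = len(o)
        p_all = o.mean()
        for k in range(len(totals)):
            mask = g == k
            nk = mask.sum()
            obs1 = o[mask].sum()
            for obs, exp in ((obs1, nk * p_all), (nk - obs1, nk * (1 - p_all))):
                chi2 += (obs - exp) ** 2 / exp
        return chi2

    observed = stat(groups, outcome)
    hits = 0
    for _ in range(n_perm):
        hits += stat(groups, rng.permutation(outcome)) >= observed - 1e-12
    return observed, (hits + 1) / (n_perm + 1)
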
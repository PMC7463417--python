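"""Independent brute-force oracles used by the tests.

Every function here is a deliberately naive re-derivation (explicit loops,
sorting, exhaustive enumeration) kept separate from the package code so the
two routes cannot share a bug.
"""

import math
from itertools import combinations

import numpy as np


def naive_first_order(values, n_bins=256):
    """First-order statistics by sorting and direct moment sums."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    mean = sum(vals) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    else:
        sd = 0.0

    def pct(q):
        # linear interpolation between closest ranks
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return vals[lo] + (h - lo) * (vals[hi] - vals[lo])

    m2 = sum((v - mean) ** 2 for v in vals) / n
    if m2 > 0:
        skew = (sum((v - mean) ** 3 for v in vals) / n) / m2**1.5
        kurt = (sum((v - mean) ** 4 for v in vals) / n) / m2**2 - 3.0
    else:
        skew = kurt = 0.0

    lo_v, hi_v = vals[0], vals[-1]
    if hi_v > lo_v:
        width = (hi_v - lo_v) / n_bins
        hist = [0] * n_bins
        for v in vals:
            b = min(int((v - lo_v) / width), n_bins - 1)
            hist[b] += 1
        entropy = -sum(c / n * math.log2(c / n) for c in hist if c)
    else:
        entropy = 0.0

    counts = {}
    for v in vals:
        q = round(v)
        counts[q] = counts.get(q, 0) + 1
    top = max(counts.values())
    mode = min(k for k, c in counts.items() if c == top)

    return {
        "mean": mean, "sd": sd, "minimum": vals[0], "maximum": vals[-1],
        "p5": pct(5), "p10": pct(10), "p25": pct(25), "p50": pct(50),
        "p75": pct(75), "p90": pct(90), "skewness": skew, "kurtosis": kurt,
        "entropy": entropy, "max_frequency": float(top), "mode": float(mode),
    }


def naive_glcm(image, mask, offset, n_bins=256, symmetric=True):
    """Co-occurrence counts by explicit per-slice pair loops."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    binned = np.zeros(image.shape, dtype=int)
    if hi > lo:
        b = np.floor((image - lo) / (hi - lo) * n_bins).astype(int)
        binned = np.clip(b, 0, n_bins - 1)
    dr, dc = offset
    P = np.zeros((n_bins, n_bins))
    nz, ny, nx = image.shape
    for z in range(nz):
        for r in range(ny):
            for c in range(nx):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < ny and 0 <= c2 < nx and mask[z, r, c] and mask[z, r2, c2]:
                    P[binned[z, r, c], binned[z, r2, c2]] += 1
    if symmetric:
        P = P + P.T
    s = P.sum()
    return P / s if s else P


def naive_glcm_features(P):
    """Literal double-loop evaluation of the GLCM scalar formulas."""
    k = P.shape[0]
    energy = entropy = inertia = mu = 0.0
    for i in range(k):
        for j in range(k):
            p = P[i, j]
            energy += p * p
            if p > 0:
                entropy -= p * math.log2(p)
            inertia += (i - j) ** 2 * p
            mu += i * p
    variance = 0.0
    for i in range(k):
        for j in range(k):
            variance += (i - mu) ** 2 * P[i, j]
    return {"entropy_glcm": entropy, "energy_glcm": energy,
            "inertia_glcm": inertia, "variance_glcm": variance}


def brute_force_diameter(mask_flags, spacing):
    """Exhaustive all-pairs maximum distance between masked voxel centers."""
    pts = [tuple(idx[k] * spacing[k] for k in range(3))
           for idx in np.argwhere(mask_flags)]
    if len(pts) < 2:
        return 0.0
    best = 0.0
    for p, q in combinations(pts, 2):
        d = math.dist(p, q)
        if d > best:
            best = d
    return best


def brute_force_mtv(image, mask, spacing, fraction):
    """Count voxels strictly above fraction*max by explicit scan."""
    vmax = max(image[tuple(i)] for i in np.argwhere(mask))
    thr = fraction * vmax
    count = sum(1 for i in np.argwhere(mask) if image[tuple(i)] > thr)
    return count * spacing[0] * spacing[1] * spacing[2]


def anova_icc21(ratings):
    """ICC(2,1) from a hand-rolled two-way ANOVA decomposition."""
    ratings = np.asarray(ratings, float)
    n, k = ratings.shape
    grand = ratings.mean()
    msr = k * sum((ratings[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((ratings[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (ratings[i, j] - ratings[i].mean() - ratings[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def enumerate_mann_whitney_tail(x, y):
    """Exact one-sided MW p (observed-direction tail) by full enumeration."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = [sum(c) - n1 * (n1 + 1) / 2 for c in combinations(range(1, len(pooled) + 1), n1)]
    ge = sum(1 for u in us if u >= u_obs - 1e-9) / len(us)
    le = sum(1 for u in us if u <= u_obs + 1e-9) / len(us)
    return min(ge, le)


def enumerate_wilcoxon(d):
    """Exact two-sided signed-rank p over all 2^n sign patterns (no ties)."""
    d = [v for v in d if v != 0]
    n = len(d)
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0] * n
    for r, (_, i) in enumerate(absd, start=1):
        ranks[i] = r
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    mu = n * (n + 1) / 4
    totals = []
    for bits in range(2**n):
        totals.append(sum(ranks[i] for i in range(n) if bits >> i & 1))
    ge = sum(1 for t in totals if t >= w_obs) / len(totals)
    le = sum(1 for t in totals if t <= w_obs) / len(totals)
    return min(1.0, 2 * min(ge, le))
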
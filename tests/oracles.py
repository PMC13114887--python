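"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths (and where possible the library
routines) they are used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def anova_f(groups: list[np.ndarray]) -> float:
    """Classical one-way F statistic by direct sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def permutation_anova_p(
    groups: list[np.ndarray], n_shuffles: int, seed: int, strict: bool = False
) -> float:
    """Monte-Carlo permutation p for the one-way F statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    f0 = anova_f(groups)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        out = []
        start = 0
        for s in sizes:
            out.append(perm[start : start + s])
            start += s
        f = anova_f(out)
        if (f > f0 + 1e-12) if strict else (f >= f0 - 1e-12):
            hits += 1
    return hits / n_shuffles


def exact_permutation_anova_p(groups: list[np.ndarray], strict: bool = False) -> float:
    """Exact permutation p by full enumeration (tiny balanced designs only)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    f0 = anova_f(groups)
    idx = list(range(n))

    def rec(remaining: list[int], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in rec(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    hits = tot = 0
    for assignment in rec(idx, sizes):
        f = anova_f([pooled[a] for a in assignment])
        tot += 1
        if (f > f0 + 1e-12) if strict else (f >= f0 - 1e-12):
            hits += 1
    return hits / tot


def studentized_range_cdf(q: float, k: int, df: int) -> float:
    """P(Q <= q) for the studentized range by direct double quadrature.

    Conditional on the scaled residual SD s ~ sqrt(chi2_df / df), the range
    of k standard normals falling within q*s has probability
    k * int phi(z) [Phi(z) - Phi(z - q s)]^(k-1) dz; integrate over the
    density of s.
    """
    if q <= 0:
        return 0.0

    def inner(s: float) -> float:
        def f(z: float) -> float:
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

        val, _ = quad(f, -8.0, 8.0 + q * s, limit=200, epsabs=1e-11, epsrel=1e-11)
        return k * val

    half = df / 2.0
    log_c = half * math.log(df) - (half - 1.0) * math.log(2.0) - math.lgamma(half)

    def s_density(s: float) -> float:
        return math.exp(log_c + (df - 1.0) * math.log(s) - df * s * s / 2.0)

    val, _ = quad(lambda s: s_density(s) * inner(s), 0.0, 10.0, limit=200, epsabs=1e-10, epsrel=1e-10)
    return min(val, 1.0)


def studentized_range_quantile(p: float, k: int, df: int) -> float:
    """Inverse of :func:`studentized_range_cdf` by bisection."""
    from scipy.optimize import brentq

    return brentq(lambda q: studentized_range_cdf(q, k, df) - p, 1e-6, 50.0, xtol=1e-8)
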
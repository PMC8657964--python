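"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the code paths (and where possible the library
calls) used by the package: sums of squares are accumulated directly, the
studentized-range CDF is integrated numerically from its definition, the
Benjamini-Hochberg step-up is the textbook min-over-suffix formula, and the
Fisher two-sided p-value is an exact integer-arithmetic enumeration of the
hypergeometric support.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln
from scipy.stats import f as f_dist
from scipy.stats import norm

_GL_NODES = np.polynomial.legendre.leggauss(400)


def anova_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p from direct sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(f_dist.sf(F, df_b, df_w))


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: adj_i = min_{j >= i} min(1, m * p_(j) / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def tukey_sf_oracle(q: float, k: int, df: float) -> float:
    """Studentized-range survival function by direct numerical integration.

    P(Q > q) with Q = range(k standard normals) / (chi_df / sqrt(df)),
    integrating the range CDF against the density of S = sqrt(W/df),
    W ~ chi-squared(df).
    """

    # inner integral over z on a wide fixed interval; the integrand decays
    # like the normal density, so 400 Gauss-Legendre nodes give ~1e-14
    def range_cdf(w: float) -> float:
        if w <= 0:
            return 0.0
        lo, hi = -9.0, 9.0 + w
        z, wt = _GL_NODES
        z = 0.5 * (hi - lo) * z + 0.5 * (hi + lo)
        wt = 0.5 * (hi - lo) * wt
        vals = norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - w)) ** (k - 1)
        return k * float(np.sum(wt * vals))

    def outer(s: float) -> float:
        log_pdf = (
            (df / 2.0) * math.log(df)
            + (df - 1.0) * math.log(s)
            - df * s * s / 2.0
            + (1.0 - df / 2.0) * math.log(2.0)
            - gammaln(df / 2.0)
        )
        return math.exp(log_pdf) * range_cdf(q * s)

    cdf, _ = integrate.quad(outer, 0, np.inf, epsabs=1e-12, epsrel=1e-11, limit=200)
    return 1.0 - cdf


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Sums P(X = x) over all x in the support whose point probability does not
    exceed that of the observed table; comparisons use exact integers
    (the common denominator cancels), so there is no floating-point tie
    ambiguity.
    """
    r1, r2 = a + b, c + d
    m = a + c
    lo, hi = max(0, m - r2), min(r1, m)
    weights = {x: math.comb(r1, x) * math.comb(r2, m - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= obs)
    return tail / total


def closure_oracle(terms: set[str], parents: dict[str, set[str]]) -> set[str]:
    """Ancestor closure by repeated parent expansion until fixed point."""
    out = set(terms)
    while True:
        new = set()
        for t in out:
            new |= parents.get(t, set())
        if new <= out:
            return out
        out |= new
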
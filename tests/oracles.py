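"""Independent reference implementations used only to check the package.

Everything here is built from textbook definitions and the math module
(erf, lgamma) plus bisection — deliberately avoiding the code paths the
package itself uses (scipy.stats.norm/chi2/ttest_ind).
"""

from __future__ import annotations

import math


def normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def normal_quantile(p: float, tol: float = 1e-15) -> float:
    """Inverse normal CDF by bisection on erf."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def chi2_sf_even_df(x: float, df: int) -> float:
    """Survival function of chi-square with even df, closed form:
    e^{-x/2} * sum_{i=0}^{df/2-1} (x/2)^i / i!."""
    assert df % 2 == 0 and df >= 2
    half = x / 2.0
    term = 1.0
    total = 1.0
    for i in range(1, df // 2):
        term *= half / i
        total += term
    return math.exp(-half) * total


def stouffer_reference(p_lefts) -> tuple[float, int]:
    z = sum(normal_quantile(p) for p in p_lefts) / math.sqrt(len(p_lefts))
    p_l = normal_cdf(z)
    p_r = normal_cdf(-z)
    p = min(1.0, 2.0 * min(p_l, p_r))
    sign = 0 if abs(z) < 1e-9 else (-1 if z < 0 else 1)
    return p, sign


def pearson_reference(p_lefts) -> tuple[float, int]:
    q_l = -2.0 * sum(math.log(p) for p in p_lefts)
    q_r = -2.0 * sum(math.log(1.0 - p) for p in p_lefts)
    q_t = max(q_l, q_r)
    p = min(1.0, 2.0 * chi2_sf_even_df(q_t, 2 * len(p_lefts)))
    sign = 0 if abs(q_l - q_r) < 1e-9 else (-1 if q_l > q_r else 1)
    return p, sign


def bh_stepup(p) -> list[float]:
    """Brute-force Benjamini–Hochberg adjusted p-values: for each i,
    q_i = min over all j with p_j >= p_i of (m * p_j / rank_j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(1.0, running)
    return q


def t_sf(t: float, df: float, n_grid: int = 200001) -> float:
    """P(T > t) for Student's t by Simpson integration of the density
    (variable change u = df / (df + x^2) keeps the tail finite)."""
    # integrate density from t to a far cutoff where the tail is negligible
    upper = max(t, 0.0) + 400.0

    def density(x: float) -> float:
        log_c = (
            math.lgamma((df + 1.0) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi)
        )
        return math.exp(log_c - (df + 1.0) / 2.0 * math.log1p(x * x / df))

    h = (upper - t) / (n_grid - 1)
    total = density(t) + density(upper)
    for k in range(1, n_grid - 1):
        total += density(t + k * h) * (4 if k % 2 else 2)
    return total * h / 3.0


def welch_reference(g1, g2) -> tuple[float, int]:
    """Two-sided Welch t-test from the textbook formulas."""
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    v1 = sum((x - m1) ** 2 for x in g1) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in g2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    sign = 0 if diff == 0 else (-1 if diff < 0 else 1)
    if se2 == 0.0:
        return (1.0 if diff == 0 else 0.0), sign
    t = abs(diff) / math.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    return min(1.0, 2.0 * t_sf(t, df)), sign
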
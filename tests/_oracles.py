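"""Independent slow oracles used only by the test suite.

Each oracle recomputes a quantity by a method unrelated to the library's
own algorithm (linear programming, exhaustive enumeration, restarted
heuristics), so that agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(sample) -> float:
    """Dip statistic by direct sup-norm minimisation via linear programming.

    A unimodal CDF is convex up to its mode and concave after it; it may
    carry an atom only at the mode.  Restricted to curves that are piecewise
    linear between the distinct sample values (which is sufficient for the
    minimiser), such a CDF with mode at knot ``t`` is parameterised by its
    knot values ``g_1..g_m`` plus a nonnegative jump ``a`` at the mode.
    Unimodality then means the segment slopes are nondecreasing before the
    mode and nonincreasing after it.  For every candidate mode knot, the
    minimal band half-width ``d`` keeping the ECDF within ``d`` of the curve
    everywhere is a linear program; the dip is the minimum over modes.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    if m == 1:
        return 0.0
    c = np.cumsum(counts) / n  # ECDF right limits at the knots
    c_prev = np.concatenate([[0.0], c[:-1]])  # left limits
    h = np.diff(u)

    best = np.inf
    # Variables: g_1..g_m (values left of / at each knot), a (jump at the
    # mode), d.  Minimise d.
    nv = m + 2
    ja, jd = m, m + 1
    cost = np.zeros(nv)
    cost[jd] = 1.0
    for t in range(m):  # mode at knot t
        a_ub = []
        b_ub = []

        def le(coeffs, rhs):  # sum coeffs·vars <= rhs
            row = np.zeros(nv)
            for idx, val in coeffs:
                row[idx] += val
            a_ub.append(row)
            b_ub.append(rhs)

        for k in range(m):
            # left-limit upper band: g_k <= c_{k-1} + d
            le([(k, 1.0), (jd, -1.0)], c_prev[k])
            # point lower band on G(u_k); at the mode the value is g_t + a
            if k == t:
                le([(k, -1.0), (ja, -1.0), (jd, -1.0)], -c[k])
                # and the jumped value must not overshoot the band
                le([(k, 1.0), (ja, 1.0), (jd, -1.0)], c[k])
            else:
                le([(k, -1.0), (jd, -1.0)], -c[k])
        # monotonicity, including across the jump
        for k in range(m - 1):
            if k == t:
                le([(k, 1.0), (ja, 1.0), (k + 1, -1.0)], 0.0)
            else:
                le([(k, 1.0), (k + 1, -1.0)], 0.0)
        # slope of segment i is (g_{i+1} - g_i)/h_i, with the mode's jump
        # subtracted on the segment leaving the mode
        def slope_coeffs(i, sign):
            out = [(i + 1, sign / h[i]), (i, -sign / h[i])]
            if i == t:
                out.append((ja, -sign / h[i]))
            return out

        for i in range(m - 2):
            if i + 1 <= t - 1:
                # convex region: s_i <= s_{i+1}
                le(slope_coeffs(i, 1.0) + slope_coeffs(i + 1, -1.0), 0.0)
            elif i >= t:
                # concave region: s_i >= s_{i+1}
                le(slope_coeffs(i, -1.0) + slope_coeffs(i + 1, 1.0), 0.0)
        bounds = [(0.0, 1.0)] * m + [(0.0, 1.0), (0.0, 1.0)]
        res = linprog(
            cost,
            A_ub=np.array(a_ub),
            b_ub=np.array(b_ub),
            bounds=bounds,
            method="highs",
        )
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)


def kmeans_1d_bruteforce(sample, k: int):
    """Exhaustive search over all contiguous partitions of the sorted sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x[a:b]
            ss += float(np.sum((seg - seg.mean()) ** 2))
        if ss < best[0] - 1e-15:
            best = (ss, bounds)
    return best


def lloyd_1d(sample, k: int, n_restarts: int = 100, seed: int = 0) -> float:
    """Best within-cluster SS over seeded random-restart Lloyd iterations."""
    x = np.asarray(sample, dtype=float)
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        centres = rng.choice(x, size=k, replace=False)
        for _ in range(200):
            d = np.abs(x[:, None] - centres[None, :])
            lab = np.argmin(d, axis=1)
            new = np.array(
                [x[lab == j].mean() if np.any(lab == j) else centres[j] for j in range(k)]
            )
            if np.allclose(new, centres):
                break
            centres = new
        ss = float(np.sum((x - centres[lab]) ** 2))
        best = min(best, ss)
    return best


def friedman_statistic(table: np.ndarray) -> float:
    """Friedman chi-square from the direct rank formula (no tie correction).

    ``table`` is blocks x treatments with a complete design and no within-
    block ties.
    """
    from scipy.stats import rankdata

    b, t = table.shape
    ranks = np.apply_along_axis(rankdata, 1, table)
    rj = ranks.sum(axis=0)
    return float(12.0 / (b * t * (t + 1)) * np.sum((rj - b * (t + 1) / 2.0) ** 2))


def durbin_permutation_p(table: np.ndarray, statistic_fn, n_perm: int = 10000, seed: int = 0):
    """Within-block permutation p-value for a block-design rank statistic."""
    rng = np.random.default_rng(seed)
    obs = statistic_fn(table)
    count = 0
    for _ in range(n_perm):
        perm = np.empty_like(table)
        for i in range(table.shape[0]):
            perm[i] = rng.permutation(table[i])
        if statistic_fn(perm) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (1 + n_perm)
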
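"""Size-distribution analysis of follicle diameters.

The vitellogenic follicles of a nesting green turtle fall into two size
classes: small follicles destined for resorption and large ("dominant")
follicles destined for ovulation.  This module provides the statistical
machinery used to establish that structure from a pooled sample of
diameters:

* Hartigan's dip statistic and a Monte-Carlo dip test for unimodality;
* exact 1-D k-means via dynamic programming over the sorted sample
  (the optimal partition is contiguous in sorted order, so the global
  optimum is reachable without random restarts);
* cluster-count selection by the elbow and silhouette criteria;
* derivation of the dominant/non-dominant diameter threshold from the
  two-cluster model (floor of the smallest diameter in the upper cluster,
  used as a strict lower bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._dip import dip_from_sorted

__all__ = [
    "DipResult",
    "ClusterModel",
    "KSelection",
    "dip_statistic",
    "dip_test",
    "kmeans_1d",
    "mean_silhouette",
    "select_k",
    "derive_dominance_threshold",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DipResult:
    """Dip statistic of a sample, optionally with a Monte-Carlo p-value.

    The statistic D is the smallest sup-norm distance between the empirical
    CDF and any unimodal CDF; it lies in [0, 0.25].  The p-value, when
    present, is calibrated against samples of the same size drawn from the
    uniform distribution on (0, 1), the classical least-favourable unimodal
    null for the dip test.
    """

    statistic_D: float
    p_value: Optional[float]
    n: int
    n_monte_carlo: int = 0
    rng_seed: Optional[int] = None


@dataclass
class ClusterModel:
    """A fitted 1-D k-means partition (globally optimal)."""

    k: int
    centres: np.ndarray  # ascending, mm
    assignments: np.ndarray  # per-observation cluster index, input order
    within_ss: float  # mm^2
    cluster_sizes: np.ndarray
    cluster_means: np.ndarray
    cluster_sds: np.ndarray  # sample SD (ddof=1), 0 for singletons
    min_of_upper_cluster: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.centres) > 0):
            raise ValueError("cluster centres must be strictly ascending")


@dataclass
class KSelection:
    """Diagnostics for choosing the number of clusters."""

    candidate_ks: list[int]
    elbow_k: Optional[int]
    silhouette_k: Optional[int]
    total_within_ss_by_k: dict[int, float] = field(default_factory=dict)
    mean_silhouette_by_k: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dip statistic and test


def _as_sample(sample: Sequence[float]) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("sample too small: the dip statistic needs n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return x


def dip_statistic(sample: Sequence[float]) -> DipResult:
    """Hartigan's dip statistic of a sample (no p-value).

    D is half the maximal deviation accumulated by the greatest-convex-
    minorant / least-concave-majorant iteration over candidate modal
    intervals, equal to the minimal sup-norm distance between the ECDF and
    the class of unimodal distribution functions.  An all-equal sample is
    perfectly unimodal (a point mass) and has D = 0.
    """
    x = _as_sample(sample)
    d = dip_from_sorted(np.sort(x))
    return DipResult(statistic_D=d, p_value=None, n=int(x.size))


def dip_test(
    sample: Sequence[float],
    n_monte_carlo: int = 999,
    rng_seed: int = 0,
) -> DipResult:
    """Dip test of unimodality with a Monte-Carlo p-value.

    The null distribution of D is simulated from ``n_monte_carlo`` uniform
    samples of the same size; p = (1 + #{D_null >= D_obs}) / (1 + R), which
    is never smaller than 1/(1+R).
    """
    x = _as_sample(sample)
    if n_monte_carlo < 99:
        raise ValueError("n_monte_carlo must be >= 99")
    d_obs = dip_from_sorted(np.sort(x))
    rng = np.random.default_rng(rng_seed)
    n = x.size
    exceed = 0
    for _ in range(n_monte_carlo):
        null = np.sort(rng.random(n))
        if dip_from_sorted(null) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_monte_carlo)
    return DipResult(
        statistic_D=d_obs,
        p_value=p,
        n=int(n),
        n_monte_carlo=int(n_monte_carlo),
        rng_seed=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# exact 1-D k-means


def _weighted_prefix(u: np.ndarray, w: np.ndarray):
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * u)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * u * u)])

    def cost(a: int, b: int) -> float:
        """Weighted SS of unique values u[a:b] around their mean."""
        wt = cw[b] - cw[a]
        if wt <= 0.0:
            return 0.0
        s = cwx[b] - cwx[a]
        q = cwx2[b] - cwx2[a]
        return max(0.0, q - s * s / wt)

    return cost


def kmeans_1d(sample: Sequence[float], k: int) -> ClusterModel:
    """Globally optimal 1-D k-means by dynamic programming.

    The optimal k-means partition of scalars is contiguous in sorted order,
    so the exact optimum is found by dynamic programming over the distinct
    values (with multiplicity weights), using divide-and-conquer on the
    monotone split points.  Deterministic; no seed.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot fit k={k} clusters to n={n} observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    u, w = np.unique(xs, return_counts=True)
    m = u.size
    if k > m:
        raise ValueError(
            f"cannot fit k={k} clusters with strictly ascending centres to "
            f"{m} distinct values"
        )
    cost = _weighted_prefix(u, w.astype(float))

    # dp[i] = optimal cost of first i unique values in the current layer
    inf = math.inf
    prev = np.array([0.0] + [cost(0, i) for i in range(1, m + 1)])
    args_by_layer = []
    for layer in range(2, k + 1):
        cur = np.full(m + 1, inf)
        arg = np.zeros(m + 1, dtype=int)

        def solve(lo: int, hi: int, optlo: int, opthi: int) -> None:
            # fill cur[i] for i in [lo, hi]; optimal split in [optlo, opthi]
            if lo > hi:
                return
            mid = (lo + hi) // 2
            best = inf
            bests = optlo
            smax = min(opthi, mid - 1)
            for s in range(max(optlo, layer - 1), smax + 1):
                v = prev[s] + cost(s, mid)
                if v < best:
                    best = v
                    bests = s
            cur[mid] = best
            arg[mid] = bests
            solve(lo, mid - 1, optlo, bests)
            solve(mid + 1, hi, bests, opthi)

        solve(layer, m, layer - 1, m - 1)
        args_by_layer.append(arg)
        prev = cur

    within_ss = float(prev[m])

    # backtrack contiguous boundaries over unique values
    bounds = [m]
    i = m
    for layer in range(k, 1, -1):
        i = int(args_by_layer[layer - 2][i])
        bounds.append(i)
    bounds.append(0)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = m

    labels_u = np.empty(m, dtype=int)
    means = np.empty(k)
    sizes = np.empty(k, dtype=int)
    sds = np.empty(k)
    for j in range(k):
        a, b = bounds[j], bounds[j + 1]
        labels_u[a:b] = j
        seg_w = w[a:b].astype(float)
        seg_u = u[a:b]
        sizes[j] = int(seg_w.sum())
        means[j] = float(np.average(seg_u, weights=seg_w))
        if sizes[j] > 1:
            ss = float(np.sum(seg_w * (seg_u - means[j]) ** 2))
            sds[j] = math.sqrt(ss / (sizes[j] - 1))
        else:
            sds[j] = 0.0

    # map back to input order
    labels_sorted = labels_u[np.searchsorted(u, xs)]
    assignments = np.empty(n, dtype=int)
    assignments[order] = labels_sorted

    upper_a = bounds[k - 1]
    return ClusterModel(
        k=k,
        centres=means.copy(),
        assignments=assignments,
        within_ss=within_ss,
        cluster_sizes=sizes,
        cluster_means=means,
        cluster_sds=sds,
        min_of_upper_cluster=float(u[upper_a]),
    )


# ---------------------------------------------------------------------------
# cluster-count selection


def mean_silhouette(sample: Sequence[float], model: ClusterModel) -> float:
    """Mean silhouette width of a fitted 1-D partition.

    Uses exact mean absolute deviations computed from per-cluster prefix
    sums (no pairwise distance matrix).  Silhouette of a point in a
    singleton cluster is defined as 0.
    """
    x = np.asarray(sample, dtype=float).ravel()
    labels = model.assignments
    k = model.k
    if k < 2:
        raise ValueError("silhouette requires k >= 2")

    clusters = [np.sort(x[labels == j]) for j in range(k)]
    prefixes = [np.concatenate([[0.0], np.cumsum(c)]) for c in clusters]

    def sum_absdist(points: np.ndarray, j: int) -> np.ndarray:
        c, p = clusters[j], prefixes[j]
        idx = np.searchsorted(c, points)
        left = points * idx - p[idx]
        right = (p[-1] - p[idx]) - points * (c.size - idx)
        return left + right

    a = np.empty(x.size)
    b = np.full(x.size, np.inf)
    for j in range(k):
        mask = labels == j
        size = clusters[j].size
        pts = x[mask]
        within = sum_absdist(pts, j)
        a[mask] = within / (size - 1) if size > 1 else 0.0
        for other in range(k):
            if other == j:
                continue
            d = sum_absdist(pts, other) / clusters[other].size
            b[mask] = np.minimum(b[mask], d)

    s = np.zeros(x.size)
    denom = np.maximum(a, b)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    for j in range(k):
        if clusters[j].size == 1:
            s[labels == j] = 0.0
    return float(s.mean())


def select_k(sample: Sequence[float], candidate_ks: Sequence[int] = range(1, 11)) -> KSelection:
    """Choose the number of clusters by the elbow and silhouette methods.

    The elbow is formalised as the k maximising the second difference of
    total within-cluster SS over k (ties resolved toward smaller k); the
    silhouette choice maximises mean silhouette width.  k = 1 cannot be
    scored by either criterion and is only ever reported through the
    diagnostics table.
    """
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks or ks[0] < 1 or ks[-1] > 10:
        raise ValueError("candidate_ks must be within [1, 10]")
    x = np.asarray(sample, dtype=float).ravel()
    if x.size <= ks[-1]:
        raise ValueError("sample size must exceed max(candidate_ks)")
    if np.unique(x).size == 1:
        raise ValueError("no dispersion: all observations are identical")

    m_distinct = np.unique(x).size
    # WSS for neighbours of the candidate range so second differences exist
    wss_ks = sorted(set(ks) | {k - 1 for k in ks if k - 1 >= 1} | {k + 1 for k in ks})
    wss_ks = [k for k in wss_ks if k <= m_distinct]

    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for k in wss_ks:
        models[k] = kmeans_1d(x, k)
        wss[k] = models[k].within_ss
    for k in ks:
        if k >= 2 and k in models:
            sil[k] = mean_silhouette(x, models[k])

    elbow_k = None
    best_curv = -np.inf
    for k in ks:
        if k - 1 in wss and k + 1 in wss and k in wss and k >= 2:
            curv = wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
            if curv > best_curv + 1e-12:
                best_curv = curv
                elbow_k = k

    silhouette_k = None
    if sil:
        best = max(sil.values())
        silhouette_k = min(k for k, v in sil.items() if v >= best - 1e-12)

    return KSelection(
        candidate_ks=ks,
        elbow_k=elbow_k,
        silhouette_k=silhouette_k,
        total_within_ss_by_k={k: wss[k] for k in ks if k in wss},
        mean_silhouette_by_k=sil,
    )


# ---------------------------------------------------------------------------
# dominance threshold


def derive_dominance_threshold(model: ClusterModel) -> int:
    """Dominance threshold (mm) from a two-cluster diameter model.

    Returns the floor of the smallest diameter assigned to the upper
    cluster, to be used as a strict lower bound: a follicle is dominant iff
    its diameter exceeds the threshold.  A diameter exactly at the
    threshold classifies as non-dominant.
    """
    if model.k != 2:
        raise ValueError("dominance threshold requires a k=2 cluster model")
    return int(math.floor(model.min_of_upper_cluster))
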
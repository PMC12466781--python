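"""Independent brute-force oracles used to validate the library implementations.

Everything here is deliberately naive — BFS flood fill, exhaustive Ward
agglomeration, the textbook BH definition, a likelihood grid search — so that
agreement with the fast library paths is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special


def connectivity_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(v) for v in d)
        if connectivity == 6 and manhattan == 1:
            offsets.append(d)
        elif connectivity == 18 and manhattan <= 2:
            offsets.append(d)
        elif connectivity == 26:
            offsets.append(d)
    return offsets


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[dict]:
    """BFS connected components of a boolean 3D mask.

    Returns one dict per component with ``n_voxels`` and ``centroid``
    (unweighted mean of voxel indices), sorted by centroid (z, y, x).
    """
    offsets = connectivity_offsets(connectivity)
    visited = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    comps = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        members = []
        while stack:
            v = stack.pop()
            members.append(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                        and 0 <= w[2] < shape[2]
                        and mask[w] and not visited[w]):
                    visited[w] = True
                    stack.append(w)
        arr = np.array(members, dtype=float)
        comps.append(
            {"n_voxels": len(members), "centroid": tuple(arr.mean(axis=0))}
        )
    comps.sort(key=lambda c: c["centroid"])
    return comps


def bh_adjust_bruteforce(p: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values straight from the definition.

    adjusted_i = min over j with p_j >= p_i of min(1, m * p_j / rank_j).
    """
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    adjusted = []
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / rank[j]) for j in range(m) if p[j] >= p[i]
        ]
        adjusted.append(min(candidates))
    return adjusted


def ward_bruteforce(points: np.ndarray) -> list[dict]:
    """Exhaustive Ward agglomeration.

    At each step merges the pair of clusters minimizing the increase in
    within-cluster sum of squares, Delta = |A||B|/(|A|+|B|) ||cA - cB||^2,
    ties broken by the smallest (i, j) cluster-index pair.  Heights are
    reported as sqrt(2 * Delta), the scale scipy's ward linkage uses.
    """
    n = len(points)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                pa = points[clusters[a]]
                pb = points[clusters[b]]
                ca, cb = pa.mean(axis=0), pb.mean(axis=0)
                delta = (len(pa) * len(pb)) / (len(pa) + len(pb)) * float(
                    np.sum((ca - cb) ** 2)
                )
                key = (delta, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _, _), a, b = best
        delta = best[0][0]
        members = sorted(clusters[a] + clusters[b])
        merges.append(
            {"members": members, "height": math.sqrt(2.0 * delta)}
        )
        clusters[next_id] = members
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def linkage_to_merges(Z: np.ndarray, n: int) -> list[dict]:
    """Convert a scipy linkage matrix to the same merge-list form as the oracle."""
    members = {i: [i] for i in range(n)}
    merges = []
    for k, (a, b, height, _) in enumerate(Z):
        merged = sorted(members[int(a)] + members[int(b)])
        members[n + k] = merged
        merges.append({"members": merged, "height": float(height)})
    return merges


def nb_loglik_grid_best(
    y: np.ndarray, groups: np.ndarray, mu_grid: np.ndarray, theta_grid: np.ndarray
) -> tuple[float, float, float, float]:
    """Grid-search NB2 MLE for a two-group design.

    Returns (best mu0, best mu1, best theta, best log-likelihood) over the
    Cartesian grid.  Used to confirm the analytic property that the fitted
    group means equal the sample means for indicator designs.
    """
    y0, y1 = y[groups == 0], y[groups == 1]

    def ll(yv, mu, theta):
        return float(
            np.sum(
                special.gammaln(yv + theta) - special.gammaln(theta)
                - special.gammaln(yv + 1)
                + theta * math.log(theta / (theta + mu))
                + yv * np.log(mu / (theta + mu))
            )
        )

    best = (-math.inf, None, None, None)
    for theta in theta_grid:
        for mu0 in mu_grid:
            l0 = ll(y0, mu0, theta)
            for mu1 in mu_grid:
                total = l0 + ll(y1, mu1, theta)
                if total > best[0]:
                    best = (total, mu0, mu1, theta)
    return best[1], best[2], best[3], best[0]
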
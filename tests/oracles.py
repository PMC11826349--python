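"""Brute-force reference implementations used only by the tests.

Every oracle enumerates explicitly (all simple paths, all triangles, all
assignments) and is deliberately independent of the library code paths it
checks: no scipy graph routines, no networkx, no shared helpers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TOL = 1e-9


def _neighbors(w: np.ndarray, i: int) -> list[int]:
    return [j for j in range(w.shape[0]) if w[i, j] > 0]


def enumerate_simple_paths(w: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All simple paths s -> t via DFS."""
    paths: list[list[int]] = []

    def dfs(node: int, visited: list[int]) -> None:
        if node == t:
            paths.append(list(visited))
            return
        for nb in _neighbors(w, node):
            if nb not in visited:
                visited.append(nb)
                dfs(nb, visited)
                visited.pop()

    dfs(s, [s])
    return paths


def path_length(w: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))


def shortest_distance_and_hops(w: np.ndarray, s: int, t: int) -> tuple[float, float]:
    """Min distance on lengths 1/w; min hop count among tied shortest paths."""
    paths = enumerate_simple_paths(w, s, t)
    if not paths:
        return math.inf, math.inf
    dists = [path_length(w, p) for p in paths]
    dmin = min(dists)
    hmin = min(len(p) - 1 for p, d in zip(paths, dists) if d <= dmin + TOL)
    return dmin, float(hmin)


def global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2 or w.max() == 0:
        return 0.0
    wn = w / w.max()
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            d, _ = shortest_distance_and_hops(wn, s, t)
            if math.isfinite(d):
                total += 1.0 / d
    return total / (n * (n - 1))


def local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if w.max() == 0:
        return 0.0
    wn = w / w.max()
    vals = []
    for i in range(n):
        nb = _neighbors(w, i)
        if len(nb) < 2:
            vals.append(0.0)
            continue
        sub = wn[np.ix_(nb, nb)]
        k = len(nb)
        total = 0.0
        for s in range(k):
            for t in range(k):
                if s == t:
                    continue
                d, _ = shortest_distance_and_hops(sub, s, t)
                if math.isfinite(d):
                    total += 1.0 / d
        vals.append(total / (k * (k - 1)))
    return float(np.mean(vals))


def char_path_and_edge_count(w: np.ndarray) -> tuple[float, float]:
    n = w.shape[0]
    dists, hops = [], []
    for s in range(n):
        for t in range(s + 1, n):
            d, h = shortest_distance_and_hops(w, s, t)
            if math.isfinite(d):
                dists.append(d)
                hops.append(h)
    if not dists:
        return math.nan, math.nan
    return float(np.mean(dists)), float(np.mean(hops))


def betweenness(w: np.ndarray) -> np.ndarray:
    """Raw betweenness with exact fractional counting of tied paths."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(w, s, t)
            if not paths:
                continue
            dists = [path_length(w, p) for p in paths]
            dmin = min(dists)
            shortest = [p for p, d in zip(paths, dists) if d <= dmin + TOL]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                bc[v] += through / sigma
    return bc


def onnela_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    if w.max() == 0:
        return 0.0
    wn = w / w.max()
    vals = []
    for i in range(n):
        nb = _neighbors(w, i)
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        s = 0.0
        for j, h in itertools.combinations(nb, 2):
            if w[j, h] > 0:
                s += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        vals.append(2.0 * s / (k * (k - 1)))
    return float(np.mean(vals))


def assortativity(w: np.ndarray) -> float:
    deg = [len(_neighbors(w, i)) for i in range(w.shape[0])]
    xs, ys = [], []
    for i in range(w.shape[0]):
        for j in range(w.shape[0]):
            if i != j and w[i, j] > 0:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return math.nan
    xs_a, ys_a = np.array(xs, dtype=float), np.array(ys, dtype=float)
    if xs_a.std() == 0 or ys_a.std() == 0:
        return math.nan
    return float(
        np.mean((xs_a - xs_a.mean()) * (ys_a - ys_a.mean())) / (xs_a.std() * ys_a.std())
    )


def modularity(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    two_m = w.sum()
    if two_m == 0:
        return math.nan
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += (w[i, j] - gamma * k[i] * k[j] / two_m) / two_m
    return q


def participation(w: np.ndarray, labels: np.ndarray) -> float:
    n = w.shape[0]
    vals = []
    for i in range(n):
        k = w[i].sum()
        if k == 0:
            vals.append(0.0)
            continue
        acc = 0.0
        for c in set(labels.tolist()):
            kc = sum(w[i, j] for j in range(n) if labels[j] == c)
            acc += (kc / k) ** 2
        vals.append(1.0 - acc)
    return float(np.mean(vals))


def rich_club_curve(w: np.ndarray) -> np.ndarray:
    """phi_w(k) by explicit edge-list construction at every degree level."""
    n = w.shape[0]
    deg = [len(_neighbors(w, i)) for i in range(n)]
    kmax = max(deg, default=0)
    all_weights = sorted(
        (w[i, j] for i in range(n) for j in range(i + 1, n) if w[i, j] > 0),
        reverse=True,
    )
    phi = np.full(max(kmax - 1, 0), np.nan)
    for k in range(1, kmax):
        rich_nodes = [i for i in range(n) if deg[i] > k]
        sub_edges = [
            w[i, j]
            for a, i in enumerate(rich_nodes)
            for j in rich_nodes[a + 1 :]
            if w[i, j] > 0
        ]
        if not sub_edges:
            continue
        phi[k - 1] = sum(sub_edges) / sum(all_weights[: len(sub_edges)])
    return phi


def best_matching_size(adm: np.ndarray) -> int:
    """Maximum-cardinality bipartite matching by exhaustive search."""
    n_a, n_b = adm.shape
    best = 0
    cols = list(range(n_b))
    for r in range(min(n_a, n_b), 0, -1):
        for rows in itertools.combinations(range(n_a), r):
            for perm in itertools.permutations(cols, r):
                if all(adm[i, j] for i, j in zip(rows, perm)):
                    return r
        # no matching of size r; try r - 1
    return best


def random_weighted_graph(rng: np.random.Generator, n: int, max_weight: int = 3,
                          p_edge: float = 0.5) -> np.ndarray:
    """Random symmetric integer-weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = float(rng.integers(1, max_weight + 1))
    return w
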
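"""Twelve weighted network measures of the structural connectome.

All measures operate on validated, thresholded connectomes (symmetric,
non-negative, zero diagonal). Conventions follow the Brain Connectivity
Toolbox for weighted undirected graphs:

* shortest-path measures map weights to lengths as ``l = 1/w`` on
  strictly positive edges (stronger connections are shorter);
* global and local efficiency first normalize weights by the matrix
  maximum, so both lie in [0, 1];
* clustering is the Onnela coefficient on max-normalized weights;
* assortativity correlates the *binary* degrees at edge endpoints;
* the rich-club curve phi_w(k) is the weight inside the >k-degree
  subgraph divided by the summed E_k strongest weights of the whole graph.

A measure that is undefined on a given graph (e.g. path length of a graph
with no finite pair, assortativity of a regular graph) is reported as NaN
("undefined-flag"); no measure raises on disconnected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from connharm.io import Cohort, Connectome

#: fixed field order of the measure vector; also the prediction-head order
MEASURE_NAMES: tuple[str, ...] = (
    "modularity",
    "avg_betweenness",
    "assortativity",
    "avg_participation",
    "avg_clustering",
    "avg_strength",
    "avg_local_efficiency",
    "global_efficiency",
    "density",
    "rich_club",
    "char_path_length",
    "edge_count",
)

#: float tolerance when deciding that two path lengths tie
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class MeasureVector:
    """The 12 network measures of one connectome; NaN marks undefined."""

    modularity: float
    avg_betweenness: float
    assortativity: float
    avg_participation: float
    avg_clustering: float
    avg_strength: float
    avg_local_efficiency: float
    global_efficiency: float
    density: float
    rich_club: float
    char_path_length: float
    edge_count: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MEASURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "MeasureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(MEASURE_NAMES),):
            raise ValueError(f"expected {len(MEASURE_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(MEASURE_NAMES, values.tolist())))


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every node to exactly one community."""

    assignment: Mapping[int, int]
    n_communities: int

    def labels(self, n: int) -> np.ndarray:
        return np.array([self.assignment[i] for i in range(n)], dtype=int)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _weights(conn: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(conn, Connectome):
        return conn.weights
    return np.asarray(conn, dtype=float)


def _length_graph(w: np.ndarray) -> csr_array:
    """Sparse graph of lengths 1/w on positive edges."""
    lengths = np.zeros_like(w)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    return csr_array(lengths)


def _nx_graph(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(w, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        g.add_edge(i, j, weight=w[i, j], length=1.0 / w[i, j])
    return g


# ---------------------------------------------------------------------------
# individual measures
# ---------------------------------------------------------------------------


def density(conn: Connectome | np.ndarray) -> float:
    """Fraction of possible edges that are present (weight > 0)."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(w[iu] > 0) / len(iu[0]))


def avg_strength(conn: Connectome | np.ndarray) -> float:
    """Mean node strength (row sum of weights)."""
    w = _weights(conn)
    return float(np.mean(w.sum(axis=1)))


def global_efficiency(conn: Connectome | np.ndarray) -> float:
    """Mean inverse shortest-path distance on max-normalized weights.

    Disconnected pairs contribute 0; an edgeless graph has efficiency 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        return 0.0
    wmax = w.max()
    if wmax == 0:
        return 0.0
    d = dijkstra(_length_graph(w / wmax), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def avg_local_efficiency(conn: Connectome | np.ndarray) -> float:
    """Mean, over nodes, of the efficiency of the neighbor-induced subgraph.

    Weights are normalized by the whole-matrix maximum once, so nodal values
    stay in [0, 1]; nodes with fewer than two neighbors score 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    wn = w / wmax
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(wn[i] > 0)
        if nb.size < 2:
            continue
        sub = wn[np.ix_(nb, nb)]
        k = nb.size
        d = dijkstra(_length_graph(sub), directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        vals[i] = inv.sum() / (k * (k - 1))
    return float(vals.mean())


def _lex_shortest_paths(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (distance, hops) minimizing distance, then hop count.

    Floyd–Warshall on the length matrix ``1/w`` with a lexicographic
    tie-break: among equal-length shortest paths (within ``_TIE_TOL``) the
    one with fewer edges is preferred. Returns (dist, hops); unreachable
    pairs have dist = inf.
    """
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    hops = np.full((n, n), np.inf)
    pos = w > 0
    dist[pos] = 1.0 / w[pos]
    hops[pos] = 1.0
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(hops, 0.0)
    for k in range(n):
        alt_d = dist[:, k, None] + dist[None, k, :]
        alt_h = hops[:, k, None] + hops[None, k, :]
        with np.errstate(invalid="ignore"):
            shorter = alt_d < dist - _TIE_TOL
            tie = (np.abs(alt_d - dist) <= _TIE_TOL) & (alt_h < hops)
        upd = shorter | tie
        dist = np.where(shorter, alt_d, dist)
        hops = np.where(upd, alt_h, hops)
    return dist, hops


def char_path_and_edge_count(conn: Connectome | np.ndarray) -> tuple[float, float]:
    """Characteristic path length and mean hop count of those paths.

    Both are means over unordered node pairs at finite distance on lengths
    ``1/w`` (raw weights). Among tied shortest paths the minimal hop count
    is used. (NaN, NaN) when no finite pair exists.
    """
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        return (float("nan"), float("nan"))
    dist, hops = _lex_shortest_paths(w)
    iu = np.triu_indices(n, k=1)
    d, h = dist[iu], hops[iu]
    finite = np.isfinite(d)
    if not finite.any():
        return (float("nan"), float("nan"))
    return (float(d[finite].mean()), float(h[finite].mean()))


def avg_clustering(conn: Connectome | np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient on max-normalized weights."""
    w = _weights(conn)
    if w.max() == 0:
        return 0.0
    g = _nx_graph(w)
    cc = nx.clustering(g, weight="weight")
    return float(np.mean(list(cc.values())))


def avg_betweenness(conn: Connectome | np.ndarray) -> float:
    """Mean raw (unnormalized) weighted betweenness on lengths 1/w.

    Equal-length parallel shortest paths are handled by Brandes fractional
    dependency accumulation.
    """
    w = _weights(conn)
    if w.max() == 0:
        return 0.0
    g = _nx_graph(w)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return float(np.mean(list(bc.values())))


def assortativity(conn: Connectome | np.ndarray) -> float:
    """Pearson correlation of binary degrees at edge endpoints.

    Every edge is counted in both orientations. NaN when the endpoint
    degrees have zero variance (e.g. any regular graph).
    """
    w = _weights(conn)
    deg = (w > 0).sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(w, k=1))
    if iu.size == 0:
        return float("nan")
    x = np.concatenate([deg[iu], deg[ju]])
    y = np.concatenate([deg[ju], deg[iu]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    return float(r)


def modularity_value(
    conn: Connectome | np.ndarray,
    partition: Partition | Sequence[int],
    gamma: float = 1.0,
) -> float:
    """Weighted Newman modularity Q of a given partition.

    ``Q = (1/2m) * sum_ij (w_ij - gamma * k_i k_j / 2m) * delta(c_i, c_j)``
    with ``2m`` the total weight and ``k`` node strengths.
    """
    w = _weights(conn)
    n = w.shape[0]
    labels = (
        partition.labels(n) if isinstance(partition, Partition) else np.asarray(partition)
    )
    two_m = w.sum()
    if two_m == 0:
        return float("nan")
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() / two_m - gamma * (k[idx].sum() / two_m) ** 2
    return float(q)


def modularity_louvain(
    conn: Connectome | np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[Partition | None, float]:
    """Best-of-``n_restarts`` seeded Louvain community detection.

    Returns the winning partition and its modularity Q; (None, NaN) on an
    edgeless graph. Deterministic given ``seed``.
    """
    w = _weights(conn)
    if w.max() == 0:
        return None, float("nan")
    g = _nx_graph(w)
    best_q, best_labels = -np.inf, None
    for r in range(n_restarts):
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed + r
        )
        labels = np.empty(w.shape[0], dtype=int)
        for cid, nodes in enumerate(communities):
            for node in nodes:
                labels[node] = cid
        q = modularity_value(w, labels, gamma=gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    partition = Partition(
        assignment={i: int(c) for i, c in enumerate(best_labels)},
        n_communities=int(best_labels.max()) + 1,
    )
    return partition, float(best_q)


def avg_participation(
    conn: Connectome | np.ndarray, partition: Partition | Sequence[int]
) -> float:
    """Mean participation coefficient ``P_i = 1 - sum_c (k_ic / k_i)^2``.

    Computed with strengths; isolated nodes score 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    labels = (
        partition.labels(n) if isinstance(partition, Partition) else np.asarray(partition)
    )
    k = w.sum(axis=1)
    p = np.zeros(n)
    nonzero = k > 0
    for c in np.unique(labels):
        kc = w[:, labels == c].sum(axis=1)
        p[nonzero] += (kc[nonzero] / k[nonzero]) ** 2
    out = np.zeros(n)
    out[nonzero] = 1.0 - p[nonzero]
    return float(out.mean())


def rich_club_curve(conn: Connectome | np.ndarray) -> np.ndarray:
    """Weighted rich-club coefficient phi_w(k) for k = 1..max_degree-1.

    At level k, restrict to nodes of binary degree > k; phi_w(k) is the
    summed weight of the edges among them divided by the sum of the E_k
    strongest edge weights of the whole network, E_k being the number of
    edges in the restricted subgraph. Levels with no such edge are NaN.
    """
    w = _weights(conn)
    deg = (w > 0).sum(axis=1)
    kmax = int(deg.max(initial=0))
    if kmax < 2:
        return np.full(max(kmax - 1, 0), np.nan)
    iu = np.triu_indices(w.shape[0], k=1)
    ranked = np.sort(w[iu][w[iu] > 0])[::-1]
    cum = np.concatenate([[0.0], np.cumsum(ranked)])
    phi = np.full(kmax - 1, np.nan)
    for k in range(1, kmax):
        rich = deg > k
        sub = w[np.ix_(rich, rich)]
        e = int(np.count_nonzero(np.triu(sub, k=1) > 0))
        if e == 0:
            continue
        phi[k - 1] = np.triu(sub, k=1).sum() / cum[e]
    return phi


def rich_club(
    conn: Connectome | np.ndarray,
    reduction: str = "mean",
    k: int | None = None,
) -> float:
    """Scalar rich-club summary: mean of the defined phi_w(k) (default),
    the highest-k defined value (``max_k``), or the value at a fixed ``k``."""
    phi = rich_club_curve(conn)
    defined = np.isfinite(phi)
    if not defined.any():
        return float("nan")
    if reduction == "mean":
        return float(phi[defined].mean())
    if reduction == "max_k":
        return float(phi[np.flatnonzero(defined)[-1]])
    if reduction == "fixed_k":
        if k is None or not (1 <= k <= len(phi)) or not np.isfinite(phi[k - 1]):
            return float("nan")
        return float(phi[k - 1])
    raise ValueError(f"unknown rich-club reduction {reduction!r}")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def all_measures(
    conn: Connectome | np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
    rich_club_reduction: str = "mean",
) -> MeasureVector:
    """Compute the full 12-measure vector; never raises on degenerate graphs.

    The Louvain partition found for modularity is reused for the
    participation coefficient. Deterministic given ``seed``.
    """
    w = _weights(conn)
    partition, q = modularity_louvain(w, gamma=gamma, seed=seed)
    cpl, ec = char_path_and_edge_count(w)
    return MeasureVector(
        modularity=q,
        avg_betweenness=avg_betweenness(w),
        assortativity=assortativity(w),
        avg_participation=(
            avg_participation(w, partition) if partition is not None else float("nan")
        ),
        avg_clustering=avg_clustering(w),
        avg_strength=avg_strength(w),
        avg_local_efficiency=avg_local_efficiency(w),
        global_efficiency=global_efficiency(w),
        density=density(w),
        rich_club=rich_club(w, reduction=rich_club_reduction),
        char_path_length=cpl,
        edge_count=ec,
    )


def measures_table(
    cohort: Cohort,
    gamma: float = 1.0,
    seed: int = 0,
    rich_club_reduction: str = "mean",
) -> pd.DataFrame:
    """Per-subject measure table: subject_id, site, then the 12 measures."""
    rows = []
    for rec in cohort:
        mv = all_measures(
            rec.connectome,
            gamma=gamma,
            seed=seed,
            rich_club_reduction=rich_club_reduction,
        )
        rows.append(
            {"subject_id": rec.subject_id, "site": rec.site}
            | dict(zip(MEASURE_NAMES, mv.to_array().tolist()))
        )
    return pd.DataFrame(rows, columns=["subject_id", "site", *MEASURE_NAMES])
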
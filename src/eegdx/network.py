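"""Functional-connectivity graphs and their topology metrics.

Per epoch, the 19 x 19 matrix of absolute Pearson correlations between
channels is thresholded into a binary undirected graph, from which five
features derive:

* mean degree  k_bar
* clustering coefficient  C = mean_i 2 e_i / (k_i (k_i - 1))  (C_i = 0
  when k_i < 2)
* characteristic path length  L = mean over connected ordered pairs of
  the shortest-path edge count (disconnected pairs excluded, with the
  connected fraction logged)
* global efficiency  E = mean over ordered pairs of 1 / l_ij, with
  1/inf = 0 for disconnected pairs
* small-worldness  sigma = gamma / delta, where gamma = C / <C_null> and
  delta = L / <L_null> over degree-preserving rewired null graphs.

Implemented directly on adjacency matrices (numpy + scipy.sparse.csgraph);
the formulas are simple enough that the null-model rewiring is the only
non-trivial piece.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger("eegdx")


@dataclass
class NetworkConfig:
    """Connectivity binarization and null-model settings."""

    threshold: float = 0.7
    n_random: int = 20
    swap_factor: int = 10  # rewiring attempts per null = swap_factor * |E|

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swap_factor < 1:
            raise ValueError("swap_factor must be >= 1")


def connectivity(data: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between channels, zero diagonal.

    ``data`` is a channels x samples epoch.  A constant channel has
    undefined correlations; its row and column are set to 0 with a
    logged notice.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 channels")
    constant = data.max(axis=1) == data.min(axis=1)
    if constant.any():
        logger.info("connectivity: %d constant channel(s); correlations "
                    "set to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    corr = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return corr


def binarize(conn: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Edge (i, j) iff conn[i, j] >= threshold (boundary included)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    adj = (conn >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def mean_degree(adj: np.ndarray) -> float:
    return float(adj.sum(axis=1).mean())


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean over nodes of C_i = 2 e_i / (k_i (k_i - 1)); C_i = 0 if k_i < 2."""
    a = adj.astype(float)
    k = a.sum(axis=1)
    e = np.diag(a @ a @ a) / 2.0  # edges among the neighbors of each node
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(k >= 2, 2.0 * e / (k * (k - 1.0)), 0.0)
    return float(c.mean())


def _pairwise_lengths(adj: np.ndarray) -> np.ndarray:
    d = shortest_path(csr_matrix(adj), method="D", directed=False,
                      unweighted=True)
    return d


def path_length(adj: np.ndarray) -> float:
    """Characteristic path length over connected ordered pairs.

    Disconnected pairs are excluded from the average (the connected
    fraction is logged).  A graph with no edges has no defined path
    length and returns NaN (flagged missing feature).
    """
    if adj.sum() == 0:
        logger.info("path_length: empty graph; feature undefined")
        return float("nan")
    d = _pairwise_lengths(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    frac = finite.sum() / off.sum()
    if frac < 1.0:
        logger.debug("path_length: %.0f%% of pairs connected", 100 * frac)
    return float(d[finite].mean())


def global_efficiency(adj: np.ndarray) -> float:
    """Mean reciprocal shortest-path length over ordered pairs (1/inf = 0)."""
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if adj.sum() == 0:
        return 0.0
    d = _pairwise_lengths(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


@njit(cache=False)
def _rewire(adj: np.ndarray, edges: np.ndarray,
            choices: np.ndarray) -> None:
    """In-place degree-preserving double-edge swaps.

    ``choices`` is a (attempts, 2) array of random edge indices; a swap
    of edges (a, b) and (c, d) into (a, d) and (c, b) is applied when it
    creates neither self-loops nor duplicate edges.
    """
    n_edges = edges.shape[0]
    for t in range(choices.shape[0]):
        e1 = choices[t, 0] % n_edges
        e2 = choices[t, 1] % n_edges
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 1] = d
        edges[e2, 1] = b


def rewired_null(adj: np.ndarray, rng: np.random.Generator,
                 swap_factor: int = 10) -> np.ndarray:
    """One degree-preserving randomised copy of the graph."""
    null = adj.astype(np.int8).copy()
    edges = np.argwhere(np.triu(null, k=1) > 0).astype(np.int64)
    if len(edges) < 2:
        return null
    attempts = swap_factor * len(edges)
    choices = rng.integers(0, len(edges), size=(attempts, 2)).astype(np.int64)
    _rewire(null, edges, choices)
    return null


def small_worldness(adj: np.ndarray, n_random: int = 20, seed: int = 0,
                    swap_factor: int = 10) -> float:
    """sigma = gamma / delta against degree-preserving rewired nulls.

    gamma = C / <C_null>, delta = L / <L_null> over ``n_random`` seeded
    null graphs.  A complete graph cannot be rewired: the null equals
    the original and sigma is 1.  If the metrics are undefined (empty or
    clustering-free graph, or clustering-free nulls), NaN is returned
    and the feature flagged missing.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    n = adj.shape[0]
    n_edges = int(adj.sum()) // 2
    if n_edges == n * (n - 1) // 2:
        logger.info("small_worldness: complete graph; null equals original, "
                    "sigma = 1")
        return 1.0
    c = clustering_coefficient(adj)
    length = path_length(adj)
    if not np.isfinite(length):
        return float("nan")
    c_null = np.empty(n_random)
    l_null = np.empty(n_random)
    for i in range(n_random):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(seed), i)))
        null = rewired_null(adj, rng, swap_factor)
        c_null[i] = clustering_coefficient(null)
        l_null[i] = path_length(null)
    c_bar = c_null.mean()
    l_bar = np.nanmean(l_null)
    if c_bar == 0 or c == 0 or not np.isfinite(l_bar) or l_bar == 0:
        logger.info("small_worldness: undefined (clustering or null path "
                    "length degenerate)")
        return float("nan")
    gamma = c / c_bar
    delta = length / l_bar
    return float(gamma / delta)


def network_features(epoch_data: np.ndarray,
                     cfg: NetworkConfig | None = None,
                     seed: int = 0) -> dict[str, float]:
    """All five graph features of one epoch's channel matrix."""
    cfg = cfg or NetworkConfig()
    cfg.validate()
    conn = connectivity(epoch_data)
    adj = binarize(conn, cfg.threshold)
    return {
        "mean_degree": mean_degree(adj),
        "clustering": clustering_coefficient(adj),
        "path_length": path_length(adj),
        "efficiency": global_efficiency(adj),
        "small_worldness": small_worldness(
            adj, n_random=cfg.n_random, seed=seed,
            swap_factor=cfg.swap_factor),
    }
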
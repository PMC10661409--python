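"""Naive direct-from-formula reference implementations.

These deliberately mirror the defining equations with explicit template
enumeration (numpy broadcasting over the full pairwise distance matrix),
independently of the package's JIT-compiled kernels, and serve as the
oracles in equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


def naive_apen(x: np.ndarray, m: int, r: float) -> float:
    """ApEn via explicit phi^m - phi^{m+1}, self-matches included."""
    x = np.asarray(x, dtype=float)

    def phi(mm: int) -> float:
        nt = len(x) - mm + 1
        templates = np.array([x[i:i + mm] for i in range(nt)])
        d = np.max(np.abs(templates[:, None, :] - templates[None, :, :]),
                   axis=2)
        c = (d <= r).sum(axis=1) / nt
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def naive_sampen(x: np.ndarray, m: int, r: float) -> float:
    """SampEn via pair counting over i < j, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    nt = len(x) - m

    def count(mm: int) -> int:
        templates = np.array([x[i:i + mm] for i in range(nt)])
        d = np.max(np.abs(templates[:, None, :] - templates[None, :, :]),
                   axis=2)
        iu = np.triu_indices(nt, k=1)
        return int((d[iu] <= r).sum())

    b_m = count(m)
    b_m1 = count(m + 1)
    if b_m == 0 or b_m1 == 0:
        return float("nan")
    return -math.log(b_m1 / b_m)


def naive_permen(x: np.ndarray, n: int) -> float:
    """PermEn by literal window enumeration and stable rank tallying."""
    x = np.asarray(x, dtype=float)
    tallies: dict[tuple, int] = {}
    for i in range(len(x) - n + 1):
        window = x[i:i + n]
        pattern = tuple(sorted(range(n), key=lambda k: (window[k], k)))
        tallies[pattern] = tallies.get(pattern, 0) + 1
    total = sum(tallies.values())
    return -sum((c / total) * math.log(c / total) for c in tallies.values())


def naive_mse(x: np.ndarray, m: int, r_factor: float, tau: int) -> float:
    """MSE by hand coarse-graining then naive SampEn (r from original SD)."""
    x = np.asarray(x, dtype=float)
    n_coarse = len(x) // tau
    coarse = np.array([x[j * tau:(j + 1) * tau].mean()
                       for j in range(n_coarse)])
    return naive_sampen(coarse, m, r_factor * x.std())


def brute_clustering(adj: np.ndarray) -> float:
    """Mean clustering by direct neighbor-pair enumeration."""
    n = adj.shape[0]
    cs = []
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]]
        k = len(neigh)
        if k < 2:
            cs.append(0.0)
            continue
        e = sum(adj[a, b] for ai, a in enumerate(neigh)
                for b in neigh[ai + 1:])
        cs.append(2.0 * e / (k * (k - 1)))
    return float(np.mean(cs))


def brute_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """All-pairs BFS edge counts (inf when unreachable)."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def brute_path_length(adj: np.ndarray) -> float:
    d = brute_shortest_paths(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_efficiency(adj: np.ndarray) -> float:
    d = brute_shortest_paths(adj)
    n = adj.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))
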
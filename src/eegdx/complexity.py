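"""Entropy measures of signal regularity: ApEn, PermEn, SampEn, MSE.

All four quantify how predictable a time series is; they fall in AD EEG,
reflecting simpler cortical dynamics.  Conventions used here:

* Template distance is Chebyshev (maximum coordinate difference).
* ApEn (Pincus): self-matches are included, so the count ratio is always
  positive; ``ApEn = phi_m - phi_{m+1}`` with
  ``phi_m = mean_k ln(count_k / (N - m + 1))``.
* SampEn (Richman-Moorman): self-matches excluded; ``N - m`` templates
  at both lengths; ``SampEn = -ln(B_{m+1} / B_m)`` over pair counts.
  If no pair matches at length ``m+1`` the value is undefined and NaN is
  returned (callers drop the epoch).
* The tolerance r defaults to ``r_factor`` times the population SD of
  the series it is applied to.
* PermEn uses natural log and is not normalised; ordinal ties are broken
  earlier-index-first.
* MSE coarse-grains with non-overlapping means of ``tau`` samples, then
  applies SampEn; r is anchored to the SD of the original series.

The pairwise-template loops are JIT-compiled with numba; tests compare
them against naive direct-from-formula implementations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger("eegdx")


@dataclass
class EntropyConfig:
    """Parameters of the four entropies (m, r, n, tau)."""

    apen_m: int = 1
    apen_r_factor: float = 0.2
    permen_order: int = 3
    sampen_m: int = 2
    sampen_r_factor: float = 0.15
    mse_m: int = 2
    mse_r_factor: float = 0.15
    mse_tau: int = 5
    #: recompute r on the coarse-grained series instead of the original
    mse_r_on_coarse: bool = False
    #: average SampEn over scales 1..tau instead of the single scale tau
    mse_average_scales: bool = False

    def validate(self) -> None:
        if self.apen_m < 1 or self.sampen_m < 1 or self.mse_m < 1:
            raise ValueError("pattern length m must be >= 1")
        for rf in (self.apen_r_factor, self.sampen_r_factor,
                   self.mse_r_factor):
            if not 0 < rf < 1:
                raise ValueError("r_factor must be in (0, 1)")
        if self.permen_order < 2:
            raise ValueError("permutation order n must be >= 2")
        if self.mse_tau < 1:
            raise ValueError("tau must be >= 1")


@njit(cache=False)
def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    n = x.size
    nt = n - m + 1
    total = 0.0
    for k in range(nt):
        count = 0
        for l in range(nt):
            d = 0.0
            for i in range(m):
                diff = abs(x[k + i] - x[l + i])
                if diff > d:
                    d = diff
            if d <= r:
                count += 1
        total += math.log(count / nt)
    return total / nt


@njit(cache=False)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.size
    nt = n - m
    b_m = 0
    b_m1 = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b_m += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    b_m1 += 1
    return b_m, b_m1


def _resolve_r(x: np.ndarray, r: float | None, r_factor: float) -> float:
    return float(r_factor * x.std()) if r is None else float(r)


def apen(series: np.ndarray, m: int = 1, r: float | None = None,
         r_factor: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    ``r`` defaults to ``r_factor`` times the population SD of the
    series.  A constant series (r = 0 under the relative rule) is
    defined to have ApEn 0.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need N > m + 1 (N={x.size}, m={m})")
    r = _resolve_r(x, r, r_factor)
    if r <= 0:
        logger.info("ApEn: zero tolerance (constant series); returning 0")
        return 0.0
    return float(_apen_phi(x, m, r) - _apen_phi(x, m + 1, r))


def sampen(series: np.ndarray, m: int = 2, r: float | None = None,
           r_factor: float = 0.15) -> float:
    """Sample entropy SampEn(m, r) = -ln(B_{m+1}/B_m), self-matches excluded.

    Returns NaN when no template pair matches at length ``m + 1`` (the
    value is undefined; downstream code drops such epochs).
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need N > m + 1 (N={x.size}, m={m})")
    r = _resolve_r(x, r, r_factor)
    if r < 0:
        raise ValueError("r must be >= 0")
    b_m, b_m1 = _sampen_counts(x, m, r)
    if b_m == 0 or b_m1 == 0:
        return float("nan")
    return float(-math.log(b_m1 / b_m))


def ordinal_patterns(series: np.ndarray, n: int) -> np.ndarray:
    """Integer code of the ordinal pattern of each length-n window.

    Each window maps to the permutation that sorts it; ties are broken
    earlier-index-first (stable sort).
    """
    x = np.asarray(series, dtype=float)
    windows = np.lib.stride_tricks.sliding_window_view(x, n)
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = np.zeros(len(windows), dtype=np.int64)
    for col in range(n):
        codes = codes * n + ranks[:, col]
    return codes


def permen(series: np.ndarray, n: int = 3) -> float:
    """Permutation entropy: Shannon entropy (nats) of ordinal patterns.

    Unnormalised; ranges over [0, ln(n!)].  An all-equal series has a
    single ordinal pattern under the tie rule and returns 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < n:
        raise ValueError(f"need N >= n (N={x.size}, n={n})")
    if np.all(x == x[0]):
        logger.info("PermEn: all-equal series; single pattern, returning 0")
        return 0.0
    codes = ordinal_patterns(x, n)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping means of ``tau`` consecutive samples."""
    x = np.asarray(series, dtype=float)
    n = (x.size // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def mse(series: np.ndarray, m: int = 2, r_factor: float = 0.15,
        tau: int = 5, r_on_coarse: bool = False,
        average_scales: bool = False) -> float:
    """Multiscale entropy: SampEn of the coarse-grained series at scale tau.

    By default the tolerance r is ``r_factor`` times the SD of the
    *original* series; set ``r_on_coarse`` to recompute it per scale.
    ``average_scales`` averages SampEn over scales 1..tau instead of
    reporting the single scale tau.
    """
    x = np.asarray(series, dtype=float)
    # the coarse series needs headroom beyond the bare SampEn minimum of
    # m+2 samples, otherwise the estimate rests on a single template pair
    if x.size // tau <= m + 2:
        raise ValueError(
            f"coarse series too short: floor({x.size}/{tau}) must exceed "
            f"m + 2 = {m + 2}")
    r_orig = r_factor * x.std()
    scales = range(1, tau + 1) if average_scales else (tau,)
    values = []
    for t in scales:
        coarse = coarse_grain(x, t)
        r = r_factor * coarse.std() if r_on_coarse else r_orig
        values.append(sampen(coarse, m=m, r=r))
    return float(np.mean(values))
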
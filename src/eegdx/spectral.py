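"""Spectral features: time-domain statistics and Welch relative band power.

Relative band power (RBP) of rhythm i is its PSD energy divided by the
total energy over 0.5-45 Hz:

    RBP_i = Energy_i / sum_j Energy_j ,   i in {delta, theta, alpha, beta, gamma}

Energies are trapezoidal integrals of the one-sided Welch density over
each band, with the density linearly interpolated at the band edges so
the five bands tile 0.5-45 Hz exactly and RBP sums to 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import trapezoid


@dataclass(frozen=True)
class BandDefinition:
    """One EEG rhythm as a half-open frequency interval [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("gamma", 25.0, 45.0),
)


def validate_bands(bands: tuple[BandDefinition, ...]) -> None:
    """Bands must be ordered, non-overlapping and contiguous."""
    if not bands:
        raise ValueError("at least one band required")
    for b in bands:
        if not b.lo_hz < b.hi_hz:
            raise ValueError(f"band {b.name}: need lo_hz < hi_hz")
    for a, b in zip(bands, bands[1:]):
        if a.hi_hz != b.lo_hz:
            raise ValueError(
                f"bands {a.name} and {b.name} must be contiguous "
                f"({a.hi_hz} != {b.lo_hz})")


@dataclass
class WelchSettings:
    """Welch estimator settings: 1-s Hamming segments, 50% overlap."""

    segment_s: float = 1.0
    overlap_fraction: float = 0.5
    window: str = "hamming"
    detrend: str = "constant"


@dataclass
class SpectralConfig:
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    welch: WelchSettings = field(default_factory=WelchSettings)


def time_domain(x: np.ndarray) -> tuple[float, float, float]:
    """Mean, variance (N-1 denominator) and interquartile range.

    The IQR uses the linear-interpolation quantile rule (numpy's
    default, "type 7"): for ``[1, 2, 3, 4]`` it equals 1.5.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples (variance undefined)")
    q1, q3 = np.percentile(x, [25, 75])
    return float(x.mean()), float(x.var(ddof=1)), float(q3 - q1)


def welch_psd(x: np.ndarray, fs: float,
              settings: WelchSettings | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of one epoch channel."""
    settings = settings or WelchSettings()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(settings.segment_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"series ({x.size} samples) shorter than one Welch segment "
            f"({nperseg})")
    noverlap = int(round(nperseg * settings.overlap_fraction))
    freqs, psd = signal.welch(
        x, fs=fs, window=settings.window, nperseg=nperseg,
        noverlap=noverlap, detrend=settings.detrend)
    return freqs, psd


def band_energy(freqs: np.ndarray, density: np.ndarray,
                lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi].

    Interior frequency samples are combined with linearly interpolated
    density values at the band edges, so adjacent bands tile the axis.
    """
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inside], [hi]))
    d = np.concatenate(([np.interp(lo, freqs, density)],
                        density[inside],
                        [np.interp(hi, freqs, density)]))
    return float(trapezoid(d, f))


def relative_band_power(
    freqs: np.ndarray, density: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> tuple[dict[str, float], float]:
    """RBP per band plus the total power over the covered range.

    Raises ``ValueError`` on an identically zero density (degenerate
    epoch; RBP undefined).
    """
    validate_bands(bands)
    energies = {b.name: band_energy(freqs, density, b.lo_hz, b.hi_hz)
                for b in bands}
    total = sum(energies.values())
    if total <= 0:
        raise ValueError("zero spectral density: RBP undefined "
                         "(degenerate epoch)")
    return {name: e / total for name, e in energies.items()}, total
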
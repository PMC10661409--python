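"""Seeded generator for CN-like and AD-like resting-state EEG cohorts.

The generator emulates the three effect families that distinguish AD from
control EEG — spectral slowing, reduced signal complexity, and decreased
inter-channel synchrony — with one knob per family:

``band_power_profile``
    Target relative power per rhythm (delta, theta, alpha, beta, gamma).
    Shifting mass from alpha/beta/gamma to delta/theta produces slowing.
``regularity``
    AR(1) coefficient applied to every band source before band-pass
    filtering.  A higher coefficient reddens the within-band spectrum,
    making the signal smoother and lowering its entropy.
``coupling`` and ``modularity``
    ``coupling`` is the fraction of each channel's signal drawn from
    latent sources shared across channels.  Shared content is organised
    in two tiers — one global source per rhythm plus one source per
    scalp region (frontal, central, parietal, occipital) — mixed as
    ``sqrt(1 - m) * global + sqrt(m) * regional`` with regional weight
    ``m = modularity * (1 - coupling)``.  At ``coupling=1`` every channel
    reduces to the same global source (all pairwise correlations exactly
    1); at ``coupling=0`` channels are independent.  In between,
    ``modularity`` sets how much more strongly within-region pairs couple
    than cross-region pairs: near 1, thresholded connectivity graphs are
    modular and small-world-like; at 0, coupling is spatially uniform
    and the graphs resemble Erdős–Rényi networks.  The AD-like default
    therefore lowers both knobs: weaker and more random connectivity.

Per-band signals are rescaled so their realized variance fractions match
the requested profile, then summed and topped with independent white
sensor noise.  Amplitudes are nominal microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .core import CHANNELS_10_20, REGIONS_10_20, EEGRecording

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Band edges in Hz used when synthesising band-limited sources.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "gamma": (25.0, 45.0),
}

#: Control-like relative band-power profile (delta, theta, alpha, beta,
#: gamma).  Healthy resting EEG here carries substantial fast (beta/gamma)
#: broadband activity; every band above theta exceeds its AD counterpart.
CN_PROFILE: dict[str, float] = {
    "delta": 0.15, "theta": 0.12, "alpha": 0.25, "beta": 0.28, "gamma": 0.20,
}

#: AD-like profile: elevated delta/theta, attenuated alpha/beta/gamma.
AD_PROFILE: dict[str, float] = {
    "delta": 0.35, "theta": 0.25, "alpha": 0.20, "beta": 0.12, "gamma": 0.08,
}


@dataclass
class GroupSpec:
    """Generative parameters for one subject group.

    Parameters
    ----------
    label
        Group name, conventionally ``"CN"`` or ``"AD"``.
    n_subjects
        Number of recordings to generate for the group.
    duration_s
        Recording length in seconds.
    fs
        Sampling rate in Hz; must exceed twice the top band edge (45 Hz).
    band_power_profile
        Map rhythm name -> target relative power; non-negative, sums to 1.
    regularity
        AR(1) coefficient in ``[0, 0.99)`` applied to band sources.
    coupling
        Fraction in ``[0, 1]`` of each channel drawn from shared sources.
    modularity
        Fraction in ``[0, 1]`` of the shared tier's coupling-dependent
        variance allocated to regional (per-lobe) rather than global
        sources; 0 gives spatially uniform coupling.
    noise_sd
        Scale (microvolts) of channel-independent white sensor noise.
    amplitude_uv
        Target standard deviation (microvolts) of the noise-free signal.
    """

    label: str
    n_subjects: int
    duration_s: float = 120.0
    fs: float = 250.0
    band_power_profile: dict[str, float] = field(
        default_factory=lambda: dict(CN_PROFILE))
    regularity: float = 0.2
    coupling: float = 0.65
    modularity: float = 1.0
    noise_sd: float = 1.5
    amplitude_uv: float = 10.0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.fs <= 2 * 45.0:
            raise ValueError(
                f"fs={self.fs} too low: must exceed 2 x 45 Hz to carry the "
                "gamma band")
        keys = set(self.band_power_profile)
        if keys != set(BAND_NAMES):
            raise ValueError(
                f"band_power_profile must have exactly the keys {BAND_NAMES}")
        vals = np.array([self.band_power_profile[b] for b in BAND_NAMES])
        if np.any(vals < 0):
            raise ValueError("band_power_profile values must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"band_power_profile must sum to 1 (got {vals.sum():.12f})")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 0.0 <= self.modularity <= 1.0:
            raise ValueError("modularity must be in [0, 1]")
        if not 0.0 <= self.regularity < 1.0:
            raise ValueError("regularity must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude_uv must be positive")

    def copy_with(self, **changes) -> "GroupSpec":
        return replace(self, **changes)


def default_specs(
    n_cn: int = 10,
    n_ad: int = 10,
    duration_s: float = 120.0,
    fs: float = 250.0,
) -> tuple[GroupSpec, GroupSpec]:
    """Default CN and AD group specifications for the synthetic cohort."""
    cn = GroupSpec(label="CN", n_subjects=n_cn, duration_s=duration_s, fs=fs,
                   band_power_profile=dict(CN_PROFILE),
                   regularity=0.2, coupling=0.70, modularity=1.0)
    ad = GroupSpec(label="AD", n_subjects=n_ad, duration_s=duration_s, fs=fs,
                   band_power_profile=dict(AD_PROFILE),
                   regularity=0.8, coupling=0.60, modularity=0.0)
    return cn, ad


def _band_source(rng: np.random.Generator, n: int, fs: float,
                 band: str, regularity: float) -> np.ndarray:
    """Unit-variance band-limited source: white -> AR(1) -> band-pass."""
    x = rng.standard_normal(n)
    if regularity > 0:
        x = signal.lfilter([1.0], [1.0, -regularity], x)
    lo, hi = BAND_EDGES[band]
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def generate_recording(spec: GroupSpec, subject_id: str,
                       seed: int) -> EEGRecording:
    """Generate one multichannel recording from a group specification.

    Per rhythm, a global shared source, one shared source per scalp
    region, and one private source per channel are synthesised (white
    noise -> AR(1) -> band-pass -> unit variance).  Channel ``i`` in
    region ``g`` receives, for rhythm ``b``::

        m          = modularity * (1 - c)
        shared_b,i = sqrt(1 - m) * global_b + sqrt(m) * regional_b,g
        x_b,i      = c * shared_b,i + (1 - c) * private_b,i

    where ``c`` is the coupling.  Each ``x_b,i`` is rescaled so its
    variance fraction matches ``band_power_profile[b]``, bands are
    summed, and white noise of scale ``noise_sd`` is added.

    Identical ``(spec, subject_id, seed)`` yield bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    if n <= 0:
        raise ValueError("recording must contain at least one sample")
    c = spec.coupling
    channels = CHANNELS_10_20
    region_of = {ch: name for name, chs in REGIONS_10_20.items() for ch in chs}
    region_names = list(REGIONS_10_20)

    data = np.zeros((len(channels), n))
    for band in BAND_NAMES:
        target_sd = np.sqrt(spec.band_power_profile[band]) * spec.amplitude_uv
        glob = _band_source(rng, n, spec.fs, band, spec.regularity)
        regional = {g: _band_source(rng, n, spec.fs, band, spec.regularity)
                    for g in region_names}
        m = spec.modularity * (1.0 - c)
        shared = {
            g: np.sqrt(1.0 - m) * glob + np.sqrt(m) * regional[g]
            for g in region_names
        }
        for i, ch in enumerate(channels):
            private = _band_source(rng, n, spec.fs, band, spec.regularity)
            x = c * shared[region_of[ch]] + (1.0 - c) * private
            sd = x.std()
            if sd > 0 and target_sd > 0:
                x = x * (target_sd / sd)
            elif target_sd == 0:
                x = np.zeros_like(x)
            data[i] += x
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)

    return EEGRecording(data=data, fs=spec.fs, channel_labels=channels,
                        subject_id=subject_id, group=spec.label,
                        reference="synthetic-average")


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the master seed.

    Uses :class:`numpy.random.SeedSequence` keyed on
    ``(master_seed, subject_index)``; stable across runs and platforms.
    """
    ss = np.random.SeedSequence((int(master_seed), int(subject_index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(cn: GroupSpec, ad: GroupSpec,
                    seed: int) -> list[EEGRecording]:
    """Generate the full two-group cohort.

    Subject ids are ``<label><k>`` (``CN01``, ``AD07``, ...); per-subject
    seeds derive deterministically from the master seed so the cohort is
    reproducible as a whole and per subject.
    """
    cn.validate()
    ad.validate()
    recordings: list[EEGRecording] = []
    ids: set[str] = set()
    index = 0
    for spec in (cn, ad):
        for k in range(spec.n_subjects):
            sid = f"{spec.label}{k + 1:02d}"
            if sid in ids:
                raise ValueError(f"duplicate subject id {sid!r}")
            ids.add(sid)
            recordings.append(
                generate_recording(spec, sid, subject_seed(seed, index)))
            index += 1
    return recordings
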
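"""Core containers for multichannel resting-state EEG.

The pipeline works on three in-memory objects: a continuous
:class:`EEGRecording` (channels x samples, microvolts), a fixed-length
:class:`Epoch` cut from it, and an ordered :class:`EpochSet` that keeps
per-epoch provenance (subject, epoch index, retained flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system, in the
#: conventional anterior-to-posterior order.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Mastoid reference electrodes that accompany the scalp montage in
#: clinical recordings.
REFERENCE_CHANNELS: tuple[str, str] = ("A1", "A2")

#: Coarse anatomical grouping of the scalp electrodes (frontal, left and
#: right temporo-central, parietal, occipital).  Used by the synthetic
#: generator to give inter-channel coupling a regional structure.
REGIONS_10_20: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("T3", "C3", "Cz", "C4", "T4"),
    "parietal": ("T5", "P3", "Pz", "P4", "T6"),
    "occipital": ("O1", "O2"),
}


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names, one per row of ``data``.
    subject_id
        Subject identifier.
    group
        Group label (``"CN"`` or ``"AD"`` in the diagnostic setting).
    reference
        Free-text tag describing the referencing state.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_10_20
    subject_id: str = ""
    group: str = ""
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        self.channel_labels = tuple(self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        """Index of a channel by case-insensitive label match."""
        lowered = [c.lower() for c in self.channel_labels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)


@dataclass
class Epoch:
    """One fixed-length segment of a recording."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str
    group: str
    epoch_index: int
    retained: bool = True

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Ordered collection of equally shaped epochs from one recording."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            shape = self.epochs[0].data.shape
            fs = self.epochs[0].fs
            for ep in self.epochs:
                if ep.data.shape != shape or ep.fs != fs:
                    raise ValueError("all epochs must share shape and fs")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    @property
    def retained(self) -> list[Epoch]:
        return [e for e in self.epochs if e.retained]


def concat_epochsets(sets: Sequence[EpochSet]) -> EpochSet:
    """Concatenate epoch sets from several subjects into one collection."""
    out: list[Epoch] = []
    for s in sets:
        out.extend(s.epochs)
    return EpochSet(out)
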
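"""Preprocessing: re-referencing, band-pass filtering, artifact-window
rejection, and epoching.

The fixed stage order is re-reference -> band-pass -> reject -> epoch.
Artifact handling uses the standard-deviation rule on consecutive 0.5-s
windows: any window where any channel's sample SD exceeds the threshold
(default 17 microvolts) is excised and the remainder concatenated.  This
is a deliberately simple, fully reproducible criterion; no independent
component analysis or artifact subspace reconstruction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import EEGRecording, Epoch, EpochSet, REFERENCE_CHANNELS

logger = logging.getLogger("eegdx")


@dataclass
class PreprocessConfig:
    """Filtering, rejection and epoching parameters.

    Defaults follow the clinical-pipeline convention: a 0.5-45 Hz
    Butterworth band-pass, 0.5-s artifact windows with an SD threshold
    of 17 uV, and 4-s epochs with 50% overlap.
    """

    low_hz: float = 0.5
    high_hz: float = 45.0
    filter_order: int = 4
    artifact_window_s: float = 0.5
    artifact_sd_threshold: float = 17.0
    epoch_length_s: float = 4.0
    overlap_fraction: float = 0.5

    def validate(self, fs: float | None = None) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if fs is not None and self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} violates the Nyquist constraint "
                f"high_hz < fs/2 = {fs / 2}")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.artifact_window_s <= 0 or self.epoch_length_s <= 0:
            raise ValueError("window and epoch lengths must be positive")
        if self.artifact_sd_threshold <= 0:
            raise ValueError("artifact_sd_threshold must be positive")

    def copy_with(self, **changes) -> "PreprocessConfig":
        return replace(self, **changes)


def rereference(rec: EEGRecording,
                ref_labels: tuple[str, str] = REFERENCE_CHANNELS
                ) -> EEGRecording:
    """Re-reference to the mean of two reference channels (e.g. A1-A2).

    The mean of the two reference channels is subtracted from every
    scalp channel and the reference channels are dropped.  A recording
    without either reference channel (the synthetic default) is returned
    unchanged apart from a logged notice; exactly one present is an
    error, since the montage is then ambiguous.
    """
    lowered = {c.lower(): i for i, c in enumerate(rec.channel_labels)}
    idx = [lowered.get(lbl.lower()) for lbl in ref_labels]
    present = [i for i in idx if i is not None]
    if len(present) == 0:
        logger.info("subject %s: no %s channels; re-referencing skipped",
                    rec.subject_id, "/".join(ref_labels))
        return rec
    if len(present) == 1:
        raise ValueError(
            f"only one of the reference channels {ref_labels} is present; "
            "ambiguous montage")
    ref = rec.data[present].mean(axis=0)
    keep = [i for i in range(rec.n_channels) if i not in present]
    data = rec.data[keep] - ref
    labels = tuple(rec.channel_labels[i] for i in keep)
    return rec.copy_with(data=data, channel_labels=labels,
                         reference="-".join(ref_labels))


def bandpass(rec: EEGRecording, cfg: PreprocessConfig) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    cfg.validate(fs=rec.fs)
    sos = signal.butter(cfg.filter_order, [cfg.low_hz, cfg.high_hz],
                        btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def reject_windows(rec: EEGRecording, cfg: PreprocessConfig
                   ) -> tuple[EEGRecording, np.ndarray]:
    """Excise high-variance windows; return cleaned recording and mask.

    The recording is split into consecutive non-overlapping windows of
    ``artifact_window_s``.  A window is bad if any channel's sample SD
    within it exceeds ``artifact_sd_threshold``.  Bad windows are removed
    and the remainder concatenated; the boolean mask (True = rejected) is
    returned for audit.  A trailing partial window is never rejected.
    """
    cfg.validate()
    w = int(round(cfg.artifact_window_s * rec.fs))
    n_win = rec.n_samples // w
    if n_win < 1:
        raise ValueError(
            f"recording shorter than one artifact window ({w} samples)")
    head = rec.data[:, :n_win * w].reshape(rec.n_channels, n_win, w)
    sd = head.std(axis=2, ddof=1)
    bad = (sd > cfg.artifact_sd_threshold).any(axis=0)
    if bad.any():
        logger.info("subject %s: rejected %d/%d windows",
                    rec.subject_id, int(bad.sum()), n_win)
    keep_blocks = [head[:, i, :] for i in range(n_win) if not bad[i]]
    tail = rec.data[:, n_win * w:]
    parts = keep_blocks + ([tail] if tail.shape[1] else [])
    data = (np.concatenate(parts, axis=1) if parts
            else np.empty((rec.n_channels, 0)))
    return rec.copy_with(data=data), bad


def make_epochs(rec: EEGRecording, cfg: PreprocessConfig) -> EpochSet:
    """Cut a recording into fixed-length overlapping epochs.

    Epochs of ``L = epoch_length_s * fs`` samples start every
    ``L * (1 - overlap_fraction)`` samples from sample 0; a trailing
    partial epoch is discarded.  The count is
    ``floor((n_samples - L) / step) + 1``.
    """
    cfg.validate()
    L = int(round(cfg.epoch_length_s * rec.fs))
    step = max(1, int(round(L * (1 - cfg.overlap_fraction))))
    if rec.n_samples < L:
        logger.warning("subject %s: recording (%d samples) shorter than one "
                       "epoch (%d); no epochs produced",
                       rec.subject_id, rec.n_samples, L)
        return EpochSet([])
    n_epochs = (rec.n_samples - L) // step + 1
    epochs = [
        Epoch(data=rec.data[:, k * step: k * step + L], fs=rec.fs,
              channel_labels=rec.channel_labels, subject_id=rec.subject_id,
              group=rec.group, epoch_index=k)
        for k in range(n_epochs)
    ]
    return EpochSet(epochs)


def preprocess_recording(rec: EEGRecording, cfg: PreprocessConfig,
                         ref_labels: tuple[str, str] = REFERENCE_CHANNELS
                         ) -> tuple[EpochSet, np.ndarray]:
    """Full chain: re-reference -> band-pass -> reject -> epoch."""
    rec = rereference(rec, ref_labels)
    rec = bandpass(rec, cfg)
    rec, mask = reject_windows(rec, cfg)
    epochs = make_epochs(rec, cfg)
    logger.info("subject %s: %d epochs retained", rec.subject_id, len(epochs))
    return epochs, mask
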
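"""Readers and writers for recordings and cohorts.

Two on-disk representations are supported:

* European Data Format (EDF): one file per subject, 16-bit samples,
  1-second data records.  Writing is implemented here; reading goes
  through MNE's EDF reader.
* Delimited text matrix: samples as rows, channels as columns, a header
  row of channel labels, and an optional ``#``-prefixed metadata line
  carrying the sampling rate and subject fields.

A cohort directory holds one file per subject plus ``subjects.csv``
(columns ``subject_id,group``).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .core import EEGRecording

logger = logging.getLogger("eegdx")

_EDF_DIGITAL_MAX = 32767


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file (16-bit, 1-s data records).

    The recording length must be a whole number of seconds and the
    sampling rate an integer, so that samples fill 1-second data records
    exactly.  A fixed epoch-start date is written, making repeated runs
    byte-identical.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    if rec.n_samples % fs_i != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {fs_i} Hz); trim the recording")
    n_records = rec.n_samples // fs_i
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1.0)
    phys_min = -phys_max
    dig_max, dig_min = _EDF_DIGITAL_MAX, -_EDF_DIGITAL_MAX

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", errors="replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad(f"{rec.subject_id or 'X'} {rec.group or 'X'}", 80),
        pad(f"Startdate 01-JAN-2000 {rec.reference}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    fields = [
        b"".join(pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(f"{phys_min[i]:.2f}"[:8], 8) for i in range(ns)),
        b"".join(pad(f"{phys_max[i]:.2f}"[:8], 8) for i in range(ns)),
        b"".join(pad(str(dig_min), 8) for _ in range(ns)),
        b"".join(pad(str(dig_max), 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(fs_i), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ]
    # physical min/max re-parsed from their 8-char ASCII form so that the
    # scaling used for quantisation matches what a reader will see
    pmin = np.array([float(f"{phys_min[i]:.2f}"[:8]) for i in range(ns)])
    pmax = np.array([float(f"{phys_max[i]:.2f}"[:8]) for i in range(ns)])

    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.round((rec.data - pmin[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.writelines(fields)
        for r in range(n_records):
            block = digital[:, r * fs_i:(r + 1) * fs_i]
            fh.write(block.tobytes())


def read_edf(path: str | Path, subject_id: str = "",
             group: str = "") -> EEGRecording:
    """Read an EDF file via MNE into an :class:`EEGRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    sid = subject_id or Path(path).stem
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_labels=tuple(raw.ch_names),
                        subject_id=sid, group=group, reference="as-recorded")


def write_matrix(rec: EEGRecording, path: str | Path,
                 delimiter: str = "\t") -> None:
    """Write a recording as a delimited text matrix (channels as columns)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g} subject_id={rec.subject_id} "
                 f"group={rec.group} reference={rec.reference}\n")
        fh.write(delimiter.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter=delimiter)


def read_matrix(path: str | Path, fs: float | None = None,
                subject_id: str = "", group: str = "",
                delimiter: str = "\t") -> EEGRecording:
    """Read a delimited matrix with a channel-label header row.

    An optional leading ``#`` line may carry ``fs=... subject_id=...
    group=...`` metadata; an explicit ``fs`` argument overrides it.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            header = fh.readline()
        else:
            header = first
        labels = tuple(h.strip() for h in header.strip().split(delimiter))
        data = np.loadtxt(fh, delimiter=delimiter, ndmin=2)
    rate = fs if fs is not None else float(meta.get("fs", 0) or 0)
    if rate <= 0:
        raise ValueError(
            f"{path}: sampling rate not in file metadata; pass fs explicitly")
    return EEGRecording(
        data=data.T, fs=rate, channel_labels=labels,
        subject_id=subject_id or meta.get("subject_id", Path(path).stem),
        group=group or meta.get("group", ""),
        reference=meta.get("reference", "unknown"))


def write_cohort(recordings: list[EEGRecording], outdir: str | Path,
                 fmt: str = "edf") -> None:
    """Write one file per subject plus a ``subjects.csv`` sidecar table."""
    if fmt not in ("edf", "txt"):
        raise ValueError("fmt must be 'edf' or 'txt'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"edf": ".edf", "txt": ".tsv"}[fmt]
    with open(outdir / "subjects.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"])
        for rec in recordings:
            fname = rec.subject_id + ext
            if fmt == "edf":
                write_edf(rec, outdir / fname)
            else:
                write_matrix(rec, outdir / fname)
            w.writerow([rec.subject_id, rec.group])
    logger.info("wrote %d recordings to %s", len(recordings), outdir)


def read_cohort(indir: str | Path, fs: float | None = None
                ) -> list[EEGRecording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    table = indir / "subjects.csv"
    if not table.exists():
        raise FileNotFoundError(f"{table} not found")
    recordings = []
    with open(table) as fh:
        for row in csv.DictReader(fh):
            sid, group = row["subject_id"], row["group"]
            edf, tsv = indir / f"{sid}.edf", indir / f"{sid}.tsv"
            if edf.exists():
                rec = read_edf(edf, subject_id=sid, group=group)
            elif tsv.exists():
                rec = read_matrix(tsv, fs=fs, subject_id=sid, group=group)
            else:
                raise FileNotFoundError(f"no data file for subject {sid}")
            recordings.append(rec)
    return recordings
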
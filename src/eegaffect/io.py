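"""Reading and writing recordings: CSV and EDF, plus segment annotations.

CSV layout: one row per sample, one column per channel (header = channel
names), with a sidecar ``*_segments.csv`` of (start_s, end_s, label) rows and
a per-cohort ``manifest.json`` carrying the sampling rate and channel order.

EDF: recordings are written with a minimal European-Data-Format writer
(ASCII header, 1 s data records of little-endian int16 with per-channel
physical scaling) and read back through :mod:`mne`, which serves as the
independent reader in the round-trip tests.  Segment annotations travel in
the same sidecar CSV as for CSV recordings.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import EEGRecording, Segment

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_recording_edf",
    "read_recording_edf",
]


def _segments_frame(rec: EEGRecording) -> pd.DataFrame:
    fs = rec.sampling_rate
    return pd.DataFrame(
        [(s.start / fs, s.stop / fs, s.label) for s in rec.segments],
        columns=["start_s", "end_s", "label"],
    )


def _segments_from_frame(df: pd.DataFrame, fs: float) -> list[Segment]:
    return [
        Segment(round(r.start_s * fs), round(r.end_s * fs), r.label)
        for r in df.itertuples()
    ]


def _stem(subject_id: int, trial_id: int) -> str:
    return f"sub{subject_id:02d}_trial{trial_id:02d}"


def write_recording_csv(rec: EEGRecording, directory: str | Path) -> Path:
    """Write ``<stem>_eeg.csv`` (samples x channels) + ``<stem>_segments.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _stem(rec.subject_id, rec.trial_id)
    eeg_path = directory / f"{stem}_eeg.csv"
    pd.DataFrame(rec.signal.T, columns=list(rec.channel_names)).to_csv(
        eeg_path, index=False, float_format="%.4f"
    )
    _segments_frame(rec).to_csv(directory / f"{stem}_segments.csv", index=False)
    return eeg_path


def read_recording_csv(
    eeg_path: str | Path,
    sampling_rate: float,
    subject_id: int | None = None,
    trial_id: int | None = None,
) -> EEGRecording:
    eeg_path = Path(eeg_path)
    df = pd.read_csv(eeg_path)
    seg_path = eeg_path.with_name(eeg_path.name.replace("_eeg.csv", "_segments.csv"))
    segments = (
        _segments_from_frame(pd.read_csv(seg_path), sampling_rate)
        if seg_path.exists()
        else []
    )
    if subject_id is None or trial_id is None:
        # recover ids from the canonical file stem when possible
        name = eeg_path.stem
        try:
            subject_id = int(name.split("_")[0].removeprefix("sub"))
            trial_id = int(name.split("_")[1].removeprefix("trial"))
        except (ValueError, IndexError):
            subject_id = subject_id if subject_id is not None else -1
            trial_id = trial_id if trial_id is not None else -1
    return EEGRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        signal=df.to_numpy(dtype=float).T,
        sampling_rate=sampling_rate,
        channel_names=tuple(df.columns),
        segments=segments,
    )


def write_cohort_csv(
    recordings: Sequence[EEGRecording], directory: str | Path
) -> Path:
    """Write every trial as CSV plus a ``manifest.json`` for the cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording_csv(rec, directory)
    first = recordings[0]
    manifest = {
        "sampling_rate": first.sampling_rate,
        "channel_names": list(first.channel_names),
        "recordings": [
            {"subject_id": r.subject_id, "trial_id": r.trial_id,
             "file": f"{_stem(r.subject_id, r.trial_id)}_eeg.csv"}
            for r in recordings
        ],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort_csv(directory: str | Path) -> list[EEGRecording]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    fs = manifest["sampling_rate"]
    return [
        read_recording_csv(
            directory / entry["file"], fs, entry["subject_id"], entry["trial_id"]
        )
        for entry in manifest["recordings"]
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def write_recording_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Minimal EDF writer: 1 s records, int16 samples, physical unit uV.

    Requires an integer sampling rate and a whole number of seconds of
    signal.  Segment annotations are written to a ``*_segments.csv`` sidecar
    next to the EDF file.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = round(fs)
    n_records, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires a whole number of 1 s records")
    ns = rec.n_channels

    def num(x: float, width: int = 8) -> str:
        # densest representation that fits the fixed-width ASCII field
        for p in range(10, 0, -1):
            s = f"{x:.{p}g}"
            if len(s) <= width:
                return s
        raise ValueError(f"cannot format {x} in {width} bytes")

    pmin = rec.signal.min(axis=1)
    pmax = rec.signal.max(axis=1)
    flat = pmax <= pmin
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    # quantize the physical range to its stored header representation first,
    # widened outward so no sample falls outside it
    pmin = np.array([float(num(v)) for v in pmin])
    pmax = np.array([float(num(v)) for v in pmax])
    pmin = np.minimum(pmin, rec.signal.min(axis=1))
    pmax = np.maximum(pmax, rec.signal.max(axis=1))
    pmin = np.array([float(num(v if v <= rec.signal[i].min() else v - abs(v) * 1e-3 - 1e-6))
                     for i, v in enumerate(pmin)])
    pmax = np.array([float(num(v if v >= rec.signal[i].max() else v + abs(v) * 1e-3 + 1e-6))
                     for i, v in enumerate(pmax)])
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((rec.signal - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(f"subject {rec.subject_id}", 80)
    header += _pad(f"trial {rec.trial_id}", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)
    for ch in rec.channel_names:
        header += _pad(ch, 16)
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    for v in pmin:
        header += _pad(num(float(v)), 8)
    for v in pmax:
        header += _pad(num(float(v)), 8)
    header += b"".join(_pad(str(dmin), 8) for _ in range(ns))
    header += b"".join(_pad(str(dmax), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad(str(fs), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())

    sidecar = path.with_name(path.stem + "_segments.csv")
    _segments_frame(rec).to_csv(sidecar, index=False)
    return path


def read_recording_edf(
    path: str | Path,
    subject_id: int | None = None,
    trial_id: int | None = None,
) -> EEGRecording:
    """Read an EDF recording via mne; restores microvolt units and segments."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne converts uV -> V on load
    fs = float(raw.info["sfreq"])
    sidecar = path.with_name(path.stem + "_segments.csv")
    segments = (
        _segments_from_frame(pd.read_csv(sidecar), fs) if sidecar.exists() else []
    )
    return EEGRecording(
        subject_id=-1 if subject_id is None else subject_id,
        trial_id=-1 if trial_id is None else trial_id,
        signal=signal,
        sampling_rate=fs,
        channel_names=tuple(raw.ch_names),
        segments=segments,
    )
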
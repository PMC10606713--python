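"""File I/O: EDF signals, per-second annotation TSV, HDF5 containers.

EDF (European Data Format) reading goes through :mod:`mne`.  Writing uses a
minimal built-in EDF encoder (16-bit, 1 s data records) that exists so
synthetic records and test fixtures can round-trip through the same reader
as real polysomnography files.

The annotation dialect is a TSV with columns ``onset_s  duration_s  label``
(label in {A1, A2, A3, B}); spans not covered by any event default to the
B phase.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np

from capnet.records import A_SUBTYPES, SUBTYPES, EEGRecord
from capnet.segmentation import FS_ANALYSIS, Segment

__all__ = [
    "ChannelNotFoundError",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "save_record",
    "load_record",
    "save_segments",
    "load_segments",
    "save_tfr_batch",
    "load_tfr_batch",
]


class ChannelNotFoundError(KeyError):
    """Requested EDF channel is absent; the message lists available ones."""


def read_edf(path: str | Path, channel: str) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF file.

    Returns ``(samples, fs_hz)`` with samples in microvolts for EEG-typed
    channels (other channel types are returned in their native physical
    units).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not found; available channels: {raw.ch_names}"
        )
    try:
        data = raw.get_data(picks=[channel], units="uV")[0]
    except ValueError:
        data = raw.get_data(picks=[channel])[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signals: dict[str, np.ndarray],
    fs_hz: int,
    physical_dim: str = "uV",
) -> None:
    """Write channels to a 16-bit EDF file with 1 s data records.

    ``fs_hz`` must be an integer (samples per 1 s record).  Each channel is
    scaled to the full 16-bit digital range over a symmetric physical range
    covering its extremes, so the quantization step is
    ``2*phys_max / 65535``.  Trailing samples beyond the last whole second
    are dropped.
    """
    fs_hz = int(fs_hz)
    names = list(signals)
    arrays = [np.asarray(signals[n], dtype=float) for n in names]
    n_records = min(len(a) // fs_hz for a in arrays)
    if n_records < 1:
        raise ValueError("signals must contain at least one full second")
    ns = len(names)

    phys_max = []
    for a in arrays:
        m = float(np.max(np.abs(a[: n_records * fs_hz]))) if len(a) else 1.0
        phys_max.append(m if m > 0 else 1.0)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    header += b"".join(_edf_field(n, 16) for n in names)
    header += b"".join(_edf_field("", 80) for _ in names)
    header += b"".join(_edf_field(physical_dim, 8) for _ in names)
    header += b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field("-32768", 8) for _ in names)
    header += b"".join(_edf_field("32767", 8) for _ in names)
    header += b"".join(_edf_field("", 80) for _ in names)
    header += b"".join(_edf_field(str(fs_hz), 8) for _ in names)
    header += b"".join(_edf_field("", 32) for _ in names)

    # digital = physical / phys_max * 32767 (phys range written with %.6g,
    # so re-parse it to keep writer and reader scaling bit-consistent)
    parsed_max = [float(f"{m:.6g}"[:8]) for m in phys_max]
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for a, m in zip(arrays, parsed_max):
                chunk = a[r * fs_hz : (r + 1) * fs_hz]
                dig = np.clip(np.round(chunk / m * 32767), -32768, 32767)
                fh.write(dig.astype("<i2").tobytes())


def read_annotations(path: str | Path, n_seconds: int | None = None) -> np.ndarray:
    """Expand an event TSV into a dense per-second subtype label sequence.

    Unannotated seconds are B.  ``n_seconds`` fixes the sequence length
    (defaulting to the end of the last event).  Overlapping A events and
    unknown labels are errors.
    """
    events: list[tuple[int, int, str]] = []
    first = True
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated columns")
            if first:
                first = False
                if not parts[0].lstrip("-").replace(".", "", 1).isdigit():
                    continue  # header row
            onset, dur, label = int(float(parts[0])), int(float(parts[1])), parts[2]
            if label not in SUBTYPES:
                raise ValueError(f"{path}:{line_no}: unknown label {label!r}")
            if onset < 0 or dur < 1:
                raise ValueError(f"{path}:{line_no}: bad onset/duration {onset}/{dur}")
            events.append((onset, dur, label))

    extent = max((o + d for o, d, _ in events), default=0)
    if n_seconds is None:
        n_seconds = extent
    elif extent > n_seconds:
        raise ValueError(f"events extend to {extent} s beyond the {n_seconds} s span")

    labels = np.full(n_seconds, "B", dtype="U2")
    for onset, dur, label in sorted(events):
        span = labels[onset : onset + dur]
        if label in A_SUBTYPES and np.any(np.isin(span, A_SUBTYPES)):
            raise ValueError(f"overlapping A events at seconds {onset}..{onset + dur - 1}")
        labels[onset : onset + dur] = label
    return labels


def write_annotations(path: str | Path, labels: np.ndarray) -> None:
    """Write per-second subtype labels as an event TSV (B spans implicit)."""
    labels = np.asarray(labels, dtype="U2")
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        t = 0
        while t < len(labels):
            if labels[t] in A_SUBTYPES:
                t0 = t
                while t < len(labels) and labels[t] == labels[t0]:
                    t += 1
                fh.write(f"{t0}\t{t - t0}\t{labels[t0]}\n")
            else:
                t += 1


def save_record(path: str | Path, record: EEGRecord, seed: int | None = None) -> None:
    """Persist a record to HDF5 (/signal, /labels, /subtypes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=record.samples)
        f.create_dataset("labels", data=record.binary_labels.astype("S1"))
        f.create_dataset("subtypes", data=record.labels.astype("S2"))
        f.attrs["fs_hz"] = record.fs_hz
        f.attrs["subject_id"] = record.subject_id
        f.attrs["channel"] = record.channel
        if seed is not None:
            f.attrs["seed"] = seed


def load_record(path: str | Path) -> EEGRecord:
    with h5py.File(path, "r") as f:
        return EEGRecord(
            subject_id=str(f.attrs["subject_id"]),
            channel=str(f.attrs["channel"]),
            samples=f["signal"][:],
            fs_hz=float(f.attrs["fs_hz"]),
            labels=f["subtypes"][:].astype("U2"),
        )


def save_segments(path: str | Path, segments: list[Segment]) -> None:
    """Persist prepared segments to HDF5."""
    if not segments:
        raise ValueError("no segments to save")
    window_s = segments[0].window_s
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "segments", data=np.stack([s.samples for s in segments]).astype(np.float32)
        )
        f.create_dataset(
            "center_label", data=np.array([s.center_label for s in segments], dtype="S1")
        )
        f.create_dataset(
            "center_subtype", data=np.array([s.center_subtype for s in segments], dtype="S2")
        )
        f.create_dataset("split", data=np.array([s.split for s in segments], dtype="S5"))
        f.create_dataset(
            "subject", data=np.array([s.subject_id for s in segments], dtype="S32")
        )
        f.create_dataset(
            "center_time_s", data=np.array([s.center_time_s for s in segments], dtype=np.int64)
        )
        f.attrs["window_s"] = window_s
        f.attrs["fs"] = FS_ANALYSIS


def load_segments(path: str | Path) -> list[Segment]:
    with h5py.File(path, "r") as f:
        window_s = int(f.attrs["window_s"])
        samples = f["segments"][:]
        subtypes = f["center_subtype"][:].astype("U2")
        splits = f["split"][:].astype("U5")
        subjects = f["subject"][:].astype("U32")
        times = f["center_time_s"][:]
    return [
        Segment(
            samples=samples[i].astype(float),
            window_s=window_s,
            center_subtype=str(subtypes[i]),
            center_time_s=int(times[i]),
            subject_id=str(subjects[i]),
            split=str(splits[i]),
        )
        for i in range(len(samples))
    ]


def save_tfr_batch(
    path: str | Path,
    images: np.ndarray,
    labels: np.ndarray,
    subtypes: np.ndarray,
    splits: np.ndarray,
    method: str,
    window_s: int,
    **attrs,
) -> None:
    """Persist a batch of time-frequency images with their labels."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tfr", data=np.asarray(images, dtype=np.float32))
        f.create_dataset("center_label", data=np.asarray(labels, dtype="S1"))
        f.create_dataset("center_subtype", data=np.asarray(subtypes, dtype="S2"))
        f.create_dataset("split", data=np.asarray(splits, dtype="S5"))
        f.attrs["method"] = method
        f.attrs["window_s"] = window_s
        for k, v in attrs.items():
            f.attrs[k] = v


def load_tfr_batch(path: str | Path):
    with h5py.File(path, "r") as f:
        return (
            f["tfr"][:],
            f["center_label"][:].astype("U1"),
            f["center_subtype"][:].astype("U2"),
            f["split"][:].astype("U5"),
            dict(f.attrs),
        )
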
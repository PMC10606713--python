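"""Segmentation of annotated EEG records into labeled context windows.

Implements the per-second analysis protocol: the whole record is resampled
to 32 Hz, every annotated second becomes one segment consisting of that
second plus (W-1)/2 seconds of context on each side, and the segment is
labeled by its central second only.  Train/validation/test membership is
assigned by non-overlapping 300 s blocks (240 s train / 30 s val / 30 s
test), segments whose context crosses a split boundary are dropped to make
the splits fully disjoint, and B-phase segments are randomly subsampled per
recording and split to balance the two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from capnet.records import A_SUBTYPES, EEGRecord

__all__ = [
    "Segment",
    "SplitSpec",
    "resample_to_32hz",
    "extract_segments",
    "assign_splits",
    "trim_edges",
    "balance_classes",
]

FS_ANALYSIS = 32
VALID_WINDOWS = (1, 3, 5, 7, 9, 11)


@dataclass
class Segment:
    """One W-second context window at 32 Hz, labeled by its central second.

    ``center_time_s`` is the 0-based offset of the central second in the
    recording; the window covers seconds
    ``center_time_s - (W-1)/2 ... center_time_s + (W-1)/2`` (samples
    ``32*t ... 32*t+31`` per second t, half-open convention).
    """

    samples: np.ndarray
    window_s: int
    center_subtype: str
    center_time_s: int
    subject_id: str
    split: str = ""

    def __post_init__(self) -> None:
        if len(self.samples) != self.window_s * FS_ANALYSIS:
            raise ValueError(
                f"segment has {len(self.samples)} samples, expected {self.window_s * FS_ANALYSIS}"
            )

    @property
    def center_label(self) -> str:
        """Binary label: 'A' iff the central second is any A subtype."""
        return "A" if self.center_subtype in A_SUBTYPES else "B"

    @property
    def covered_seconds(self) -> range:
        half = (self.window_s - 1) // 2
        return range(self.center_time_s - half, self.center_time_s + half + 1)


@dataclass(frozen=True)
class SplitSpec:
    """Block protocol for train/val/test assignment along the recording."""

    block_s: int = 300
    train_s: int = 240
    val_s: int = 30
    test_s: int = 30

    def __post_init__(self) -> None:
        if self.train_s + self.val_s + self.test_s != self.block_s:
            raise ValueError("train_s + val_s + test_s must equal block_s")


def resample_to_32hz(signal: np.ndarray, fs_hz: float) -> np.ndarray:
    """Anti-aliased resampling of a signal to the 32 Hz analysis rate.

    Uses polyphase rational resampling with scipy's default linear-phase
    Kaiser low-pass, which keeps content below 16 Hz and attenuates
    everything above.  Rates must be >= 32 and commensurable with 32
    (every integer rate is).
    """
    signal = np.asarray(signal, dtype=float)
    if fs_hz < FS_ANALYSIS:
        raise ValueError(f"unsupported rate {fs_hz} Hz: must be >= {FS_ANALYSIS}")
    if fs_hz == FS_ANALYSIS:
        return signal.copy()
    from fractions import Fraction

    frac = Fraction(FS_ANALYSIS, 1) / Fraction(fs_hz).limit_denominator(10**6)
    return resample_poly(signal, frac.numerator, frac.denominator)


def resample_record(record: EEGRecord) -> EEGRecord:
    """Resample a whole record to 32 Hz, keeping its labels."""
    out = resample_to_32hz(record.samples, record.fs_hz)
    # keep exactly the annotated seconds worth of samples
    out = out[: record.duration_s * FS_ANALYSIS]
    return EEGRecord(record.subject_id, record.channel, out, FS_ANALYSIS, record.labels)


def extract_segments(record: EEGRecord, window_s: int) -> list[Segment]:
    """Cut one context window per annotated second of a 32 Hz record.

    Only seconds whose full W-second window lies inside the recording yield
    a segment; each is labeled by its central second alone, regardless of
    the context labels.
    """
    if window_s % 2 == 0 or window_s < 1:
        raise ValueError(f"window_s must be a positive odd integer, got {window_s}")
    if record.fs_hz != FS_ANALYSIS:
        raise ValueError("extract_segments expects a 32 Hz record (resample first)")
    if record.duration_s < window_s:
        raise ValueError("record shorter than the context window")
    half = (window_s - 1) // 2
    segments = []
    for t in range(half, record.duration_s - half):
        i0 = (t - half) * FS_ANALYSIS
        segments.append(
            Segment(
                samples=record.samples[i0 : i0 + window_s * FS_ANALYSIS].copy(),
                window_s=window_s,
                center_subtype=str(record.labels[t]),
                center_time_s=t,
                subject_id=record.subject_id,
            )
        )
    return segments


def assign_splits(duration_s: int, spec: SplitSpec = SplitSpec()) -> np.ndarray:
    """Per-second train/val/test membership by the block protocol.

    Second t falls in block floor(t/block_s); within-block offsets
    [0, train_s) are train, [train_s, train_s+val_s) val, the rest test.
    A trailing partial block follows the same offsets.
    """
    offsets = np.arange(duration_s) % spec.block_s
    split = np.full(duration_s, "train", dtype="U5")
    split[(offsets >= spec.train_s) & (offsets < spec.train_s + spec.val_s)] = "val"
    split[offsets >= spec.train_s + spec.val_s] = "test"
    return split


def attach_splits(segments: list[Segment], split_map: np.ndarray) -> list[Segment]:
    """Stamp each segment with the split of its central second."""
    for seg in segments:
        seg.split = str(split_map[seg.center_time_s])
    return segments


def trim_edges(
    segments: list[Segment], window_s: int, split_map: np.ndarray
) -> list[Segment]:
    """Drop segments whose context window crosses a split boundary.

    A segment survives only if all ``window_s`` seconds it covers belong to
    its own split, which makes the train/val/test signal coverage fully
    disjoint.  ``window_s`` may exceed the segments' own window (e.g. when
    training will read time-shifted context), in which case the wider
    coverage is enforced.
    """
    half = (window_s - 1) // 2
    kept = []
    for seg in segments:
        covered = range(seg.center_time_s - half, seg.center_time_s + half + 1)
        if all(
            0 <= t < len(split_map) and split_map[t] == seg.split for t in covered
        ):
            kept.append(seg)
    return kept


def balance_classes(segments: list[Segment], seed: int) -> list[Segment]:
    """Randomly drop B segments until B count equals A count.

    Balancing is applied independently per (recording, split) group; A
    segments are never removed.  If a group has fewer B than A segments a
    warning is emitted and the group is left untouched.  Surviving segments
    keep their original order; the same seed always keeps the same set.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, seg in enumerate(segments):
        groups.setdefault((seg.subject_id, seg.split), []).append(i)

    drop: set[int] = set()
    for key in sorted(groups):
        idx = groups[key]
        a_idx = [i for i in idx if segments[i].center_label == "A"]
        b_idx = [i for i in idx if segments[i].center_label == "B"]
        n_a, n_b = len(a_idx), len(b_idx)
        if n_b < n_a:
            warnings.warn(
                f"group {key}: only {n_b} B segments for {n_a} A segments; not balancing"
            )
            continue
        if n_a == 0:
            if n_b:
                warnings.warn(f"group {key}: no A segments; removing all {n_b} B segments")
            drop.update(b_idx)
            continue
        removed = rng.choice(len(b_idx), size=n_b - n_a, replace=False)
        drop.update(b_idx[j] for j in removed)
    return [seg for i, seg in enumerate(segments) if i not in drop]


def prepare_segments(
    record: EEGRecord,
    window_s: int,
    seed: int,
    spec: SplitSpec = SplitSpec(),
    balance: bool = True,
) -> list[Segment]:
    """Full preparation chain: resample, segment, split, trim, balance."""
    rec32 = resample_record(record) if record.fs_hz != FS_ANALYSIS else record
    segments = extract_segments(rec32, window_s)
    split_map = assign_splits(rec32.duration_s, spec)
    attach_splits(segments, split_map)
    segments = trim_edges(segments, window_s, split_map)
    if balance:
        segments = balance_classes(segments, seed)
    return segments
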
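"""Core container for an annotated single-channel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: CAP label alphabet. B is the background phase; A1/A2/A3 are the
#: activation-phase subtypes (slow high-amplitude, mixed, fast low-amplitude).
SUBTYPES = ("A1", "A2", "A3", "B")
A_SUBTYPES = ("A1", "A2", "A3")


@dataclass
class EEGRecord:
    """Continuous EEG samples plus one CAP subtype label per second.

    Parameters
    ----------
    subject_id : str
        Recording identifier (e.g. ``"n1"`` or a synthetic seed tag).
    channel : str
        Channel name, typically ``"C4-A1"`` or ``"C3-A2"``.
    samples : ndarray
        1-D real signal.
    fs_hz : float
        Sampling rate of ``samples``.
    labels : ndarray of str
        Per-second subtype labels over {A1, A2, A3, B}; one entry per full
        second of signal, i.e. ``len(labels) == floor(len(samples)/fs_hz)``.
    """

    subject_id: str
    channel: str
    samples: np.ndarray
    fs_hz: float
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U2")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.fs_hz < 32:
            raise ValueError(f"sampling rate {self.fs_hz} Hz below the 32 Hz analysis rate")
        n_expected = int(len(self.samples) // self.fs_hz)
        if len(self.labels) != n_expected:
            raise ValueError(
                f"labels length {len(self.labels)} != floor(n_samples/fs) = {n_expected}"
            )
        bad = set(np.unique(self.labels)) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {SUBTYPES}")

    @property
    def duration_s(self) -> int:
        """Number of annotated seconds."""
        return len(self.labels)

    @property
    def binary_labels(self) -> np.ndarray:
        """Per-second A/B labels (subtypes collapsed to 'A')."""
        return np.where(np.isin(self.labels, A_SUBTYPES), "A", "B")
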
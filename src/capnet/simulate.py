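"""Synthetic CAP-EEG generator.

Emulates the phase phenomenology of sleep-EEG microstructure: a B-phase
background rhythm (band-limited 1/f noise) interrupted by A-phase events —
A1 as high-amplitude slow waves (0.5-4 Hz), A3 as faster (8-12 Hz)
lower-amplitude activity, and A2 as a mixture of both.  Events are
non-overlapping contiguous runs of whole seconds, so the generated record
carries exact per-second ground-truth labels for every downstream stage.

The generator makes no claim of physiological realism (no sleep
macrostructure, no artifacts); its job is to produce signals whose
label/spectral relationship is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from capnet.records import EEGRecord

__all__ = [
    "PhaseSpec",
    "SimConfig",
    "DEFAULT_PHASES",
    "generate_record",
    "render_phase_waveform",
    "background_noise",
]


@dataclass(frozen=True)
class PhaseSpec:
    """Spectral/amplitude recipe for one A-phase subtype.

    ``amplitude_gain`` is the ratio of event RMS to background RMS.  For the
    mixed subtype (A2) the waveform is a sum of components, each a
    band-limited oscillation with its own gain; ``components`` then lists
    ``(band_hz, gain)`` pairs and ``band_hz``/``amplitude_gain`` describe the
    envelope (union band, total gain) used for in-band power checks.
    """

    subtype: str
    band_hz: tuple[float, float]
    amplitude_gain: float
    duration_range_s: tuple[int, int] = (2, 10)
    components: tuple[tuple[tuple[float, float], float], ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi <= 16):
            raise ValueError(f"band_hz {self.band_hz} must lie within (0, 16] Hz (32 Hz Nyquist)")
        if self.duration_range_s[0] < 1:
            raise ValueError("minimum event duration must be >= 1 s")
        if self.duration_range_s[0] > self.duration_range_s[1]:
            raise ValueError("duration_range_s must be (min, max) with min <= max")
        if self.amplitude_gain < 0:
            raise ValueError("amplitude_gain must be non-negative")


#: Default subtype recipes.  Gains are relative to unit background RMS:
#: A1 events are strong slow waves, A3 weaker fast activity, A2 a sum of a
#: slow (gain 2.0) and a fast (gain 0.7) component.
DEFAULT_PHASES: dict[str, PhaseSpec] = {
    "A1": PhaseSpec("A1", (0.5, 4.0), 3.0),
    "A3": PhaseSpec("A3", (8.0, 12.0), 0.7),
    "A2": PhaseSpec(
        "A2",
        (0.5, 12.0),
        float(np.hypot(2.0, 0.7)),
        components=(((0.5, 4.0), 2.0), ((8.0, 12.0), 0.7)),
    ),
}

#: Minimum run of background seconds separating consecutive A events.
MIN_GAP_S = 2


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic full-night-like recording.

    Defaults: 128 Hz output (so the 32 Hz downsampling step is exercised),
    A:B second ratio of roughly 1:5 (a_fraction ~ 0.17 mirrors the strong
    B-phase dominance of real CAP annotations; tests typically set 0.2),
    subtype mix weighted toward A1 as in healthy-subject tallies.
    """

    duration_s: int = 3000
    fs_hz: int = 128
    a_fraction: float = 0.2
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: {"A1": 0.5, "A2": 0.2, "A3": 0.3}
    )
    phases: dict[str, PhaseSpec] = field(default_factory=lambda: dict(DEFAULT_PHASES))
    noise_band_hz: tuple[float, float] = (0.3, 16.0)
    noise_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 10:
            raise ValueError("duration_s must be >= 10")
        if not (0 <= self.a_fraction <= 0.5):
            raise ValueError("a_fraction must lie in [0, 0.5]")
        if self.fs_hz < 32:
            raise ValueError("fs_hz must be >= 32")
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix must sum to 1 (got {total})")
        if set(self.subtype_mix) - {"A1", "A2", "A3"}:
            raise ValueError("subtype_mix keys must be a subset of {A1, A2, A3}")


def _band_limited_noise(
    n_samples: int,
    fs_hz: float,
    band_hz: tuple[float, float],
    rng: np.random.Generator,
    slope: float = 0.0,
) -> np.ndarray:
    """White Gaussian noise shaped in the frequency domain.

    The spectrum is zeroed outside ``band_hz`` and, for ``slope`` > 0,
    weighted by 1/f^(slope/2) inside it (power spectral density ~ 1/f^slope).
    Output is NOT normalized; callers scale to a target RMS.
    """
    x = rng.standard_normal(n_samples)
    if n_samples < 2:
        return np.zeros(n_samples)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    mask = (f >= band_hz[0]) & (f <= band_hz[1])
    if not mask.any():
        return np.zeros(n_samples)
    weight = np.zeros_like(f)
    if slope > 0:
        weight[mask] = f[mask] ** (-slope / 2.0)
    else:
        weight[mask] = 1.0
    return np.fft.irfft(spec * weight, n=n_samples)


def _scale_rms(x: np.ndarray, target_rms: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0 or target_rms == 0:
        return np.zeros_like(x)
    return x * (target_rms / rms)


def background_noise(
    n_samples: int,
    fs_hz: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (0.3, 16.0),
    slope: float = 1.0,
) -> np.ndarray:
    """Unit-RMS pink (1/f) background rhythm band-limited to ``band_hz``."""
    return _scale_rms(_band_limited_noise(n_samples, fs_hz, band_hz, rng, slope), 1.0)


def render_phase_waveform(
    spec: PhaseSpec,
    n_samples: int,
    fs_hz: float,
    rng: np.random.Generator,
    background_rms: float = 1.0,
) -> np.ndarray:
    """Render one A-phase event as a band-limited oscillation.

    The waveform is confined to ``spec.band_hz`` and scaled so that its RMS
    equals ``spec.amplitude_gain * background_rms``.  For a composite spec
    (A2) each component is rendered and scaled separately, then summed.
    A short cosine taper (up to 0.25 s) softens event onsets/offsets; the
    RMS is rescaled after tapering so the gain contract is exact.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if spec.band_hz[1] > fs_hz / 2:
        raise ValueError(
            f"band {spec.band_hz} exceeds Nyquist ({fs_hz / 2} Hz) at fs={fs_hz}"
        )
    if spec.amplitude_gain == 0:
        return np.zeros(n_samples)

    if spec.components is not None:
        parts = [
            render_phase_waveform(
                replace(spec, band_hz=band, amplitude_gain=gain, components=None),
                n_samples,
                fs_hz,
                rng,
                background_rms,
            )
            for band, gain in spec.components
        ]
        return np.sum(parts, axis=0)

    x = _band_limited_noise(n_samples, fs_hz, spec.band_hz, rng)
    if not np.any(x):
        return np.zeros(n_samples)
    ramp = min(int(0.25 * fs_hz), n_samples // 4)
    if ramp > 0:
        taper = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= taper
        x[-ramp:] *= taper[::-1]
    return _scale_rms(x, spec.amplitude_gain * background_rms)


def _draw_event_durations(
    target_a_s: int, mix: dict[str, float], phases: dict[str, PhaseSpec], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Draw (subtype, duration) pairs totalling at most ``target_a_s`` seconds.

    The last event may be shortened to land on the target; a residual shorter
    than the subtype minimum is dropped, so the shortfall is < min duration.
    """
    names = sorted(mix)
    probs = np.array([mix[k] for k in names])
    events: list[tuple[str, int]] = []
    total = 0
    while total < target_a_s:
        sub = names[rng.choice(len(names), p=probs)]
        lo, hi = phases[sub].duration_range_s
        dur = int(rng.integers(lo, hi + 1))
        if total + dur > target_a_s:
            dur = target_a_s - total
            if dur < lo:
                break
        events.append((sub, dur))
        total += dur
    return events


def _place_events(
    events: list[tuple[str, int]], duration_s: int, rng: np.random.Generator
) -> list[tuple[int, str, int]]:
    """Place events non-overlapping with >= MIN_GAP_S background seconds between them.

    Returns (onset_s, subtype, duration_s) triples in time order.  Background
    slack is spread over the n+1 gaps by a random composition.
    """
    n = len(events)
    if n == 0:
        return []
    used = sum(d for _, d in events) + MIN_GAP_S * (n - 1)
    slack = duration_s - used
    if slack < 0:
        raise ValueError("events do not fit in the record with the required gaps")
    # random composition of `slack` into n+1 non-negative parts
    cuts = np.sort(rng.integers(0, slack + 1, size=n)) if n > 0 else np.array([], int)
    parts = np.diff(np.concatenate(([0], cuts, [slack])))
    order = rng.permutation(n)
    placed = []
    t = int(parts[0])
    for i, k in enumerate(order):
        sub, dur = events[k]
        placed.append((t, sub, dur))
        t += dur + MIN_GAP_S + int(parts[i + 1])
    return placed


def generate_record(config: SimConfig) -> EEGRecord:
    """Generate a synthetic annotated EEG record.

    Background seconds are labeled B; each A event is a contiguous run of
    whole seconds labeled by its subtype, with its waveform added on top of
    the background rhythm ("high amplitude about the typical background").
    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.duration_s * config.fs_hz
    signal = background_noise(
        n_samples, config.fs_hz, rng, config.noise_band_hz, config.noise_slope
    )
    labels = np.full(config.duration_s, "B", dtype="U2")

    target_a = int(round(config.a_fraction * config.duration_s))
    if target_a > 0:
        events = _draw_event_durations(target_a, config.subtype_mix, config.phases, rng)
        for onset, sub, dur in _place_events(events, config.duration_s, rng):
            labels[onset : onset + dur] = sub
            i0, i1 = onset * config.fs_hz, (onset + dur) * config.fs_hz
            signal[i0:i1] += render_phase_waveform(
                config.phases[sub], i1 - i0, config.fs_hz, rng, background_rms=1.0
            )

    return EEGRecord(
        subject_id=f"sim{config.seed}",
        channel="SIM",
        samples=signal,
        fs_hz=config.fs_hz,
        labels=labels,
    )
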
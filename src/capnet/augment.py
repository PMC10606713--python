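"""Dataset normalization and structure-preserving augmentation.

Normalization centers each image and divides by the *mean* per-image
standard deviation of the training set (a single shared scale), rather than
each image's own std.  Per-image standardization would erase the energy
contrast between A-phase and B-phase samples, which is exactly the cue the
classifier needs; the shared scale preserves the ratio of image stds.

Augmentations operate on time-frequency images (rows = frequency, columns
= time) and are designed not to destroy their spectral structure:

* random time-shift — horizontal crop of a pre-extended image (all rows kept);
* additive white Gaussian noise with a uniformly drawn std;
* Gaussian blur applied with probability 0.5;
* SpecAugment-style masking — one time band (<= 5% of width) and one
  frequency band (<= 3% of height) set to the image mean;
* time crop-and-resize — trims random amounts from the image's time edges
  and stretches back to the original width, mimicking longer CAP events.

All operations take an explicit ``numpy.random.Generator`` and are
bit-reproducible under a fixed state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "NormStats",
    "AugmentConfig",
    "fit_norm_stats",
    "normalize",
    "random_time_shift",
    "add_awgn",
    "gaussian_blur",
    "spec_augment",
    "crop_resize_time",
    "apply_tf_augment",
]


@dataclass(frozen=True)
class NormStats:
    """Shared normalization scale fitted on the training split only."""

    sigma_bar: float
    n_samples: int


@dataclass(frozen=True)
class AugmentConfig:
    """Knobs of the augmentation chain.

    ``noise_std_frac`` scales the AWGN std range relative to ``sigma_bar``
    of the fitted normalization (noise std drawn uniformly from
    ``(0, noise_std_frac * sigma_bar)`` after normalization this is simply
    ``(0, noise_std_frac)`` in normalized units).
    """

    noise_std_range: tuple[float, float] = (0.0, 0.05)
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    time_mask_max_frac: float = 0.05
    freq_mask_max_frac: float = 0.03
    crop_resize_max_frac: float = 0.1
    time_shift_margin_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("time_mask_max_frac", "freq_mask_max_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 <= self.blur_prob <= 1:
            raise ValueError("blur_prob must lie in [0, 1]")
        if not 0 <= self.crop_resize_max_frac < 0.5:
            raise ValueError("crop_resize_max_frac must lie in [0, 0.5)")


def fit_norm_stats(images: np.ndarray) -> NormStats:
    """Mean of per-image pixel standard deviations over the training set."""
    images = np.asarray(images)
    if images.ndim != 3 or len(images) == 0:
        raise ValueError("expected a non-empty stack of 2-D images (n, n_freq, n_time)")
    sigma = images.reshape(len(images), -1).std(axis=1)
    sigma_bar = float(sigma.mean())
    if sigma_bar == 0:
        raise ValueError("all training images are constant; sigma_bar = 0")
    return NormStats(sigma_bar=sigma_bar, n_samples=len(images))


def normalize(image: np.ndarray, stats: NormStats) -> np.ndarray:
    """Center per image, scale by the shared sigma_bar."""
    image = np.asarray(image, dtype=np.float32)
    return (image - image.mean()) / stats.sigma_bar


def random_time_shift(
    extended_image: np.ndarray, target_n_time: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly positioned horizontal crop of a pre-extended image."""
    n_time = extended_image.shape[1]
    if n_time < target_n_time:
        raise ValueError(f"extended width {n_time} < target {target_n_time}")
    offset = int(rng.integers(0, n_time - target_n_time + 1))
    return extended_image[:, offset : offset + target_n_time].copy()


def add_awgn(
    image: np.ndarray, std_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Additive white Gaussian noise with std drawn uniformly per call."""
    lo, hi = std_range
    if lo < 0:
        raise ValueError("noise std must be non-negative")
    std = rng.uniform(lo, hi)
    return image + rng.normal(0.0, 1.0, image.shape).astype(image.dtype) * np.asarray(
        std, dtype=image.dtype
    )


def gaussian_blur(
    image: np.ndarray,
    rng: np.random.Generator,
    prob: float = 0.5,
    sigma_range: tuple[float, float] = (0.5, 1.5),
) -> np.ndarray:
    """With probability ``prob``, blur with a normalized 2-D Gaussian kernel.

    The kernel is truncated at 4 sigma; borders are zero-padded, so the
    total sum is preserved up to edge truncation.
    """
    if rng.random() >= prob:
        return image.copy()
    sigma = rng.uniform(*sigma_range)
    return gaussian_filter(image, sigma, mode="constant", cval=0.0, truncate=4.0).astype(
        image.dtype
    )


def spec_augment(
    image: np.ndarray,
    rng: np.random.Generator,
    time_mask_max_frac: float = 0.05,
    freq_mask_max_frac: float = 0.03,
) -> np.ndarray:
    """Mask one random time band and one random frequency band to the mean.

    Band widths are drawn uniformly from 0 up to ``ceil(frac * extent)``
    and positions uniformly among the valid offsets.  Draw order: time
    width, time offset, frequency width, frequency offset.
    """
    n_freq, n_time = image.shape
    out = image.copy()
    fill = image.mean()
    wt_max = int(np.ceil(time_mask_max_frac * n_time)) if time_mask_max_frac > 0 else 0
    wt = int(rng.integers(0, wt_max + 1))
    t0 = int(rng.integers(0, n_time - wt + 1))
    wf_max = int(np.ceil(freq_mask_max_frac * n_freq)) if freq_mask_max_frac > 0 else 0
    wf = int(rng.integers(0, wf_max + 1))
    f0 = int(rng.integers(0, n_freq - wf + 1))
    if wt:
        out[:, t0 : t0 + wt] = fill
    if wf:
        out[f0 : f0 + wf, :] = fill
    return out


def crop_resize_time(
    image: np.ndarray, max_crop_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Trim random amounts from the time edges, stretch back to full width.

    The total cropped fraction is drawn uniformly from [0, max_crop_frac]
    and split at random between the leading and trailing edge; the kept
    columns are linearly interpolated back to the original width, which
    stretches event durations.  Frequency rows are untouched.
    """
    if not 0 <= max_crop_frac < 0.5:
        raise ValueError("max_crop_frac must lie in [0, 0.5)")
    n_freq, n_time = image.shape
    total = int(round(rng.uniform(0.0, max_crop_frac) * n_time))
    if total == 0:
        return image.copy()
    lead = int(rng.integers(0, total + 1))
    trail = total - lead
    core = image[:, lead : n_time - trail]
    xs_new = np.linspace(0.0, core.shape[1] - 1.0, n_time)
    i0 = np.floor(xs_new).astype(int)
    i1 = np.minimum(i0 + 1, core.shape[1] - 1)
    w = (xs_new - i0).astype(image.dtype)
    out = core[:, i0] * (1 - w) + core[:, i1] * w
    return out.astype(image.dtype)


def apply_tf_augment(
    image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """The time-frequency augmentation chain, in a fixed order.

    Order: AWGN -> Gaussian blur -> SpecAugment masking -> time
    crop-and-resize.  Applied per sample, per batch, on already-normalized
    images.
    """
    out = add_awgn(image, cfg.noise_std_range, rng)
    out = gaussian_blur(out, rng, cfg.blur_prob, cfg.blur_sigma_range)
    out = spec_augment(out, rng, cfg.time_mask_max_frac, cfg.freq_mask_max_frac)
    out = crop_resize_time(out, cfg.crop_resize_max_frac, rng)
    return out
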
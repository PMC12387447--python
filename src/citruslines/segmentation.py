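"""Laser-stripe region extraction: V channel, gamma correction, Otsu.

The stripe is much brighter than the fruit surface but reflections and
bleed-through keep the raw histogram from being bimodal.  A power-law gamma
map s = c·r^γ on the HSV value channel (γ = 8 by default) crushes the mid
tones so that Otsu's inter-class-variance criterion separates stripe from
background cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "ThresholdResult",
    "extract_v_channel",
    "gamma_correct",
    "otsu_threshold",
    "segment_stripe",
]

L = 256  # gray levels


@dataclass
class ThresholdResult:
    """Otsu threshold T, the inter-class variance there, and the histogram p_i."""

    T: int
    sigma_b2: float
    histogram: np.ndarray  # 256 probabilities

    def __post_init__(self) -> None:
        if not (0 <= self.T <= L - 2):
            raise ValueError("threshold out of range")
        if abs(float(self.histogram.sum()) - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")


def extract_v_channel(frame: np.ndarray) -> np.ndarray:
    """HSV value channel of an 8-bit color frame: V = max(R, G, B) per pixel."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected a 3-channel color frame")
    return frame.max(axis=2).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float = 8.0, c: float = 1.0) -> np.ndarray:
    """Power-law mapping s = c·r^γ on [0,1]-normalized gray, back to 8 bits.

    Monotone non-decreasing for any γ > 0; the output is clipped to [0, 1]
    before rescaling so c only shifts where saturation begins.  Rounding is
    half-up to keep the quantization deterministic.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if c <= 0:
        raise ValueError("c must be positive")
    r = np.asarray(img, dtype=float) / (L - 1)
    s = np.clip(c * np.power(r, gamma), 0.0, 1.0)
    return np.floor(s * (L - 1) + 0.5).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> ThresholdResult:
    """Exhaustive maximization of the inter-class variance σ_B².

    Pixels ≤ T form the background, pixels > T the foreground;
    σ_B²(T) = w0(μ0−μG)² + w1(μ1−μG)².  Thresholds whose classes are empty
    are skipped, and plateaus are resolved to the smallest T.
    """
    img = np.asarray(img)
    counts = np.bincount(img.ravel().astype(np.int64), minlength=L)[:L]
    p = counts / counts.sum()
    if np.count_nonzero(p) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 gray levels")
    i = np.arange(L)
    mu_g = float((i * p).sum())
    w0 = np.cumsum(p)[:-1]            # background weight for T = 0..254
    m0 = np.cumsum(i * p)[:-1]        # background first moment
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma = np.full(L - 1, -np.inf)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(mu_g - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    sigma[valid] = (w0 * (mu0 - mu_g) ** 2 + w1 * (mu1 - mu_g) ** 2)[valid]
    T = int(np.argmax(sigma))  # argmax returns the first (smallest) maximizer
    return ThresholdResult(T=T, sigma_b2=float(sigma[T]), histogram=p)


def segment_stripe(frame: np.ndarray, gamma: float = 8.0, c: float = 1.0,
                   min_area_frac: float = 0.05) -> np.ndarray:
    """Binary stripe mask from a color frame.

    V channel → gamma correction → Otsu → mask = corrected > T; 8-connected
    components smaller than ``min_area_frac`` of the largest are dropped
    (0 disables the filter).
    """
    v = extract_v_channel(frame)
    corrected = gamma_correct(v, gamma=gamma, c=c)
    result = otsu_threshold(corrected)
    mask = corrected > result.T
    if not mask.any():
        raise ValueError("no stripe found")
    if min_area_frac > 0:
        labels = measure.label(mask, connectivity=2)
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        keep = areas >= min_area_frac * areas.max()
        mask = keep[labels]
        mask[labels == 0] = False
    return mask
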
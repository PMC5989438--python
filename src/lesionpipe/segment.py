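"""Probabilistic-distribution segmentation of enhanced lesion images.

Two scalar statistics of the enhanced grayscale image drive segmentation:

* the *uniform-distribution mean* ``mu = (min + max) / 2`` — the mean of a
  uniform density supported on the observed intensity range;
* the *mean absolute deviation* of a normal fit, ``M.D = 0.7979 sigma``
  (``sigma * sqrt(2/pi)``), with ``sigma`` the population standard
  deviation of the pixel intensities.

Each statistic is inserted into a per-pixel activation function

    A(v) = 1 / (1 + stat / v)**alpha + 1 / (2 * stat) + C

which is strictly increasing in the pixel value ``v`` for fixed ``stat``.
The activation map is min-max normalized to [0, 1], thresholded with Otsu's
method (256 bins), and the binary mask's polarity is fixed so the foreground
is the class with the *lower* mean enhanced intensity — dermoscopic lesions
are hypo-intense relative to the surrounding skin.

The additive terms ``1/(2*stat)`` and ``C`` shift the activation map
uniformly and therefore never change the Otsu partition; ``C`` defaults to
0.5 and may be randomized for parity with a stochastic initialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MAD_NORMAL_RATIO",
    "UniformStats",
    "NormalStats",
    "ActivationParams",
    "rgb_to_luminance",
    "uniform_mean",
    "normal_mad",
    "activation_map",
    "otsu_threshold",
    "segment_by_stat",
    "ActivationSegmenter",
]

logger = logging.getLogger(__name__)

#: mean absolute deviation of a normal distribution per unit sigma,
#: sqrt(2/pi) rounded to 4 decimals
MAD_NORMAL_RATIO = 0.7979

_EPS_PIXEL = 1e-6


@dataclass
class UniformStats:
    """Range statistics of the enhanced image: min x, max y, mean (x+y)/2."""

    x: float
    y: float

    @property
    def mu(self) -> float:
        return 0.5 * (self.x + self.y)


@dataclass
class NormalStats:
    """Normal-fit statistics: sample mean, population sigma, M.D = 0.7979 sigma."""

    mean: float
    sigma: float

    @property
    def md(self) -> float:
        return MAD_NORMAL_RATIO * self.sigma


@dataclass
class ActivationParams:
    """Activation-function parameters: exponent alpha (<= 10, default 7) and
    the additive constant c_act in [0, 1] (irrelevant to the Otsu partition)."""

    alpha: int = 7
    c_act: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.alpha <= 10:
            raise ValueError(f"alpha must be in [1, 10], got {self.alpha}")
        if not 0 <= self.c_act <= 1:
            raise ValueError(f"c_act must be in [0, 1], got {self.c_act}")


def rgb_to_luminance(img: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance 0.299 R + 0.587 G + 0.114 B of an RGB image."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) or (H, W), got {img.shape}")
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


def uniform_mean(ch: np.ndarray) -> UniformStats:
    """Midpoint of the intensity range — mean of the fitted uniform density."""
    ch = np.asarray(ch, dtype=float)
    if ch.size == 0:
        raise ValueError("empty channel")
    return UniformStats(x=float(ch.min()), y=float(ch.max()))


def normal_mad(ch: np.ndarray) -> NormalStats:
    """Normal-fit mean absolute deviation, M.D = 0.7979 sigma."""
    ch = np.asarray(ch, dtype=float)
    if ch.size == 0:
        raise ValueError("empty channel")
    return NormalStats(mean=float(ch.mean()), sigma=float(ch.std()))


def activation_map(
    enh: np.ndarray, stat: float, p: ActivationParams | None = None
) -> np.ndarray:
    """Per-pixel activation ``1/(1 + stat/v)^alpha + 1/(2 stat) + C``.

    Strictly increasing in the pixel value v for a fixed positive statistic.
    Zero pixels are shifted by 1e-6 to keep the ratio finite.
    """
    p = p or ActivationParams()
    if stat <= 0:
        raise ValueError(
            f"statistic must be positive, got {stat} (constant image upstream?)"
        )
    v = np.asarray(enh, dtype=float)
    v = np.where(v <= 0, _EPS_PIXEL, v)
    return 1.0 / (1.0 + stat / v) ** p.alpha + 1.0 / (2.0 * stat) + p.c_act


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def otsu_threshold(m: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a map normalized to [0, 1].

    The map is histogrammed into ``nbins`` equal bins over [0, 1]; the
    returned value is the bin center maximizing the between-class variance,
    ties broken toward the lower threshold. A constant map returns its
    constant value.
    """
    m = np.asarray(m, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("empty map")
    if m.min() == m.max():
        return float(m.flat[0])
    counts, edges = np.histogram(m, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    # cumulative class probability and mean for thresholds after each bin
    omega0 = np.cumsum(w)
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    between = np.full(nbins, -np.inf)
    between[valid] = (mu_total * omega0[valid] - mu_cum[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    return float(centers[k])


def segment_by_stat(
    enh: np.ndarray,
    mode: str = "uniform_mean",
    p: ActivationParams | None = None,
) -> np.ndarray:
    """Segment an enhanced image (RGB or grayscale) with one statistic.

    mode is ``"uniform_mean"`` (range midpoint) or ``"normal_md"`` (normal
    mean absolute deviation). Returns a {0,1} uint8 mask of the image shape,
    foreground being the darker intensity class. A constant image yields an
    all-background mask.
    """
    p = p or ActivationParams()
    gray = rgb_to_luminance(enh)
    if mode == "uniform_mean":
        stat = uniform_mean(gray).mu
    elif mode == "normal_md":
        stat = normal_mad(gray).md
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if stat <= 0 or gray.min() == gray.max():
        logger.warning("degenerate image (constant or zero statistic): empty mask")
        return np.zeros(gray.shape, dtype=np.uint8)

    amap = _normalize01(activation_map(gray, stat, p))
    thresh = otsu_threshold(amap)
    mask = (amap >= thresh).astype(np.uint8)
    if mask.min() == mask.max():
        logger.warning("degenerate segmentation: single-class mask")
        return np.zeros(gray.shape, dtype=np.uint8) if mask.max() == 0 else mask

    # polarity: foreground (1) must be the darker class in the enhanced image
    if gray[mask == 1].mean() > gray[mask == 0].mean():
        mask = 1 - mask
    return mask


class ActivationSegmenter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer producing a lesion mask from an enhanced image.

    ``mode`` selects the driving statistic; ``"both"`` returns the pair
    (mean mask, M.D mask) for downstream fusion.
    """

    def __init__(self, mode: str = "both", alpha: int = 7, c_act: float = 0.5):
        self.mode = mode
        self.alpha = alpha
        self.c_act = c_act

    def _segment_one(self, img: np.ndarray):
        p = ActivationParams(alpha=self.alpha, c_act=self.c_act)
        if self.mode == "both":
            return (
                segment_by_stat(img, "uniform_mean", p),
                segment_by_stat(img, "normal_md", p),
            )
        return segment_by_stat(img, self.mode, p)

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, np.ndarray) and X.ndim in (2, 3):
            return self._segment_one(X)
        return [self._segment_one(img) for img in X]
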
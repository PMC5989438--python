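"""Multi-level feature extraction and zero-padded parallel fusion.

Three descriptor families are computed per segmented lesion:

* **HOG** (shape): 9 unsigned orientation bins, 8x8-pixel cells, 2x2-cell
  blocks with 8-pixel stride and L2-Hys normalization on a 64x128 window
  -> 7 x 15 blocks x 36 = 3780 values, reduced to 200 by a PCA-weighted
  histogram-entropy score (:class:`HogEntropyReducer`).
* **Haralick texture**: 14 gray-level co-occurrence statistics at distance 1
  for the 0/45/90/135 degree offsets (32 quantization levels, symmetric,
  normalized GLCMs); per statistic the mean, range and variance across the
  four offsets -> 42 values.
* **Color moments**: mean, population variance, skewness and excess
  kurtosis of the lesion pixels in each channel of RGB, HSI and CIELAB
  -> 36 values.

Parallel fusion zero-pads texture and color to the HOG length (200) and
combines them as the sum of two complex magnitudes per position:
``g_k = |h_k + i t_k| + |h_k + i c_k| = sqrt(h^2 + t^2) + sqrt(h^2 + c^2)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats
from skimage.color import rgb2gray, rgb2lab
from skimage.feature import graycomatrix
from skimage.feature import hog as _skimage_hog
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "HOG_WINDOW",
    "HOG_LENGTH",
    "TEXTURE_LENGTH",
    "COLOR_LENGTH",
    "FUSED_LENGTH",
    "crop_and_resize",
    "extract_hog",
    "HogEntropyReducer",
    "glcm_features",
    "color_moments",
    "parallel_fuse",
    "zero_pad",
    "texture_feature_names",
    "color_feature_names",
]

#: HOG window as (rows, cols) — 64 px wide x 128 px tall
HOG_WINDOW = (128, 64)
HOG_LENGTH = 3780
TEXTURE_LENGTH = 42
COLOR_LENGTH = 36
FUSED_LENGTH = 200

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

#: the 14 Haralick statistics, in output order
HARALICK_STATS = (
    "autocorr",
    "contrast",
    "cluster_prom",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homog1",
    "homog2",
    "max_prob",
    "average",
    "variance",
    "idn",
    "idmn",
)

COLOR_CHANNELS = (
    "rgb_r", "rgb_g", "rgb_b",
    "hsi_h", "hsi_s", "hsi_i",
    "lab_l", "lab_a", "lab_b",
)
_MOMENTS = ("mean", "var", "skew", "kurt")


# ---------------------------------------------------------------------------
# region preparation and HOG


def crop_and_resize(
    img: np.ndarray, mask: np.ndarray, out_shape: tuple[int, int] = HOG_WINDOW
) -> np.ndarray:
    """Crop the mask bounding box with a 10% margin, zero the background,
    and resize to the HOG window. Raises on an empty mask."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if mask.max() == 0:
        raise ValueError(
            "empty mask: segmentation was degenerate; skip or re-segment the sample"
        )
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = max(1, int(round(0.1 * (r1 - r0))))
    mc = max(1, int(round(0.1 * (c1 - c0))))
    r0, r1 = max(0, r0 - mr), min(mask.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(mask.shape[1], c1 + mc)
    crop = img[r0:r1, c0:c1].copy()
    crop[mask[r0:r1, c0:c1] == 0] = 0.0
    return resize(crop, out_shape, order=1, mode="reflect", anti_aliasing=True,
                  preserve_range=True)


def extract_hog(crop: np.ndarray) -> np.ndarray:
    """HOG descriptor of a (128, 64) crop; always 3780 values."""
    crop = np.asarray(crop, dtype=float)
    if crop.ndim == 3:
        crop = rgb2gray(crop)
    if crop.shape != HOG_WINDOW:
        crop = resize(crop, HOG_WINDOW, order=1, mode="reflect",
                      anti_aliasing=True, preserve_range=True)
    vec = _skimage_hog(
        crop,
        orientations=9,
        pixels_per_cell=(8, 8),
        cells_per_block=(2, 2),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    assert vec.shape == (HOG_LENGTH,)
    return vec


class HogEntropyReducer(BaseEstimator, TransformerMixin):
    """Reduce HOG vectors (n_samples x 3780) to the 200 top-scoring columns.

    Each column f receives a weight ``W_f`` from PCA importance — the sum
    over components of |loading| times the component's explained-variance
    share, min-max normalized to [0, 1] — and an information content
    ``H_f``, the Shannon entropy (base 2) of the column's 16-bin histogram.
    The score is ``W_f * H_f``; the ``n_keep`` highest-scoring column
    indices are frozen in ``selected_idx_`` (ties toward the lower index)
    and reused verbatim at prediction time. Constant (zero-entropy) columns
    are never selected ahead of informative ones.
    """

    def __init__(self, n_keep: int = FUSED_LENGTH, n_bins: int = 16):
        self.n_keep = n_keep
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 samples")
        if X.shape[1] < self.n_keep:
            raise ValueError(
                f"cannot keep {self.n_keep} of {X.shape[1]} features"
            )
        pca = PCA(n_components=min(X.shape) - 1 if min(X.shape) > 1 else 1,
                  svd_solver="full")
        pca.fit(X)
        evr = pca.explained_variance_ratio_
        weights = np.abs(pca.components_).T @ evr
        span = weights.max() - weights.min()
        if span > 0:
            weights = (weights - weights.min()) / span
        else:
            weights = np.ones_like(weights)

        entropy = np.array([_column_entropy(col, self.n_bins) for col in X.T])
        self.weights_ = weights
        self.entropy_ = entropy
        self.scores_ = weights * entropy
        order = np.argsort(-self.scores_, kind="stable")  # ties -> lower index
        self.selected_idx_ = np.sort(order[: self.n_keep])
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_idx_]


def _column_entropy(col: np.ndarray, n_bins: int) -> float:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(col, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Haralick texture


def _haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 14 statistics of one normalized symmetric GLCM (levels x levels).

    Gray-level indices are 1-based in the weighted sums. Entropy uses
    base-2 logarithms.
    """
    L = P.shape[0]
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, L + 1)[None, :]
    px = P.sum(axis=1)
    mu_x = float((np.arange(1, L + 1) * px).sum())  # = mu_y by symmetry
    diff = i - j
    s = i + j - 2.0 * mu_x
    nz = P[P > 0]
    return np.array([
        float((i * j * P).sum()),                          # autocorrelation
        float((diff ** 2 * P).sum()),                      # contrast
        float((s ** 4 * P).sum()),                         # cluster prominence
        float((s ** 3 * P).sum()),                         # cluster shade
        float((np.abs(diff) * P).sum()),                   # dissimilarity
        float((P ** 2).sum()),                             # energy (ASM)
        float(-(nz * np.log2(nz)).sum()),                  # entropy
        float((P / (1.0 + np.abs(diff))).sum()),           # homogeneity 1
        float((P / (1.0 + diff ** 2)).sum()),              # homogeneity 2
        float(P.max()),                                    # maximum probability
        mu_x,                                              # average
        float(((i - mu_x) ** 2 * P).sum()),                # variance
        float((P / (1.0 + np.abs(diff) / L)).sum()),       # inv diff normalized
        float((P / (1.0 + diff ** 2 / L ** 2)).sum()),     # inv diff moment norm
    ])


def glcm_features(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """42-value Haralick texture vector of the masked region.

    Intensities inside the mask's bounding box are quantized to 32 levels;
    symmetric normalized GLCMs are built at distance 1 for the four
    principal offsets; the output is, per statistic, its (mean, range,
    variance) across offsets, in :data:`HARALICK_STATS` order.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask)
    if mask.sum() < 4:
        raise ValueError("masked region must contain at least 4 pixels")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = gray[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    lo, hi = box.min(), box.max()
    if hi == lo:
        quant = np.zeros(box.shape, dtype=np.uint8)
    else:
        quant = np.floor((box - lo) / (hi - lo) * (GLCM_LEVELS - 1e-9)).astype(np.uint8)
    glcm = graycomatrix(
        quant, distances=[1], angles=list(GLCM_ANGLES),
        levels=GLCM_LEVELS, symmetric=True, normed=True,
    )
    per_offset = np.stack(
        [_haralick_stats(glcm[:, :, 0, a]) for a in range(len(GLCM_ANGLES))]
    )  # (4, 14)
    mean = per_offset.mean(axis=0)
    rng = per_offset.max(axis=0) - per_offset.min(axis=0)
    var = per_offset.var(axis=0)
    return np.column_stack([mean, rng, var]).ravel()  # stat-major


def texture_feature_names() -> list[str]:
    return [f"tex_{s}_{m}" for s in HARALICK_STATS for m in ("mean", "range", "var")]


# ---------------------------------------------------------------------------
# color moments


def _rgb_to_hsi(rgb01: np.ndarray) -> np.ndarray:
    """HSI per pixel from RGB in [0, 1]; H scaled from radians to [0, 1]."""
    r, g, b = rgb01[:, 0], rgb01[:, 1], rgb01[:, 2]
    ssum = r + g + b
    intensity = ssum / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(ssum > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / ssum, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.arccos(np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), 0.0),
                                  -1.0, 1.0))
    hue = np.where(b <= g, theta, 2.0 * np.pi - theta) / (2.0 * np.pi)
    return np.column_stack([hue, sat, intensity])


def _moments(col: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(col.mean())
    var = float(col.var())  # population
    # constant channel up to conversion round-off: higher moments undefined
    if var <= 1e-18 * (1.0 + mean * mean):
        return mean, 0.0, 0.0, 0.0
    return (
        mean,
        var,
        float(sstats.skew(col, bias=True)),
        float(sstats.kurtosis(col, fisher=True, bias=True)),
    )


def color_moments(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """36-value color vector: (mean, variance, skewness, excess kurtosis)
    per channel of RGB (0-255 scale), HSI and CIELAB, lesion pixels only."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if mask.sum() < 2:
        raise ValueError("masked region must contain at least 2 pixels")
    px = img[mask.astype(bool)]  # (N, 3), 0..255
    rgb01 = np.clip(px / 255.0, 0.0, 1.0)
    hsi = _rgb_to_hsi(rgb01)
    lab = rgb2lab(rgb01.reshape(-1, 1, 3)).reshape(-1, 3)
    out = []
    for space in (px, hsi, lab):
        for c in range(3):
            out.extend(_moments(space[:, c]))
    return np.asarray(out)


def color_feature_names() -> list[str]:
    return [f"col_{ch}_{m}" for ch in COLOR_CHANNELS for m in _MOMENTS]


# ---------------------------------------------------------------------------
# parallel fusion


def zero_pad(v: np.ndarray, n: int) -> np.ndarray:
    """Right-pad a vector with zeros to length n."""
    v = np.asarray(v, dtype=float)
    if v.size > n:
        raise ValueError(f"vector of length {v.size} longer than target {n}")
    out = np.zeros(n)
    out[: v.size] = v
    return out


def parallel_fuse(
    hog200: np.ndarray, texture42: np.ndarray, color36: np.ndarray
) -> np.ndarray:
    """Fuse the three blocks into one 200-vector of complex magnitudes.

    Texture and color are zero-padded to the HOG length; position k fuses to
    ``sqrt(h_k^2 + t_k^2) + sqrt(h_k^2 + c_k^2)``.
    """
    h = np.asarray(hog200, dtype=float)
    t = np.asarray(texture42, dtype=float)
    c = np.asarray(color36, dtype=float)
    if h.size != FUSED_LENGTH or t.size != TEXTURE_LENGTH or c.size != COLOR_LENGTH:
        raise ValueError(
            f"expected lengths {FUSED_LENGTH}/{TEXTURE_LENGTH}/{COLOR_LENGTH}, "
            f"got {h.size}/{t.size}/{c.size}"
        )
    tp = zero_pad(t, FUSED_LENGTH)
    cp = zero_pad(c, FUSED_LENGTH)
    return np.abs(h + 1j * tp) + np.abs(h + 1j * cp)
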
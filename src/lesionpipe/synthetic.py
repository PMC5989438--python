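"""Seeded generator of dermoscopic-like phantom images with ground truth.

Each phantom emulates the statistical structure of a dermoscopic archive
image: a lighter warm-toned skin background with a smooth illumination
gradient and Gaussian sensor noise, a roughly elliptical hypo-intense
lesion covering 5-40% of the image, and optional dark curvilinear hair
strokes. The lesion is a star-convex blob with radius
``r(theta) = r0 * (1 + a * sum of low-order sinusoids)``; the class label
controls three effect sizes:

===============  ==============  ===================  ===============
class            base intensity  border irregularity  variegation sd
===============  ==============  ===================  ===============
melanoma         40 +- 10        0.35                 18
atypical_nevus   90 +- 10        0.20                 10
benign           140 +- 10       0.08                 5
===============  ==============  ===================  ===============

so darkness, border irregularity and color variegation are each
class-conditional and ordered melanoma < atypical < benign in intensity.
The mask is the exact rasterization of the generated blob (no annotation
noise), and generation is byte-identical for identical (config, label,
seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import bezier_curve

__all__ = [
    "CLASS_ORDER",
    "ClassParams",
    "GenConfig",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "load_dataset",
]

CLASS_ORDER = ("melanoma", "benign", "atypical_nevus")


@dataclass
class ClassParams:
    base_intensity: float       # mean lesion gray level
    intensity_sd: float         # per-sample spread of the base level
    irregularity: float         # radial perturbation amplitude a
    variegation_sd: float       # per-channel smooth color jitter inside lesion


@dataclass
class GenConfig:
    image_size: tuple[int, int] = (256, 256)
    lesion_area_frac: tuple[float, float] = (0.05, 0.40)
    class_params: dict = field(default_factory=lambda: {
        "melanoma": ClassParams(40.0, 10.0, 0.35, 18.0),
        "atypical_nevus": ClassParams(90.0, 10.0, 0.20, 10.0),
        "benign": ClassParams(140.0, 10.0, 0.08, 5.0),
    })
    skin_rgb: tuple[float, float, float] = (205.0, 160.0, 140.0)
    illumination_amplitude: float = 25.0
    noise_sd: float = 5.0
    hair_prob: float = 0.3
    blur_sigma: float = 0.8

    def __post_init__(self) -> None:
        lo, hi = self.lesion_area_frac
        if not 0 < lo < hi <= 0.5:
            raise ValueError(f"infeasible lesion area bounds {self.lesion_area_frac}")
        if not 0 <= self.hair_prob <= 1:
            raise ValueError("hair_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        # JSON round-trip so tuples become lists, matching manifests on disk
        return json.loads(json.dumps(dataclasses.asdict(self)))


@dataclass
class SyntheticSample:
    image: np.ndarray   # (H, W, 3) uint8
    mask: np.ndarray    # (H, W) uint8 {0, 1}
    label: str
    params_used: dict


def _star_mask(rng, shape, r0, irregularity):
    """Exact rasterization of a star-convex blob centered near the image
    middle; returns (mask, radius field parameters)."""
    h, w = shape
    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    ks = np.arange(2, 6)
    amps = rng.uniform(0.3, 1.0, size=ks.size)
    amps = amps / amps.sum()  # max |perturbation| <= irregularity
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    th = np.arctan2(dy, dx)
    perturb = sum(a * np.sin(k * th + p) for a, k, p in zip(amps, ks, phases))

    def mask_for(r):
        return (rr <= r * (1.0 + irregularity * perturb)).astype(np.uint8)

    return mask_for, (cy, cx)


def _smooth_field(rng, shape, sd, sigma=6.0):
    """Zero-mean smooth random field rescaled to standard deviation sd."""
    f = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=sigma)
    s = f.std()
    return f * (sd / s) if s > 0 else f


def generate_sample(cfg: GenConfig, label: str, seed) -> SyntheticSample:
    """Generate one phantom image, its exact mask, and the label."""
    if label not in cfg.class_params:
        raise ValueError(f"unknown label {label!r}; known: {sorted(cfg.class_params)}")
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    cp = cfg.class_params[label]
    lo, hi = cfg.lesion_area_frac

    # lesion geometry: sample a target area fraction, build the blob, then
    # rescale the base radius once so the rasterized area matches it
    target = rng.uniform(lo, hi)
    r0 = np.sqrt(target * h * w / np.pi)
    r_max = (min(h, w) / 2.0 - 6.0) / (1.0 + cp.irregularity)
    r0 = min(r0, r_max)
    mask_for, _ = _star_mask(rng, (h, w), r0, cp.irregularity)
    mask = mask_for(r0)
    actual = mask.sum() / (h * w)
    r0 = min(r0 * np.sqrt(target / actual), r_max)
    mask = mask_for(r0)
    frac = mask.sum() / (h * w)
    if not lo <= frac <= hi:
        raise ValueError(
            f"infeasible lesion area fraction {frac:.3f} for image size {cfg.image_size}"
        )

    # background: warm skin base + illumination plane + noise
    base = np.array(cfg.skin_rgb) + rng.normal(0.0, 6.0, size=3)
    img = np.ones((h, w, 3)) * base
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(phi) * xx + np.sin(phi) * yy) / np.hypot(h, w)
    img += cfg.illumination_amplitude * (ramp - ramp.mean())[..., None]

    # lesion fill: class-conditional darkness + smooth variegation
    g = max(5.0, rng.normal(cp.base_intensity, cp.intensity_sd))
    lesion_rgb = np.array([1.15 * g, 0.95 * g, 0.85 * g])
    inside = mask.astype(bool)
    for c in range(3):
        varieg = _smooth_field(rng, (h, w), cp.variegation_sd)
        ch = img[..., c]
        ch[inside] = lesion_rgb[c] + varieg[inside]

    # optional dark curvilinear hairs across the frame
    if rng.random() < cfg.hair_prob:
        for _ in range(int(rng.integers(1, 4))):
            pts = rng.integers(0, [h, w, h, w, h, w])
            rrh, cch = bezier_curve(
                int(pts[0]), int(pts[1]), int(pts[2]), int(pts[3]),
                int(pts[4]), int(pts[5]), weight=1.0, shape=(h, w),
            )
            stroke = np.zeros((h, w), dtype=bool)
            stroke[rrh, cch] = True
            stroke = ndimage.binary_dilation(stroke, iterations=1)
            img[stroke] = 0.6 * img[stroke] + 0.4 * np.array([35.0, 25.0, 20.0])

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = ndimage.gaussian_filter(img, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    img = np.clip(img, 0, 255).astype(np.uint8)

    return SyntheticSample(
        image=img,
        mask=mask,
        label=label,
        params_used={
            "label": label,
            "area_frac": float(frac),
            "base_intensity": float(g),
            "irregularity": cp.irregularity,
            "variegation_sd": cp.variegation_sd,
        },
    )


def generate_dataset(
    cfg: GenConfig,
    n_per_class: int,
    seed: int,
    out_dir: str | Path | None = None,
    classes: tuple[str, ...] = CLASS_ORDER,
):
    """Generate a stratified phantom dataset.

    Returns ``(samples, manifest)``; when ``out_dir`` is given also writes
    ``images/``, ``masks/`` (8-bit PNG, {0, 255}), ``labels.csv`` and
    ``manifest.json`` recording the config and every per-sample seed.
    """
    samples = []
    entries = []
    idx = 0
    for label in classes:
        for _ in range(n_per_class):
            ss = np.random.SeedSequence([int(seed), idx])
            s = generate_sample(cfg, label, ss)
            samples.append(s)
            entries.append({
                "index": idx,
                "filename": f"{idx:04d}_{label}.png",
                "label": label,
                "seed": [int(seed), idx],
                "params": s.params_used,
            })
            idx += 1
    manifest = {
        "seed": int(seed),
        "n_per_class": int(n_per_class),
        "classes": list(classes),
        "config": cfg.to_dict(),
        "samples": entries,
    }
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        rows = ["filename,label"]
        for s, e in zip(samples, entries):
            Image.fromarray(s.image).save(out / "images" / e["filename"])
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                out / "masks" / e["filename"]
            )
            rows.append(f"{e['filename']},{e['label']}")
        (out / "labels.csv").write_text("\n".join(rows) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return samples, manifest


def load_dataset(out_dir: str | Path):
    """Reload a dataset written by :func:`generate_dataset`."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    samples = []
    for e in manifest["samples"]:
        img = np.asarray(Image.open(out / "images" / e["filename"]))
        mask = (np.asarray(Image.open(out / "masks" / e["filename"])) > 127).astype(
            np.uint8
        )
        samples.append(
            SyntheticSample(image=img, mask=mask, label=e["label"],
                            params_used=e["params"])
        )
    return samples, manifest
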
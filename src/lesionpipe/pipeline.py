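"""End-to-end orchestration: enhance -> segment x2 -> fuse -> features ->
select -> classify, with a YAML-round-trippable configuration and a loader
seam for external archives.

The per-image stages (enhancement, the two probabilistic segmentations,
union fusion, raw feature extraction) are deterministic functions of the
input; the data-dependent stages (HOG reduction, entropy-variance
selection, SVM) live in :class:`~lesionpipe.classify.LesionClassifier` and
are fitted inside the chosen validation protocol only on training folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classify import LesionClassifier, EvalResult, evaluate_protocol
from .enhance import EnhanceParams, stretch_contrast
from .features import (
    color_feature_names,
    color_moments,
    crop_and_resize,
    extract_hog,
    glcm_features,
    texture_feature_names,
    HOG_LENGTH,
)
from .fuse import fuse_union, postprocess
from .segment import ActivationParams, rgb_to_luminance, segment_by_stat

__all__ = [
    "PipelineConfig",
    "segment_image",
    "extract_raw_features",
    "raw_feature_names",
    "run_pipeline",
    "load_external_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's parameter block plus seeds and protocol choice."""

    beta: float = 3.0
    grid_rows: int = 3
    grid_cols: int = 4
    log_sigma: float = 2.0
    alpha: int = 7
    c_act: float = 0.5
    keep_largest: bool = True
    fill_holes: bool = True
    n_hog_keep: int = 200
    n_select: int = 172
    svm_c: float = 1.0
    protocol: str = "holdout_50_50"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def enhance_params(self) -> EnhanceParams:
        return EnhanceParams(beta=self.beta, log_sigma=self.log_sigma,
                             grid_rows=self.grid_rows, grid_cols=self.grid_cols)

    def activation_params(self) -> ActivationParams:
        return ActivationParams(alpha=self.alpha, c_act=self.c_act)


def segment_image(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Enhance, segment with both statistics, fuse, post-process."""
    cfg = cfg or PipelineConfig()
    enh = stretch_contrast(img, cfg.enhance_params())
    ap = cfg.activation_params()
    m_mean = segment_by_stat(enh, "uniform_mean", ap)
    m_md = segment_by_stat(enh, "normal_md", ap)
    fused = fuse_union(m_mean, m_md)
    return postprocess(fused, keep_largest=cfg.keep_largest,
                       fill_holes=cfg.fill_holes)


def extract_raw_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Concatenated raw descriptor row [hog 3780 | texture 42 | color 36]."""
    crop = crop_and_resize(img, mask)
    hog = extract_hog(crop)
    gray = rgb_to_luminance(img)
    tex = glcm_features(gray, mask)
    col = color_moments(img, mask)
    return np.concatenate([hog, tex, col])


def raw_feature_names() -> list[str]:
    return (
        [f"hog_{i:04d}" for i in range(HOG_LENGTH)]
        + texture_feature_names()
        + color_feature_names()
    )


def run_pipeline(
    images,
    masks=None,
    labels=None,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Run the full pipeline over a list of images.

    When ``masks`` is given segmentation is skipped and features are
    computed from the provided masks. When ``labels`` is given the chosen
    validation protocol is run and an :class:`EvalResult` is returned in
    the artifact dict. Samples whose fused mask is empty are skipped and
    counted. Identical config + seed reproduce identical artifacts.
    """
    cfg = cfg or PipelineConfig()
    predicted_masks = []
    rows, kept, skipped = [], [], []
    for k, img in enumerate(images):
        mask = masks[k] if masks is not None else segment_image(img, cfg)
        predicted_masks.append(mask)
        if mask.max() == 0 or mask.sum() < 4:
            logger.warning("sample %d: degenerate mask, skipped", k)
            skipped.append(k)
            continue
        rows.append(extract_raw_features(img, mask))
        kept.append(k)

    names = raw_feature_names()
    X = np.asarray(rows).reshape(len(rows), len(names))
    features = pd.DataFrame(X, columns=names, index=kept)
    artifacts = {
        "masks": predicted_masks,
        "features": features,
        "skipped": skipped,
        "config_digest": cfg.digest(),
    }

    if labels is not None and len(kept) > 0:
        y = np.asarray(labels)[kept]
        result: EvalResult = evaluate_protocol(
            X, y, protocol=cfg.protocol, seed=cfg.seed,
            estimator=LesionClassifier(n_hog_keep=cfg.n_hog_keep,
                                       n_select=cfg.n_select, C=cfg.svm_c),
        )
        artifacts["evaluation"] = result

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        for k, m in enumerate(predicted_masks):
            Image.fromarray((np.asarray(m) * 255).astype(np.uint8)).save(
                out / "masks" / f"{k:04d}.png"
            )
        features.to_csv(out / "features.csv", index_label="sample")
        prov = {"config_digest": cfg.digest(), "seed": cfg.seed,
                "skipped": skipped, "config": dataclasses.asdict(cfg)}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        if "evaluation" in artifacts:
            res = artifacts["evaluation"]
            pd.DataFrame(
                res.confusion, index=res.classes, columns=res.classes
            ).to_csv(out / "confusion.csv")
            rep = dataclasses.asdict(res.report)
            (out / "report.json").write_text(json.dumps(rep, indent=2))
    return artifacts


def load_external_dataset(directory: str | Path, layout: str = "flat_masks"):
    """Load an external archive into the internal dataset shape.

    ``flat_masks`` expects ``images/`` plus optional ``masks/`` (matching
    filenames) and optional ``labels.csv`` (filename,label). Corrupt images
    are skipped with a logged filename; a missing masks directory flags the
    dataset mask-less.
    """
    root = Path(directory)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    if layout != "flat_masks":
        raise ValueError(f"unsupported layout {layout!r} (supported: flat_masks)")
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise ValueError(f"layout mismatch: {img_dir} missing")
    mask_dir = root / "masks"
    has_masks = mask_dir.is_dir()
    label_map = {}
    if (root / "labels.csv").exists():
        df = pd.read_csv(root / "labels.csv")
        label_map = dict(zip(df["filename"], df["label"]))

    images, masks, labels, names = [], [], [], []
    for f in sorted(img_dir.iterdir()):
        try:
            img = np.asarray(Image.open(f).convert("RGB"))
        except Exception:
            logger.warning("corrupt image skipped: %s", f.name)
            continue
        images.append(img)
        names.append(f.name)
        if has_masks and (mask_dir / f.name).exists():
            masks.append(
                (np.asarray(Image.open(mask_dir / f.name).convert("L")) > 127
                 ).astype(np.uint8)
            )
        else:
            masks.append(None)
        labels.append(label_map.get(f.name))

    dataset = {
        "images": images,
        "masks": masks if any(m is not None for m in masks) else None,
        "labels": labels if any(l is not None for l in labels) else None,
        "filenames": names,
        "has_masks": any(m is not None for m in masks),
    }
    return dataset
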
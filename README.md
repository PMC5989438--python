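# lesionpipe

Detection and classification of skin lesions in dermoscopic RGB images.
`lesionpipe` implements a classical (non-deep-learning) pipeline aimed at
melanoma screening: the lesion is first localized by probabilistic-
distribution segmentation, then described by fused multi-level features,
and finally classified into {melanoma, benign, atypical nevus} by a
one-against-all linear SVM. A seeded dermoscopic *phantom* generator with
exact ground-truth masks makes every stage testable without access to the
public archives (PH2, ISIC, ISBI) such pipelines are usually evaluated on.

## The method

1. **Contrast stretching.** Each channel is split into a 3×4 block grid.
   Per block, a quartile coefficient ς ∈ {0.25, 0.5, 0.75, 1.0} from the
   block's Sobel-gradient sum and an edge weight *B*<sub>w</sub> =
   *E*<sub>p</sub>/*E*<sub>max</sub> from Laplacian-of-Gaussian (σ = 2)
   zero-crossing counts combine into a gain that preserves contrast in
   detail-rich blocks and flattens flat ones; the result is rescaled to
   [0, 255] and log-stretched, φ(t) = C·log(β + v) with β = 3 and
   C = 255/log(β + 255).
2. **Segmentation.** Two scalar statistics of the enhanced gray image —
   the uniform-distribution mean μ = (min + max)/2 and the normal
   mean absolute deviation M.D = 0.7979 σ — each drive a per-pixel
   activation A(v) = 1/(1 + stat/v)<sup>α</sup> + 1/(2·stat) + C with
   α = 7, thresholded by Otsu's method (256 bins). Foreground is the
   darker class (lesions are hypo-intense).
3. **Fusion.** The two masks are combined by per-pixel logical OR (the
   additive law of probability), then the largest 8-connected component is
   kept and holes are filled.
4. **Features.** From the masked lesion: HOG shape descriptor
   (64×128 window, 9 bins, 8×8 cells, 2×2 blocks, L2-Hys → 1×3780,
   reduced to 1×200 by a PCA-weighted histogram-entropy score), 14
   Haralick GLCM statistics × {mean, range, variance} over 4 offsets
   (1×42), and {mean, variance, skewness, kurtosis} per channel of RGB,
   HSI and CIELAB (1×36). Texture and color are zero-padded to 200 and
   fused per position as the sum of complex magnitudes
   √(h² + t²) + √(h² + c²).
5. **Selection.** Unsupervised entropy-controlled selection scores every
   fused column by (adjacent-pair Bhattacharyya closeness) × |variance
   log-ratio| × (16-bin histogram entropy) and keeps the top 172.
6. **Classification.** One binary linear SVM (C = 1) per class on
   z-scored features; prediction is the argmax decision value. Evaluation
   follows a stratified 50:50 holdout or 10-fold cross-validation, with
   reduction/selection/scaling refit on training folds only.

The estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores), so
`HogEntropyReducer`, `EntropyVarianceSelector`, `OneVsAllSVM` and the
composite `LesionClassifier` compose with sklearn model selection.

## Worked example

```python
import numpy as np
from lesionpipe import GenConfig, generate_dataset, mask_metrics
from lesionpipe.pipeline import segment_image, extract_raw_features
from lesionpipe.classify import evaluate_protocol

samples, _ = generate_dataset(GenConfig(), n_per_class=50, seed=0)
X, y = [], []
for s in samples:
    mask = segment_image(s.image.astype(float))
    print(f"{s.label:15s} Dice {mask_metrics(mask, s.mask).dice:.3f}")
    X.append(extract_raw_features(s.image.astype(float), mask))
    y.append(s.label)

res = evaluate_protocol(np.array(X), np.array(y),
                        protocol="holdout_50_50", seed=0)
print(f"accuracy {res.report.accuracy:.2f}%  "
      f"sensitivity {res.report.sensitivity:.2f}%  AUC {res.report.auc:.3f}")
print(res.confusion)
```

prints (abridged):

```
melanoma        Dice 0.999
benign          Dice 0.960
atypical_nevus  Dice 0.990
...
accuracy 94.67%  sensitivity 94.67%  AUC 0.958
[[21  3  1]
 [ 0 25  0]
 [ 0  0 25]]
```

i.e. the fused segmentation recovers the exact phantom masks almost
perfectly (median Dice ≈ 0.997 over 100 phantoms), and the full chain
separates the three lesion classes at ~95% accuracy on the held-out half;
the three confusion rows are atypical nevus / benign / melanoma.

The same stages are available from the shell:

```bash
lesionpipe synth --n 50 --seed 0 --out data/
lesionpipe segment data/images/0000_melanoma.png mask.png
lesionpipe eval-mask mask.png data/masks/0000_melanoma.png
lesionpipe run --data data/ --out artifacts/
```

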
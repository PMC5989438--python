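"""Entropy-controlled feature selection on the fused 200-vector.

Selection is unsupervised and purely a function of the training matrix.
Three ingredients are combined per feature column:

* **closeness** — the Bhattacharyya distance between adjacent feature
  columns, each (non-negative) column normalized to sum 1 across samples so
  it reads as a discrete distribution; a feature's closeness is the mean
  distance over the (one or two) adjacent pairs that contain it;
* **variance term** — a log-ratio of the column's mean and population
  variance, ``ln(m + s2 + eps) / (|ln(m + s2 + eps)| + |ln(|m - s2| + eps)|)``
  with ``eps = 1e-9`` guarding non-positive logarithms;
* **entropy** — base-2 Shannon entropy of the column's 16-bin histogram,
  with bin probabilities ``H_b / sum_b H_b``.

The per-feature score is the product closeness x |variance term| x entropy;
the ``n_keep`` (default 172) highest-scoring columns are retained, ties
broken toward the lower index, and the index set is frozen for reuse on
test data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["BC_FLOOR", "bhattacharyya_adjacent", "EntropyVarianceSelector"]

#: Bhattacharyya coefficients are clamped to [BC_FLOOR, 1] before the log,
#: capping the distance at -ln(1e-12) for disjoint supports
BC_FLOOR = 1e-12

_EPS = 1e-9


def _column_distributions(X: np.ndarray) -> np.ndarray:
    """Normalize each (non-negative) column to sum 1 across samples so it
    reads as a discrete distribution; an all-zero column becomes uniform."""
    sums = X.sum(axis=0, keepdims=True)
    n = X.shape[0]
    return np.where(sums > 0, X / np.where(sums > 0, sums, 1.0), 1.0 / n)


def bhattacharyya_adjacent(train: np.ndarray) -> np.ndarray:
    """Bhattacharyya distance between each adjacent feature-column pair.

    Returns a vector of length ``n_features - 1``;
    ``bd[i] = -ln(sum_u sqrt(p_i(u) p_{i+1}(u)))`` where p is the column
    normalized to sum 1, with the coefficient clamped to [1e-12, 1].
    Identical columns give 0; disjoint supports give the cap ``-ln(1e-12)``.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(X < 0):
        raise ValueError("fused features must be non-negative")
    P = _column_distributions(X)
    bc = np.sum(np.sqrt(P[:, :-1] * P[:, 1:]), axis=0)
    bc = np.clip(bc, BC_FLOOR, 1.0)
    return -np.log(bc)


class EntropyVarianceSelector(BaseEstimator, TransformerMixin):
    """Select the ``n_keep`` top-scoring columns of a fused feature matrix.

    Fitted attributes: ``bd_`` (adjacent Bhattacharyya distances),
    ``closeness_``, ``variance_term_``, ``entropy_``, ``scores_`` and the
    frozen ascending index set ``selected_idx_``.
    """

    def __init__(self, n_keep: int = 172, n_bins: int = 16):
        self.n_keep = n_keep
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        n_samples, n_features = X.shape
        if self.n_keep > n_features:
            raise ValueError(
                f"cannot keep {self.n_keep} of {n_features} features"
            )
        bd = bhattacharyya_adjacent(X)

        closeness = np.empty(n_features)
        closeness[0] = bd[0]
        closeness[-1] = bd[-1]
        closeness[1:-1] = 0.5 * (bd[:-1] + bd[1:])

        m = X.mean(axis=0)
        s2 = X.var(axis=0)  # population
        num = np.log(m + s2 + _EPS)
        den = np.abs(num) + np.abs(np.log(np.abs(m - s2) + _EPS))
        variance_term = num / den

        entropy = np.empty(n_features)
        for f in range(n_features):
            col = X[:, f]
            lo, hi = col.min(), col.max()
            if hi == lo:
                entropy[f] = 0.0
                continue
            counts, _ = np.histogram(col, bins=self.n_bins, range=(lo, hi))
            p = counts[counts > 0] / counts.sum()
            entropy[f] = -(p * np.log2(p)).sum()

        scores = closeness * np.abs(variance_term) * entropy
        order = np.argsort(-scores, kind="stable")  # ties -> lower index
        self.bd_ = bd
        self.closeness_ = closeness
        self.variance_term_ = variance_term
        self.entropy_ = entropy
        self.scores_ = scores
        self.selected_idx_ = np.sort(order[: self.n_keep])
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_idx_]
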
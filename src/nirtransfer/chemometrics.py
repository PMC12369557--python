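"""PCA diagnostics, the sorted-interleaved calibration split, and metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAModel",
    "Metrics",
    "pca_fit",
    "sorted_interleaved_split",
    "compute_metrics",
]


@dataclass
class PCAModel:
    """Mean-centered PCA of a spectral matrix.

    loadings : (d, k) orthonormal columns; per-column sign fixed so the
        largest-magnitude element is positive.
    explained_variance_ratio : fraction of total variance per component.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_spectrum) @ self.loadings


def fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip columns of ``V`` so each column's largest-|.| entry is positive."""
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit mean-centered PCA with ``k`` components via SVD."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    r = min(n - 1, d)
    if not (1 <= k <= r):
        raise ValueError(f"k={k} out of range [1, {r}]")
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    var = s**2
    total = var.sum()
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return PCAModel(
        mean_spectrum=mean,
        loadings=fix_signs(Vt[:k].T),
        explained_variance_ratio=ratio,
    )


def sorted_interleaved_split(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2:1 calibration/prediction split by interleaving the y-sorted order.

    Samples are stably sorted by target (ties by original index) and
    grouped into consecutive triples; within each triple the first and
    third go to calibration, the second to prediction.  A trailing
    remainder of one or two samples goes to calibration.  Returns
    (calibration indices, prediction indices) into the original order.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"split needs at least 3 samples, got {n}")
    order = np.argsort(y, kind="stable")
    pos = np.arange(n)
    in_pred = (pos % 3 == 1) & (pos < 3 * (n // 3))
    return order[~in_pred], order[in_pred]


@dataclass
class Metrics:
    """rmse and mae in target units (%); pearson_r dimensionless."""

    rmse: float
    mae: float
    pearson_r: float


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """RMSE, MAE and the (signed) sample Pearson correlation.

    Raises if either vector has zero variance (correlation undefined);
    errors are never silently reported as 0.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples for the metric set")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("Pearson correlation undefined: a vector has zero variance")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Metrics(rmse=rmse, mae=mae, pearson_r=r)
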
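"""Partial least squares regression (SIMPLS) for a univariate response.

The model follows the statsmodels convention: :class:`PLSR` is built
from data, ``fit()`` returns a :class:`PLSRResults` carrying the
estimates and training diagnostics, and prediction is the affine map

    y_hat = y_mean + (x - x_mean) . coefficients

SIMPLS (de Jong 1993) is used rather than NIPALS: it is a finite,
deterministic sequence of deflations with no convergence tolerance, and
for a univariate response the two algorithms give identical predictions.
The coefficient paths nest, so cross-validation over the number of
latent variables needs one decomposition per fold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .chemometrics import Metrics, compute_metrics
from .io import SpectralDataset

__all__ = [
    "PLSR",
    "PLSRResults",
    "plsr_fit",
    "plsr_predict",
    "select_latent_variables",
    "cross_val_rmse",
]

_DEFAULT_MAX_LV = 20  # conventional ceiling for NIR calibrations


def _simpls_path(X0: np.ndarray, y0: np.ndarray, max_lv: int) -> tuple[np.ndarray, np.ndarray]:
    """SIMPLS weight/loading sequence on pre-centered data.

    Returns ``(R, q)`` with ``R`` of shape (d, a_eff) and ``q`` of shape
    (a_eff,); the coefficient vector using ``k`` latent variables is
    ``R[:, :k] @ q[:k]``.  Stops early (a_eff < max_lv) when the
    covariance is numerically exhausted.
    """
    n, d = X0.shape
    s = X0.T @ y0
    s0 = np.linalg.norm(s)
    R = np.zeros((d, max_lv))
    q = np.zeros(max_lv)
    V = np.zeros((d, max_lv))
    a_eff = 0
    for a in range(max_lv):
        r = s.copy()
        t = X0 @ r
        nt = np.linalg.norm(t)
        if nt <= 1e-12 * max(s0, 1e-300) or np.linalg.norm(s) <= 1e-12 * s0:
            break
        t /= nt
        r /= nt
        p = X0.T @ t
        q[a] = y0 @ t
        v = p - V[:, :a] @ (V[:, :a].T @ p)
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            break
        v /= nv
        V[:, a] = v
        R[:, a] = r
        s = s - v * (v @ s)
        a_eff = a + 1
    return R[:, :a_eff], q[:a_eff]


def _coef_path(X: np.ndarray, y: np.ndarray, max_lv: int) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Centered SIMPLS coefficient path.

    Returns ``(B, x_mean, y_mean, ks)`` where ``B[:, k-1]`` are the
    coefficients with ``k`` latent variables.  If the rank is exhausted
    before ``max_lv`` the last column is repeated (extra components add
    nothing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    R, q = _simpls_path(X - x_mean, y - y_mean, max_lv)
    a_eff = q.size
    if a_eff == 0:
        raise ValueError("PLSR fit failed: response has no covariance with the spectra "
                         "(constant y or zero-variance X)")
    B = np.cumsum(R * q, axis=1)
    if a_eff < max_lv:
        B = np.hstack([B, np.repeat(B[:, -1:], max_lv - a_eff, axis=1)])
    return B, x_mean, y_mean, np.arange(1, max_lv + 1)


class PLSR:
    """PLS regression model of a response on spectra.

    Parameters
    ----------
    X : (n, d) absorbance matrix
    y : (n,) response (blend proportion, %)

    Use :meth:`fit` with an explicit ``n_latent``, or leave it ``None``
    to select the count by k-fold cross-validation.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} values")
        if X.shape[0] < 2:
            raise ValueError("PLSR needs at least 2 samples")
        if np.ptp(y) == 0:
            raise ValueError("PLSR fit error: constant response (covariance undefined)")
        self.X = X
        self.y = y
        self.nobs, self.n_features = X.shape

    @classmethod
    def from_dataset(cls, ds: SpectralDataset) -> "PLSR":
        return cls(ds.absorbance, ds.target)

    @property
    def max_lv_bound(self) -> int:
        return min(self.nobs - 1, self.n_features)

    def fit(
        self,
        n_latent: int | None = None,
        max_lv: int | None = None,
        k_folds: int = 10,
        seed: int = 0,
    ) -> "PLSRResults":
        """Fit the model; select ``n_latent`` by CV when not given."""
        bound = self.max_lv_bound
        if max_lv is None:
            max_lv = min(_DEFAULT_MAX_LV, bound)
        cv_curve = None
        if n_latent is None:
            n_latent, cv_curve = select_latent_variables(
                self.X, self.y, max_lv=max_lv, k_folds=k_folds, seed=seed, return_curve=True
            )
        if not (1 <= n_latent <= bound):
            raise ValueError(f"n_latent={n_latent} outside [1, {bound}]")
        B, x_mean, y_mean, _ = _coef_path(self.X, self.y, n_latent)
        coef = B[:, n_latent - 1]
        fitted = y_mean + (self.X - x_mean) @ coef
        training = compute_metrics(self.y, fitted)
        return PLSRResults(
            model=self,
            x_mean=x_mean,
            y_mean=y_mean,
            n_latent=n_latent,
            coefficients=coef,
            training_metrics=training,
            cv_rmse_curve=cv_curve,
        )


@dataclass
class PLSRResults:
    """Fitted PLSR: centering means, coefficients and diagnostics.

    ``model`` is None for predictors reloaded from JSON.
    """

    model: PLSR | None
    x_mean: np.ndarray
    y_mean: float
    n_latent: int
    coefficients: np.ndarray
    training_metrics: Metrics
    cv_rmse_curve: np.ndarray | None = None

    @property
    def r_c(self) -> float:
        return self.training_metrics.pearson_r

    @property
    def rmsec(self) -> float:
        return self.training_metrics.rmse

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Affine prediction; values are never clipped to [0, 100]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.x_mean.size}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coefficients

    def summary(self) -> str:
        nobs = self.model.nobs if self.model is not None else "n/a"
        lines = [
            "PLS Regression Results (SIMPLS)",
            "=" * 40,
            f"{'No. observations:':<26}{nobs:>14}",
            f"{'No. spectral variables:':<26}{self.x_mean.size:>14}",
            f"{'Latent variables:':<26}{self.n_latent:>14}",
            f"{'R_c (calibration):':<26}{self.r_c:>14.4f}",
            f"{'RMSEC (%):':<26}{self.rmsec:>14.4f}",
            f"{'MAE_c (%):':<26}{self.training_metrics.mae:>14.4f}",
        ]
        if self.cv_rmse_curve is not None:
            lines.append(
                f"{'min CV-RMSE (%):':<26}{float(np.min(self.cv_rmse_curve)):>14.4f}"
            )
        lines.append("=" * 40)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "n_latent": int(self.n_latent),
            "coefficients": self.coefficients.tolist(),
            "r_c": self.r_c,
            "rmsec": self.rmsec,
        }

    def to_json(self, grid: np.ndarray | None = None) -> str:
        """Serialize the fitted model; ``grid`` adds a wavenumber-grid hash
        so a reloaded model can be matched to its spectral axis."""
        doc = {"kind": "plsr", **self.to_dict(), "mae_c": self.training_metrics.mae}
        if grid is not None:
            doc["grid_hash"] = hashlib.sha256(
                np.ascontiguousarray(np.asarray(grid, dtype=float)).tobytes()
            ).hexdigest()
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PLSRResults":
        """Rebuild a predictor from :meth:`to_json` output (no training data)."""
        doc = json.loads(text)
        if doc.get("kind") != "plsr":
            raise ValueError("not a PLSR model document")
        return cls(
            model=None,
            x_mean=np.array(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            n_latent=int(doc["n_latent"]),
            coefficients=np.array(doc["coefficients"], dtype=float),
            training_metrics=Metrics(
                rmse=doc["rmsec"], mae=doc["mae_c"], pearson_r=doc["r_c"]
            ),
        )


def cross_val_rmse(
    X: np.ndarray, y: np.ndarray, max_lv: int, k_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Pooled k-fold CV-RMSE for every latent-variable count 1..max_lv."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds the sample count {n}")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    sq = np.zeros(max_lv)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        B, x_mean, y_mean, _ = _coef_path(X[train], y[train], max_lv)
        pred = y_mean + (X[test] - x_mean) @ B  # (n_test, max_lv)
        sq += np.sum((pred - y[test, None]) ** 2, axis=0)
    return np.sqrt(sq / n)


def select_latent_variables(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    k_folds: int = 10,
    seed: int = 0,
    return_curve: bool = False,
):
    """Latent-variable count minimizing the k-fold CV-RMSE.

    Near-ties (within 1e-8 relative or 1e-10 absolute of the minimum) are
    broken toward fewer latent variables, so a noiseless low-rank problem
    selects its true rank rather than chasing round-off.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bound = min(X.shape[0] - 1, X.shape[1])
    if max_lv is None:
        max_lv = min(_DEFAULT_MAX_LV, bound)
    max_lv = min(max_lv, bound)
    curve = cross_val_rmse(X, y, max_lv=max_lv, k_folds=k_folds, seed=seed)
    best = float(np.min(curve))
    tol = max(1e-10, 1e-8 * best)
    chosen = int(np.argmax(curve <= best + tol)) + 1
    return (chosen, curve) if return_curve else chosen


# -- thin functional wrappers ------------------------------------------------

def plsr_fit(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSRResults:
    return PLSR(X, y).fit(n_latent=n_latent)


def plsr_predict(results: PLSRResults, X: np.ndarray) -> np.ndarray:
    return results.predict(X)
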
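"""Feature-space alignment between spectral domains: primal TCA and CORAL.

Transfer component analysis (TCA) learns a linear projection ``W`` of the
stacked source/target spectra that maximizes retained variance while
penalizing the squared distance between the projected domain means (the
linear-kernel maximum mean discrepancy, MMD).  With the primal (linear,
no-kernel) reading the between-domain MMD term ``Z' L Z`` is rank one --
``(mu_s - mu_t)(mu_s - mu_t)'`` -- so the solution is the leading
eigenvectors of ``(g g' + mu I)^{-1} S`` where ``S`` is the combined
scatter and ``g`` the domain-mean difference.  The eigenproblem is solved
exactly in the row space of the centered data (rank r <= n_s + n_t - 1),
which is where every eigenvector with a nonzero eigenvalue lives.

Correlation alignment (CORAL) recolors the source features so their
covariance matches the target's: ``A = C_s^{-1/2} C_t^{1/2}`` with
symmetric square roots.  Spectral matrices have n << d, so both
covariances are rank deficient; a shrinkage ``lambda`` on the diagonal
keeps the inverse root defined (default: 1e-6 * trace(C)/d per domain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .chemometrics import fix_signs

__all__ = [
    "mmd_linear",
    "TCATransform",
    "tca_fit",
    "tca_transform",
    "CoralTransform",
    "coral_fit",
    "coral_transform",
]

DEFAULT_TCA_DIM = 30
DEFAULT_TCA_MU = 0.1
_RELATIVE_SHRINKAGE = 1e-6


def mmd_linear(A: np.ndarray, B: np.ndarray) -> float:
    """Squared linear-kernel MMD: ||mean row of A - mean row of B||^2."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("MMD needs non-empty matrices")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    diff = A.mean(axis=0) - B.mean(axis=0)
    return float(diff @ diff)


# ---------------------------------------------------------------------------
# TCA

@dataclass
class TCATransform:
    """Fitted primal-TCA projection.

    projection : (d, m) matrix W, columns B-orthonormal in the penalty
        metric (g g' + mu I), sign-fixed
    combined_mean : per-feature mean of the stacked training domains
    mmd_before / mmd_after : linear MMD in the raw space / in the learned
        subspace, on the training pair
    pca_baseline_mmd : linear MMD after projecting the same pair onto the
        top-m PCA axes of the stacked data (the no-adaptation baseline)
    """

    projection: np.ndarray
    combined_mean: np.ndarray
    mu: float
    m: int
    mmd_before: float
    mmd_after: float
    pca_baseline_mmd: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return tca_transform(self, X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "tca",
                "projection": self.projection.tolist(),
                "combined_mean": self.combined_mean.tolist(),
                "mu": self.mu,
                "m": self.m,
                "mmd_before": self.mmd_before,
                "mmd_after": self.mmd_after,
                "pca_baseline_mmd": self.pca_baseline_mmd,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TCATransform":
        doc = json.loads(text)
        if doc.get("kind") != "tca":
            raise ValueError("not a TCA transform document")
        return cls(
            projection=np.array(doc["projection"], dtype=float),
            combined_mean=np.array(doc["combined_mean"], dtype=float),
            mu=doc["mu"],
            m=doc["m"],
            mmd_before=doc["mmd_before"],
            mmd_after=doc["mmd_after"],
            pca_baseline_mmd=doc["pca_baseline_mmd"],
        )


def tca_fit(
    Xs: np.ndarray,
    Xt: np.ndarray,
    m: int = DEFAULT_TCA_DIM,
    mu: float = DEFAULT_TCA_MU,
) -> TCATransform:
    """Learn an m-dimensional shared subspace for two spectral domains.

    Maximizes ``tr(W' S W)`` (combined scatter S) relative to
    ``tr(W' (g g' + mu I) W)`` with ``g`` the domain-mean difference, via
    the generalized symmetric eigenproblem restricted to the row space of
    the centered stacked data.  Deterministic; columns of W are unit-norm
    with the largest-magnitude entry positive.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target must share the feature dimension")
    if mu <= 0:
        raise ValueError("mu must be positive")
    ns, nt = Xs.shape[0], Xt.shape[0]
    d = Xs.shape[1]
    if not (1 <= m <= min(d, ns + nt)):
        raise ValueError(f"m={m} out of range [1, {min(d, ns + nt)}]")

    Z = np.vstack([Xs, Xt])
    mean = Z.mean(axis=0)
    Zc = Z - mean
    g = Xs.mean(axis=0) - Xt.mean(axis=0)

    # economy SVD: every eigenvector with nonzero scatter lies in span(V)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    keep = s > max(s[0], 1e-300) * 1e-12 if s.size else np.zeros(0, bool)
    V = Vt[keep].T          # (d, r) orthonormal basis of the row space
    s = s[keep]
    r = s.size
    if m > r:
        raise np.linalg.LinAlgError(
            f"requested m={m} exceeds the data rank {r}; reduce m or add samples "
            "(raising mu does not create directions)"
        )
    A_red = np.diag(s**2)                       # V' Zc' Zc V
    gv = V.T @ g
    B_red = np.outer(gv, gv) + mu * np.eye(r)   # V' (g g' + mu I) V
    try:
        w, vecs = scipy.linalg.eigh(A_red, B_red)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded by mu > 0
        raise np.linalg.LinAlgError(
            f"TCA eigen-solver failed ({exc}); try raising mu"
        ) from exc
    # keep the B-orthonormal eigenvector scaling: coordinates along the
    # domain-mean-difference direction are attenuated by ~sqrt(mu/(mu+|g|^2)),
    # which is how TCA suppresses the shift even inside the subspace
    top = vecs[:, ::-1][:, :m]
    W = fix_signs(V @ top)

    t = TCATransform(
        projection=W,
        combined_mean=mean,
        mu=float(mu),
        m=int(m),
        mmd_before=mmd_linear(Xs, Xt),
        mmd_after=0.0,
        pca_baseline_mmd=0.0,
    )
    t.mmd_after = mmd_linear(t.transform(Xs), t.transform(Xt))
    pca_axes = fix_signs(V[:, :m])
    t.pca_baseline_mmd = mmd_linear((Xs - mean) @ pca_axes, (Xt - mean) @ pca_axes)
    return t


def tca_transform(t: TCATransform, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` into the learned subspace."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != t.combined_mean.size:
        raise ValueError(f"X has {X.shape[1]} features, transform expects {t.combined_mean.size}")
    return (X - t.combined_mean) @ t.projection


# ---------------------------------------------------------------------------
# CORAL

@dataclass
class CoralTransform:
    """Fitted CORAL recoloring map.

    recolor : (d, d) map ``A = C_s^{-1/2} C_t^{1/2}`` with shrunk
        covariances; applying it to source rows matches their covariance
        to the (shrunk) target covariance.
    mean_mode : 'match' recenters source rows on the target mean after
        recoloring; 'none' applies the raw linear map only.
    """

    source_mean: np.ndarray
    target_mean: np.ndarray
    recolor: np.ndarray
    lambda_source: float
    lambda_target: float
    mean_mode: str = "match"

    def transform(self, X: np.ndarray) -> np.ndarray:
        return coral_transform(self, X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "coral",
                "source_mean": self.source_mean.tolist(),
                "target_mean": self.target_mean.tolist(),
                "recolor": self.recolor.tolist(),
                "lambda_source": self.lambda_source,
                "lambda_target": self.lambda_target,
                "mean_mode": self.mean_mode,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CoralTransform":
        doc = json.loads(text)
        if doc.get("kind") != "coral":
            raise ValueError("not a CORAL transform document")
        return cls(
            source_mean=np.array(doc["source_mean"], dtype=float),
            target_mean=np.array(doc["target_mean"], dtype=float),
            recolor=np.array(doc["recolor"], dtype=float),
            lambda_source=doc["lambda_source"],
            lambda_target=doc["lambda_target"],
            mean_mode=doc["mean_mode"],
        )


def _cov_root_factors(Xc: np.ndarray, lam: float, inverse: bool, label: str):
    """Symmetric (inverse) square root of ``cov(X) + lam*I`` in factored form.

    Returns ``(V, diag, iso)`` such that the root equals
    ``V @ diag(diag) @ V.T + iso * I``; built from the economy SVD of the
    centered data so the cost is O(n d^2) rather than a dense d^3
    eigendecomposition.  Eigenvalues are floored at 0 before rooting.
    """
    n = Xc.shape[0]
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = np.maximum(s**2 / max(n - 1, 1), 0.0)
    if inverse and lam <= 0:
        full_rank = ev.size == Xc.shape[1]
        if not full_rank or ev.min() <= 1e-12 * max(ev.max(), 1e-300):
            smallest = ev.min() if full_rank else 0.0
            raise np.linalg.LinAlgError(
                f"{label} covariance is numerically singular with lambda=0 "
                f"(smallest eigenvalue {smallest:.3e}); use a positive shrinkage"
            )
    power = -0.5 if inverse else 0.5
    iso = lam**power if lam > 0 else 0.0
    diag = (ev + lam) ** power - iso
    return Vt.T, diag, iso


def _apply_factored(V: np.ndarray, diag: np.ndarray, iso: float, M: np.ndarray) -> np.ndarray:
    """(V diag V' + iso I) @ M without forming the d x d operator."""
    return V @ (diag[:, None] * (V.T @ M)) + iso * M


def coral_fit(Xs: np.ndarray, Xt: np.ndarray, lam: float | str = "auto",
              mean_mode: str = "match") -> CoralTransform:
    """Fit the CORAL recoloring of source features toward the target.

    ``lam='auto'`` uses per-domain relative shrinkage 1e-6 * trace(C)/d,
    needed because spectral covariances with n < d are singular; an
    explicit float is applied to both domains (0 requires full rank).
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target must share the feature dimension")
    if mean_mode not in ("match", "none"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    mu_s = Xs.mean(axis=0)
    mu_t = Xt.mean(axis=0)
    Xsc = Xs - mu_s
    Xtc = Xt - mu_t

    def auto_lam(Xc: np.ndarray) -> float:
        n, d = Xc.shape
        return _RELATIVE_SHRINKAGE * float(np.sum(Xc**2)) / max(n - 1, 1) / d

    if isinstance(lam, str):
        if lam != "auto":
            raise ValueError(f"lam must be a float or 'auto', got {lam!r}")
        lam_s, lam_t = auto_lam(Xsc), auto_lam(Xtc)
    else:
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        lam_s = lam_t = float(lam)

    Vs, ds_, iso_s = _cov_root_factors(Xsc, lam_s, inverse=True, label="source")
    Vt_, dt_, iso_t = _cov_root_factors(Xtc, lam_t, inverse=False, label="target")
    # A = C_s^{-1/2} C_t^{1/2}, assembled from the factored roots
    Ct_half = _apply_factored(Vt_, dt_, iso_t, np.eye(Xs.shape[1]))
    A = _apply_factored(Vs, ds_, iso_s, Ct_half)
    return CoralTransform(
        source_mean=mu_s,
        target_mean=mu_t,
        recolor=A,
        lambda_source=float(lam_s),
        lambda_target=float(lam_t),
        mean_mode=mean_mode,
    )


def coral_transform(t: CoralTransform, Xs: np.ndarray) -> np.ndarray:
    """Recolor source rows; target rows pass through unchanged upstream."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if Xs.shape[1] != t.recolor.shape[0]:
        raise ValueError(f"X has {Xs.shape[1]} features, transform expects {t.recolor.shape[0]}")
    if t.mean_mode == "match":
        return (Xs - t.source_mean) @ t.recolor + t.target_mean
    return Xs @ t.recolor
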
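"""Canonical correlation analysis with loadings, redundancies, and
deterministic mode orientation.

The fit whitens each block by the inverse square root of its (ridge-
stabilized) covariance and takes the SVD of the whitened cross-covariance:

    Sxx^(-1/2) Sxy Syy^(-1/2) = U diag(r) V'

The singular values are the canonical correlations r_1 >= ... >= r_K,
K = min(p, q); the back-transformed singular vectors are the canonical
weights, rescaled so every variate has unit sample variance (n-1
denominator throughout).  This route is numerically stable and exposes all
modes at once, unlike iterated-regression formulations.

:class:`CanonicalCorrelation` follows the scikit-learn estimator protocol
(``fit``/``transform``, ``get_params``, trailing-underscore fitted
attributes) so it composes with sklearn pipelines; :func:`fit_cca` is the
thin functional wrapper returning a :class:`CCAResult` record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .results import register_result

log = logging.getLogger(__name__)

#: cap applied to the eigenvalue lambda = r^2/(1-r^2) when r -> 1
LAMBDA_CAP = 1e12


def _cov(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cross-covariance of centered matrices, n-1 denominator."""
    n = A.shape[0]
    return A.T @ B / (n - 1)


def inv_sqrt_psd(S: np.ndarray, ridge_eps: float) -> tuple[np.ndarray, int]:
    """Inverse square root of a symmetric PSD matrix with ridge stabilization.

    Returns the inverse square root of ``S + ridge_eps * I`` and the
    effective rank of ``S`` (eigenvalues above a relative tolerance).
    """
    S = np.asarray(S, dtype=float)
    vals, vecs = np.linalg.eigh(S + ridge_eps * np.eye(S.shape[0]))
    tol = max(S.shape[0] * np.finfo(float).eps * max(vals.max(), 0.0), ridge_eps * 10)
    effective_rank = int(np.sum(vals - ridge_eps > tol))
    # pseudo-inverse rule: directions with (numerically) zero variance are
    # dropped rather than amplified
    pinv_tol = S.shape[0] * np.finfo(float).eps * max(vals.max(), 0.0)
    inv_root = np.where(vals > pinv_tol, 1.0 / np.sqrt(np.maximum(vals, np.finfo(float).tiny)), 0.0)
    return (vecs * inv_root) @ vecs.T, effective_rank


class CanonicalCorrelation(BaseEstimator):
    """CCA estimator over two standardized blocks.

    Parameters
    ----------
    ridge_eps : float
        Ridge added to both block covariances before the inverse square
        root; guards against ill-conditioned blocks (many collinear
        regional measures) without materially perturbing well-conditioned
        ones.

    Fitted attributes (trailing underscore) include the canonical
    correlations ``r_``, weights, training variates, structure loadings,
    and the training column means used by :meth:`transform`.
    """

    def __init__(self, ridge_eps: float = 1e-8):
        self.ridge_eps = ridge_eps

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "CanonicalCorrelation":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        n, p = X.shape
        n2, q = Y.shape
        if n != n2:
            raise ValueError(f"X has {n} rows but Y has {n2}")
        if n <= 2:
            raise ValueError("CCA needs more than two subjects")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("CCA input contains non-finite values; impute first")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_

        Sxx = _cov(Xc, Xc)
        Syy = _cov(Yc, Yc)
        Sxy = _cov(Xc, Yc)

        Wx, rank_x = inv_sqrt_psd(Sxx, self.ridge_eps)
        Wy, rank_y = inv_sqrt_psd(Syy, self.ridge_eps)
        if rank_x < p or rank_y < q:
            warnings.warn(
                f"rank-deficient block(s): effective ranks {rank_x}/{p} (X), "
                f"{rank_y}/{q} (Y); proceeding via ridge",
                stacklevel=2,
            )

        M = Wx @ Sxy @ Wy
        U, s, Vt = np.linalg.svd(M)
        K = min(p, q)
        self.r_ = np.clip(s[:K], 0.0, 1.0)
        A = Wx @ U[:, :K]
        B = Wy @ Vt.T[:, :K]

        # rescale weights so training variates have exactly unit variance
        # (degenerate zero-variance modes of rank-deficient blocks are left
        # at zero rather than amplified)
        xv = Xc @ A
        yv = Yc @ B
        sd_x = xv.std(axis=0, ddof=1)
        sd_y = yv.std(axis=0, ddof=1)
        A = A / np.where(sd_x > 0, sd_x, 1.0)
        B = B / np.where(sd_y > 0, sd_y, 1.0)
        self.x_weights_ = A
        self.y_weights_ = B
        self.x_variates_ = Xc @ A
        self.y_variates_ = Yc @ B
        self.x_loadings_ = _corr_with(Xc, self.x_variates_)
        self.y_loadings_ = _corr_with(Yc, self.y_variates_)
        self.n_ = n
        self.effective_rank_x_ = rank_x
        self.effective_rank_y_ = rank_y
        return self

    def transform(
        self, X: Optional[np.ndarray] = None, Y: Optional[np.ndarray] = None
    ) -> tuple[Optional[np.ndarray], Optional[np.ndarray]]:
        """Project new (training-standardized) data onto the fitted weights."""
        xs = ys = None
        if X is not None:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] != self.x_weights_.shape[0]:
                raise ValueError(
                    f"X has {X.shape[1]} columns, expected {self.x_weights_.shape[0]}"
                )
            xs = (X - self.x_mean_) @ self.x_weights_
        if Y is not None:
            Y = np.atleast_2d(np.asarray(Y, dtype=float))
            if Y.shape[1] != self.y_weights_.shape[0]:
                raise ValueError(
                    f"Y has {Y.shape[1]} columns, expected {self.y_weights_.shape[0]}"
                )
            ys = (Y - self.y_mean_) @ self.y_weights_
        return xs, ys


def _corr_with(Zc: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Correlation of each (centered) column with each variate column."""
    sd_z = Zc.std(axis=0, ddof=1)
    sd_v = variates.std(axis=0, ddof=1)
    C = _cov(Zc, variates - variates.mean(axis=0))
    denom = np.outer(np.where(sd_z > 0, sd_z, 1.0), np.where(sd_v > 0, sd_v, 1.0))
    return C / denom


@register_result
@dataclass
class CCAResult:
    """Full CCA output for one cohort."""

    n: int
    p: int
    q: int
    K: int
    r: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_variates: np.ndarray
    y_variates: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_center: np.ndarray
    y_center: np.ndarray
    ridge_eps: float
    oriented: bool = False
    redundancy_y_given_x: Optional[np.ndarray] = None
    pct_covariance_eigen: Optional[np.ndarray] = None
    pct_covariance_rsq: Optional[np.ndarray] = None
    x_names: Optional[list[str]] = None
    y_names: Optional[list[str]] = None
    effective_rank_x: Optional[int] = None
    effective_rank_y: Optional[int] = None

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CCAResult":
        return cls(**d)


def fit_cca(
    X: np.ndarray,
    Y: np.ndarray,
    ridge_eps: float = 1e-8,
    x_names: Optional[list[str]] = None,
    y_names: Optional[list[str]] = None,
) -> CCAResult:
    """Fit CCA on standardized blocks and return a populated result record.

    Redundancies and %-of-co-variance are filled in; orientation is left to
    :func:`orient_modes`.
    """
    est = CanonicalCorrelation(ridge_eps=ridge_eps).fit(X, Y)
    res = CCAResult(
        n=est.n_,
        p=X.shape[1],
        q=Y.shape[1],
        K=len(est.r_),
        r=est.r_,
        x_weights=est.x_weights_,
        y_weights=est.y_weights_,
        x_variates=est.x_variates_,
        y_variates=est.y_variates_,
        x_loadings=est.x_loadings_,
        y_loadings=est.y_loadings_,
        x_center=est.x_mean_,
        y_center=est.y_mean_,
        ridge_eps=ridge_eps,
        x_names=list(x_names) if x_names is not None else None,
        y_names=list(y_names) if y_names is not None else None,
        effective_rank_x=est.effective_rank_x_,
        effective_rank_y=est.effective_rank_y_,
    )
    return redundancy(res)


def redundancy(result: CCAResult) -> CCAResult:
    """Redundancy index and two %-of-co-variance conventions, per mode.

    * ``redundancy_y_given_x[k] = 100 * r_k^2 * mean_j(y_loadings[j,k]^2)``:
      the share of the cognition block's variance explained by the k-th
      brain variate.
    * ``pct_covariance_eigen[k] = 100 * lambda_k / sum(lambda)`` with
      ``lambda_k = r_k^2 / (1 - r_k^2)`` -- the eigenvalue convention and
      default display.
    * ``pct_covariance_rsq[k] = 100 * r_k^2 / sum(r^2)``.
    """
    r2 = result.r**2
    result.redundancy_y_given_x = 100.0 * r2 * np.mean(result.y_loadings**2, axis=0)
    with np.errstate(divide="ignore"):
        lam = r2 / (1.0 - r2)
    if np.any(~np.isfinite(lam)) or np.any(lam > LAMBDA_CAP):
        warnings.warn("canonical correlation at 1; capping eigenvalue at 1e12", stacklevel=2)
        lam = np.minimum(np.nan_to_num(lam, posinf=LAMBDA_CAP), LAMBDA_CAP)
    result.pct_covariance_eigen = 100.0 * lam / lam.sum() if lam.sum() > 0 else lam
    result.pct_covariance_rsq = 100.0 * r2 / r2.sum() if r2.sum() > 0 else r2
    return result


def orient_modes(result: CCAResult, anchor: str = "mean_y_loading") -> CCAResult:
    """Fix the sign of each mode so that higher Y means better cognition.

    CCA modes are sign-indeterminate: jointly negating a pair of variates
    (and its weights) changes nothing statistical.  For stability across
    runs and cohorts, each mode is flipped so that the anchor's y-loading
    (or, by default, the mean y-loading) is positive.
    """
    if anchor == "mean_y_loading":
        crit = result.y_loadings.mean(axis=0)
    else:
        if result.y_names is None or anchor not in result.y_names:
            raise ValueError(f"anchor variable {anchor!r} not among y names")
        crit = result.y_loadings[result.y_names.index(anchor), :]
    signs = np.where(crit < 0, -1.0, 1.0)
    result.x_weights = result.x_weights * signs
    result.y_weights = result.y_weights * signs
    result.x_variates = result.x_variates * signs
    result.y_variates = result.y_variates * signs
    result.x_loadings = result.x_loadings * signs
    result.y_loadings = result.y_loadings * signs
    result.oriented = True
    return result


def project(
    result: CCAResult, X_new: Optional[np.ndarray] = None, Y_new: Optional[np.ndarray] = None
) -> tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Apply trained weights to new data (standardized with training stats)."""
    xs = ys = None
    if X_new is not None:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != result.p:
            raise ValueError(f"X_new has {X_new.shape[1]} columns, expected {result.p}")
        xs = (X_new - result.x_center) @ result.x_weights
    if Y_new is not None:
        Y_new = np.atleast_2d(np.asarray(Y_new, dtype=float))
        if Y_new.shape[1] != result.q:
            raise ValueError(f"Y_new has {Y_new.shape[1]} columns, expected {result.q}")
        ys = (Y_new - result.y_center) @ result.y_weights
    return xs, ys
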
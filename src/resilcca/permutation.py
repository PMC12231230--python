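"""Permutation significance test for the first canonical correlation.

The rows of the cognition block Y are shuffled B times against a fixed
brain block X, the CCA is refit, and the first canonical correlation is
recorded to form the null distribution.  Because a row permutation leaves
Syy and the column means untouched, each refit reduces exactly to the
largest singular value of the whitened cross-covariance with permuted Y --
the same computation as a full refit, done without redundant work.

The add-one Monte-Carlo p-value (1 + #{null >= observed}) / (B + 1) is
used, so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .cca import inv_sqrt_psd, _cov
from .results import register_result


@register_result
@dataclass
class PermutationResult:
    statistic: str
    r_obs: float
    null_r: np.ndarray
    B: int
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PermutationResult":
        return cls(**d)


def mc_p_value(null_r: np.ndarray, r_obs: float) -> float:
    """Add-one Monte-Carlo p-value: (1 + #{null >= obs}) / (B + 1)."""
    null_r = np.asarray(null_r, dtype=float)
    return float((1.0 + np.sum(null_r >= r_obs)) / (null_r.size + 1.0))


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    B: int = 10000,
    seed: int = 0,
    ridge_eps: float = 1e-8,
) -> PermutationResult:
    """Permutation test of the first canonical correlation.

    Parameters
    ----------
    X, Y : arrays (n x p), (n x q)
        Standardized, complete blocks.
    B : int
        Number of row shuffles of Y (>= 1).
    seed : int
        Seeds a ``numpy.random.default_rng`` stream; recorded in the result
        for bit-reproducibility.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n < 5:
        raise ValueError("permutation test needs at least 5 subjects")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("permutation test input contains non-finite values")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Wx, _ = inv_sqrt_psd(_cov(Xc, Xc), ridge_eps)
    Wy, _ = inv_sqrt_psd(_cov(Yc, Yc), ridge_eps)
    A = Xc @ Wx  # n x p, whitened
    Bw = Yc @ Wy  # n x q, whitened

    def first_r(rows: np.ndarray) -> float:
        M = A.T @ Bw[rows] / (n - 1)
        s = np.linalg.svd(M, compute_uv=False)
        return float(np.clip(s[0], 0.0, 1.0))

    r_obs = first_r(np.arange(n))
    rng = np.random.default_rng(seed)
    null_r = np.empty(B)
    for b in range(B):
        null_r[b] = first_r(rng.permutation(n))
    p = mc_p_value(null_r, r_obs)
    return PermutationResult(
        statistic="first canonical correlation",
        r_obs=r_obs,
        null_r=null_r,
        B=B,
        p_value=float(p),
        seed=int(seed),
    )


def sequential_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_modes: int,
    B: int = 1000,
    seed: int = 0,
    ridge_eps: float = 1e-8,
) -> list[PermutationResult]:
    """Permutation tests for the first ``n_modes`` canonical correlations.

    The k-th test uses the k-th singular value of the permuted whitened
    cross-covariance as its null statistic.  Off the main path: inference
    in the primary analysis concerns the first mode only.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("permutation test needs at least 5 subjects")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Wx, _ = inv_sqrt_psd(_cov(Xc, Xc), ridge_eps)
    Wy, _ = inv_sqrt_psd(_cov(Yc, Yc), ridge_eps)
    A = Xc @ Wx
    Bw = Yc @ Wy
    K = min(A.shape[1], Bw.shape[1])
    if n_modes > K:
        raise ValueError(f"n_modes={n_modes} exceeds K={K}")

    def all_r(rows: np.ndarray) -> np.ndarray:
        s = np.linalg.svd(A.T @ Bw[rows] / (n - 1), compute_uv=False)
        return np.clip(s[:n_modes], 0.0, 1.0)

    r_obs = all_r(np.arange(n))
    rng = np.random.default_rng(seed)
    null = np.empty((B, n_modes))
    for b in range(B):
        null[b] = all_r(rng.permutation(n))
    out = []
    for k in range(n_modes):
        p = (1.0 + np.sum(null[:, k] >= r_obs[k])) / (B + 1.0)
        out.append(
            PermutationResult(
                statistic=f"canonical correlation (mode {k + 1})",
                r_obs=float(r_obs[k]),
                null_r=null[:, k].copy(),
                B=B,
                p_value=float(p),
                seed=int(seed),
            )
        )
    return out
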
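"""Shared fixtures and independent oracle helpers.

The oracle functions here deliberately take different computational routes
from the package (generalized eigenproblems instead of whitened SVD,
explicit step-up enumeration instead of vectorized FDR) so that agreement
is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from resilcca import CohortTable, VariableEntry, VariableManifest


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_cca(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force CCA oracle via the symmetric generalized eigenproblem.

    Solves Sxy Syy^-1 Syx w = r^2 Sxx w (and the mirror problem for the
    y-weights), entirely independent of the whitened-SVD implementation.
    Returns (r descending, x-weight columns, y-weight columns).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    A = Sxy @ np.linalg.solve(Syy, Sxy.T)
    vals, vecs = linalg.eigh(A, Sxx)
    order = np.argsort(vals)[::-1]
    K = min(X.shape[1], Y.shape[1])
    r = np.sqrt(np.clip(vals[order][:K], 0.0, 1.0))
    Wx = vecs[:, order][:, :K]
    B = Sxy.T @ np.linalg.solve(Sxx, Sxy)
    vals_y, vecs_y = linalg.eigh(B, Syy)
    order_y = np.argsort(vals_y)[::-1]
    Wy = vecs_y[:, order_y][:, :K]
    return r, Wx, Wy


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH q-values by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return np.minimum(q, 1.0)


def subspace_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle (radians) between two directions, sign-invariant."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return float(np.arccos(np.clip(abs(u @ v), 0.0, 1.0)))


def gaussian_blocks(
    n: int, p: int, q: int, r1: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly Gaussian blocks with exactly known population CCA.

    Sxx = I, Syy = I, Sxy = r1 * u v' with unit vectors u, v, so the
    population canonical correlations are (r1, 0, ..., 0).
    """
    u = np.zeros(p)
    u[0] = 1.0
    v = np.zeros(q)
    v[0] = 1.0
    C = np.zeros((p + q, p + q))
    C[:p, :p] = np.eye(p)
    C[p:, p:] = np.eye(q)
    C[:p, p:] = r1 * np.outer(u, v)
    C[p:, :p] = C[:p, p:].T
    L = np.linalg.cholesky(C + 1e-12 * np.eye(p + q))
    Z = rng.standard_normal((n, p + q)) @ L.T
    return Z[:, :p], Z[:, p:]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cohort(
    columns: dict[str, list | np.ndarray],
    entries: list[VariableEntry],
    label: str = "toy",
    ids: list[str] | None = None,
) -> CohortTable:
    n = len(next(iter(columns.values())))
    if ids is None:
        ids = [f"S{i + 1}" for i in range(n)]
    manifest = VariableManifest(entries=[VariableEntry(name="subject_id", role="id")] + entries)
    frame = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in columns.items()},
        index=pd.Index(ids, name="subject_id"),
    )
    return CohortTable(cohort_label=label, data=frame, manifest=manifest)


@pytest.fixture
def cohort_factory():
    return make_cohort
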
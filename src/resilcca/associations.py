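"""Resilience association models.

The operational measure of cognitive resilience is the variation of the
first cognition variate (Y1) not explained by the first brain variate
(X1).  Rather than extracting a residual and regressing it in a second
step, every term of interest enters *one* ordinary-least-squares model
together with X1:

    Y1 ~ X1 + Age + Sex + Term            (education, APOE carriership)
    Y1 ~ X1 + Age + Sex + Term + PC1..PC5 (single-SNP dosages)

Interaction sensitivity models add X1*Term, and the classical two-step
residual baseline (regress Y1 on X1 first, then its residual on the term)
is provided for comparison: the two approaches agree exactly when the term
is in-sample orthogonal to X1 (Frisch-Waugh-Lovell) and differ otherwise.

Coefficient scale: variates are standardized to unit variance, continuous
covariates (age) and continuous terms such as education are standardized
per cohort, so betas are per-SD; binary carriership and SNP dosages in
[0, 2] enter on their native scales.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .results import register_result


class AssociationError(ValueError):
    pass


@register_result
@dataclass
class AssociationResult:
    """One model term's estimate with Wald t inference."""

    cohort_label: str
    model: str
    term: str
    beta: float
    se: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    n: int
    standardized: bool
    method: str = "one_model"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationResult":
        return cls(**d)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise AssociationError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _is_continuous(x: np.ndarray) -> bool:
    return np.unique(x[~np.isnan(x)]).size > 2


def _prepare_column(
    cohort: CohortTable, name: str, standardize_continuous: bool
) -> tuple[np.ndarray, bool]:
    """Fetch a column; standardize continuous covariates, keep binary and
    genotype dosages on their native scale."""
    x = cohort.data[name].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise AssociationError(f"column {name!r} has missing values")
    role = cohort.manifest.entry(name).role if name in cohort.manifest else "covariate"
    if role == "genotype" or not _is_continuous(x):
        return x, False
    if standardize_continuous:
        return _standardize(x), True
    return x, False


def _ols_term_row(
    y: np.ndarray,
    design: pd.DataFrame,
    term: str,
    cohort_label: str,
    model_desc: str,
    standardized: bool,
    method: str,
) -> AssociationResult:
    n = len(y)
    X = sm.add_constant(design, has_constant="add")
    if n < X.shape[1] + 5:
        raise AssociationError(f"n={n} too small for {X.shape[1]} design columns")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise AssociationError(
            f"design matrix is rank deficient (perfect collinearity) in model {model_desc!r}"
        )
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    return AssociationResult(
        cohort_label=cohort_label,
        model=model_desc,
        term=term,
        beta=float(fit.params[term]),
        se=float(fit.bse[term]),
        t=float(fit.tvalues[term]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[term]),
        ci_low=float(ci.loc[term, 0]),
        ci_high=float(ci.loc[term, 1]),
        n=n,
        standardized=standardized,
        method=method,
    )


def _covariate_frame(
    cohort: CohortTable, covariates: Sequence[str], pcs: Optional[Sequence[str]]
) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        x, _ = _prepare_column(cohort, c, standardize_continuous=True)
        cols[c] = x
    for c in pcs or ():
        x, _ = _prepare_column(cohort, c, standardize_continuous=False)
        cols[c] = x
    return pd.DataFrame(cols, index=cohort.data.index)


def fit_resilience_model(
    cohort: CohortTable,
    Y1: np.ndarray,
    X1: np.ndarray,
    term: str,
    covariates: Sequence[str] = ("age", "sex"),
    pcs: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """One-model association between a term and cognitive resilience.

    OLS of the (standardized) cognition variate on intercept, the
    (standardized) brain variate, the covariates, optional genetic PCs,
    and the term; returns the term's row.
    """
    y = _standardize(np.asarray(Y1, dtype=float))
    x1 = _standardize(np.asarray(X1, dtype=float))
    t_vals, t_std = _prepare_column(cohort, term, standardize_continuous=True)
    if np.unique(t_vals).size < 2:
        raise AssociationError(f"term {term!r} is constant")
    design = _covariate_frame(cohort, covariates, pcs)
    design.insert(0, "X1", x1)
    design[term] = t_vals
    desc = "Y1 ~ X1 + " + " + ".join(list(covariates) + list(pcs or ())) + f" + {term}"
    return _ols_term_row(y, design, term, cohort.cohort_label, desc, t_std, "one_model")


def fit_interaction_model(
    cohort: CohortTable,
    Y1: np.ndarray,
    X1: np.ndarray,
    moderator: str,
    covariates: Sequence[str] = ("age", "sex"),
    pcs: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """Sensitivity model with an X1-by-moderator interaction.

    The product is formed after standardizing X1 and any continuous
    moderator; the returned row is the interaction term.
    """
    y = _standardize(np.asarray(Y1, dtype=float))
    x1 = _standardize(np.asarray(X1, dtype=float))
    m_vals, m_std = _prepare_column(cohort, moderator, standardize_continuous=True)
    if np.unique(m_vals).size < 2:
        raise AssociationError(f"moderator {moderator!r} is constant")
    inter = f"X1:{moderator}"
    design = _covariate_frame(cohort, covariates, pcs)
    design.insert(0, "X1", x1)
    design[moderator] = m_vals
    design[inter] = x1 * m_vals
    desc = (
        "Y1 ~ X1 + "
        + " + ".join(list(covariates) + list(pcs or ()))
        + f" + {moderator} + {inter}"
    )
    return _ols_term_row(y, design, inter, cohort.cohort_label, desc, m_std, "one_model")


def residual_baseline(
    cohort: CohortTable,
    Y1: np.ndarray,
    X1: np.ndarray,
    term: str,
    covariates: Sequence[str] = ("age", "sex"),
) -> AssociationResult:
    """Two-step residual baseline for comparison with the one-model fit.

    Step 1 regresses Y1 on X1 alone and keeps the residual as the
    "resilience score"; step 2 regresses that residual on the covariates
    and the term.  By Frisch-Waugh-Lovell the term's coefficient matches
    the one-model fit only when the term (and covariates) are in-sample
    orthogonal to X1.
    """
    y = _standardize(np.asarray(Y1, dtype=float))
    x1 = _standardize(np.asarray(X1, dtype=float))
    D1 = sm.add_constant(pd.DataFrame({"X1": x1}))
    resid = np.asarray(sm.OLS(y, D1).fit().resid)

    t_vals, t_std = _prepare_column(cohort, term, standardize_continuous=True)
    if np.unique(t_vals).size < 2:
        raise AssociationError(f"term {term!r} is constant")
    design = _covariate_frame(cohort, covariates, None)
    design[term] = t_vals
    desc = "resid(Y1 ~ X1) ~ " + " + ".join(list(covariates)) + f" + {term}"
    return _ols_term_row(
        resid, design, term, cohort.cohort_label, desc, t_std, "residual_two_step"
    )


def derive_carrier(cohort: CohortTable, genotype: str, carrier_name: str) -> CohortTable:
    """Append a 0/1 carriership column from a dosage column (dosage > 0)."""
    from .manifest import VariableEntry

    out = cohort.copy()
    g = out.data[genotype].to_numpy(dtype=float)
    carrier = np.where(np.isnan(g), np.nan, (g > 0).astype(float))
    out.data[carrier_name] = carrier
    out.manifest.entries.append(VariableEntry(name=carrier_name, role="covariate"))
    return out
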
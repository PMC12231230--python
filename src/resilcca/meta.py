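"""Fixed-effect inverse-variance meta-analysis and Benjamini-Hochberg FDR.

Cohort-level coefficients are pooled with weights 1/se^2; inference on the
pooled estimate uses the normal distribution (the standard fixed-effect
convention).  Cochran's Q is computed for reference but never switches the
model: pooling is fixed-effect throughout.  The FDR family is the SNP
panel tested in a given run; APOE carriership validation terms are
reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .associations import AssociationResult
from .results import register_result


class MetaError(ValueError):
    pass


@register_result
@dataclass
class MetaResult:
    term: str
    inputs: list[dict] = field(default_factory=list)
    beta_meta: float = np.nan
    se_meta: float = np.nan
    z: float = np.nan
    p: float = np.nan
    q_fdr: Optional[float] = None
    Q_het: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetaResult":
        return cls(**d)


def fixed_effect_meta(
    inputs: Sequence[AssociationResult] | Sequence[tuple],
    term: Optional[str] = None,
) -> MetaResult:
    """Pool per-cohort (beta, se) estimates with inverse-variance weights.

    Accepts :class:`AssociationResult` records or ``(label, beta, se)`` /
    ``(beta, se)`` tuples.  ``beta_meta = sum(w_i b_i) / sum(w_i)`` with
    ``w_i = se_i^-2``; ``se_meta = sum(w_i)^-1/2``; two-sided normal p.
    """
    if not inputs:
        raise MetaError("meta-analysis needs at least one input")
    rows = []
    for item in inputs:
        if isinstance(item, AssociationResult):
            rows.append({"cohort_label": item.cohort_label, "beta": item.beta, "se": item.se})
            if term is None:
                term = item.term
        elif len(item) == 3:
            rows.append({"cohort_label": str(item[0]), "beta": float(item[1]), "se": float(item[2])})
        else:
            rows.append({"cohort_label": "", "beta": float(item[0]), "se": float(item[1])})
    beta = np.array([r["beta"] for r in rows])
    se = np.array([r["se"] for r in rows])
    if np.any(se <= 0):
        raise MetaError("all standard errors must be positive")
    w = se**-2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    q_het = float(np.sum(w * (beta - beta_meta) ** 2))
    return MetaResult(
        term=term if term is not None else "",
        inputs=rows,
        beta_meta=beta_meta,
        se_meta=se_meta,
        z=float(z),
        p=p,
        Q_het=q_het,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise MetaError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(meta_results: Sequence[MetaResult]) -> list[MetaResult]:
    """Fill ``q_fdr`` across a family of meta-analysis results."""
    q = bh_fdr([m.p for m in meta_results])
    for m, qi in zip(meta_results, q):
        m.q_fdr = float(qi)
    return list(meta_results)
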
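"""End-to-end study orchestration.

simulate (or load) -> preprocess -> CCA -> mode orientation -> permutation
test -> association models per term -> cross-cohort fixed-effect meta ->
FDR over the SNP panel.  Each cohort's CCA is fitted independently; only
association summary statistics cross cohorts.  Estimation never touches
ground-truth files: synthetic cohorts are written to disk and read back
through the same loader as real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .associations import (
    AssociationResult,
    derive_carrier,
    fit_interaction_model,
    fit_resilience_model,
)
from .cca import CCAResult, fit_cca, orient_modes
from .cohort import CohortTable, read_cohort
from .meta import MetaResult, attach_fdr, fixed_effect_meta
from .permutation import permutation_test
from .preprocess import PreprocessParams, preprocess_cohort
from .results import register_result, write_results
from .synthetic import SyntheticConfig, simulate_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible study run.

    Provide either a synthetic study design or per-cohort (table, manifest)
    paths.  ``seed`` drives every stochastic stage (imputation donors,
    permutations) through derived streams.
    """

    synthetic: Optional[SyntheticConfig] = None
    cohort_paths: Sequence[tuple[str, str]] = ()
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    ridge_eps: float = 1e-8
    n_permutations: int = 1000
    covariates: tuple[str, ...] = ("age", "sex")
    pcs: tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4", "pc5")
    education_term: Optional[str] = "education"
    apoe_terms: tuple[str, ...] = ("apoe4", "apoe2")
    interaction: bool = False
    fdr: bool = True
    anchor: str = "mean_y_loading"
    seed: int = 0
    out_dir: Optional[str] = None


@register_result
@dataclass
class StudyReport:
    """Per-cohort model summaries plus the cross-cohort meta table."""

    seed: int
    cohorts: list[dict] = field(default_factory=list)
    meta: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(**d)


def _load_cohorts(config: PipelineConfig) -> list[CohortTable]:
    if config.synthetic is not None:
        if config.out_dir is not None:
            # write-and-read-back so estimation sees only the table files
            data_dir = Path(config.out_dir) / "data"
            simulate_study(config.synthetic, out_dir=data_dir)
            return [
                read_cohort(
                    data_dir / f"{c.label}.csv",
                    data_dir / f"{c.label}.manifest.yaml",
                    cohort_label=c.label,
                )
                for c in config.synthetic.cohorts
            ]
        return [c for c, _ in simulate_study(config.synthetic)]
    if not config.cohort_paths:
        raise ValueError("config needs a synthetic design or cohort paths")
    return [read_cohort(t, m) for t, m in config.cohort_paths]


def _snp_terms(cohort: CohortTable, apoe_terms: Sequence[str]) -> list[str]:
    return [g for g in cohort.manifest.by_role("genotype") if g not in apoe_terms]


def analyze_cohort(
    cohort: CohortTable, config: PipelineConfig, cohort_index: int
) -> tuple[dict, CCAResult, list[AssociationResult]]:
    """Preprocess one cohort, fit and orient its CCA, run the permutation
    test and all association models."""
    mri_before = set(cohort.manifest.mri_columns())
    prep, plog = preprocess_cohort(
        cohort, config.preprocess, seed=config.seed * 1000 + cohort_index
    )
    composites = set(prep.manifest.mri_columns()) - mri_before
    x_cols = prep.manifest.cca_x_columns(exclude=composites)
    y_cols = prep.manifest.cognition_columns()
    X = prep.values(x_cols)
    Y = prep.values(y_cols)

    cca = fit_cca(X, Y, ridge_eps=config.ridge_eps, x_names=x_cols, y_names=y_cols)
    cca = orient_modes(cca, anchor=config.anchor)
    perm = permutation_test(
        X,
        Y,
        B=config.n_permutations,
        seed=config.seed * 1000 + 500 + cohort_index,
        ridge_eps=config.ridge_eps,
    )
    Y1 = cca.y_variates[:, 0]
    X1 = cca.x_variates[:, 0]

    associations: list[AssociationResult] = []
    pcs = [p for p in config.pcs if p in prep.data.columns]

    if config.education_term and config.education_term in prep.data.columns:
        associations.append(
            fit_resilience_model(prep, Y1, X1, config.education_term, config.covariates)
        )
        if config.interaction:
            associations.append(
                fit_interaction_model(prep, Y1, X1, config.education_term, config.covariates)
            )
    for apoe in config.apoe_terms:
        if apoe in prep.data.columns:
            carrier = f"{apoe}_carrier"
            prep = derive_carrier(prep, apoe, carrier)
            associations.append(
                fit_resilience_model(prep, Y1, X1, carrier, config.covariates)
            )
            if config.interaction:
                associations.append(
                    fit_interaction_model(prep, Y1, X1, carrier, config.covariates)
                )
    for snp in _snp_terms(prep, config.apoe_terms):
        associations.append(
            fit_resilience_model(prep, Y1, X1, snp, config.covariates, pcs=pcs or None)
        )
        if config.interaction:
            associations.append(
                fit_interaction_model(prep, Y1, X1, snp, config.covariates, pcs=pcs or None)
            )

    summary = {
        "label": cohort.cohort_label,
        "n": int(prep.n),
        "p": int(cca.p),
        "q": int(cca.q),
        "K": int(cca.K),
        "r": [float(v) for v in cca.r],
        "pct_covariance_eigen": [float(v) for v in cca.pct_covariance_eigen],
        "pct_covariance_rsq": [float(v) for v in cca.pct_covariance_rsq],
        "redundancy_y_given_x": [float(v) for v in cca.redundancy_y_given_x],
        "permutation": {"r_obs": perm.r_obs, "p_value": perm.p_value, "B": perm.B},
        "x_names": list(x_cols),
        "y_names": list(y_cols),
        "x_loadings_mode1": [float(v) for v in cca.x_loadings[:, 0]],
        "y_loadings_mode1": [float(v) for v in cca.y_loadings[:, 0]],
        "associations": [a.to_dict() for a in associations],
        "preprocess_steps": [s.step_name for s in plog.steps],
    }
    return summary, cca, associations


def run_study(config: PipelineConfig) -> StudyReport:
    """Run the full multi-cohort study and return (optionally write) the
    report."""
    cohorts = _load_cohorts(config)
    report = StudyReport(
        seed=config.seed,
        parameters={
            "ridge_eps": config.ridge_eps,
            "n_permutations": config.n_permutations,
            "covariates": list(config.covariates),
            "interaction": bool(config.interaction),
            "fdr": bool(config.fdr),
        },
    )
    all_assoc: dict[str, list[AssociationResult]] = {}
    for i, cohort in enumerate(cohorts):
        log.info("analyzing cohort %s (n=%d)", cohort.cohort_label, cohort.n)
        summary, cca, associations = analyze_cohort(cohort, config, i)
        report.cohorts.append(summary)
        for a in associations:
            if a.method == "one_model":
                all_assoc.setdefault(a.term, []).append(a)
        if config.out_dir is not None:
            out_dir = Path(config.out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_results(cca, out_dir / f"{cohort.cohort_label}.cca.json")

    snp_family: list[MetaResult] = []
    if len(cohorts) > 1:
        snp_terms = {
            t for c in cohorts for t in _snp_terms(c, config.apoe_terms)
        }
        for term, rows in all_assoc.items():
            if len(rows) < 2:
                continue
            m = fixed_effect_meta(rows, term=term)
            report.meta.append(m.to_dict())
            if term in snp_terms:
                snp_family.append(m)
        if config.fdr and snp_family:
            attach_fdr(snp_family)
            by_term = {m.term: m for m in snp_family}
            for row in report.meta:
                if row["term"] in by_term:
                    row["q_fdr"] = by_term[row["term"]].q_fdr

    if config.out_dir is not None:
        write_results(report, Path(config.out_dir) / "study_report.json")
    return report


def render_report(report: StudyReport, out_dir: str | Path) -> Path:
    """Write a human-readable Markdown summary and a machine TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lines = ["# Study report", ""]
    for c in report.cohorts:
        lines += [
            f"## Cohort {c['label']} (n={c['n']})",
            "",
            f"- CCA: p={c['p']} brain variables, q={c['q']} cognitive tests, K={c['K']} modes",
            f"- first canonical correlation r1 = {c['r'][0]:.3f} "
            f"(permutation p = {c['permutation']['p_value']:.4g}, B = {c['permutation']['B']})",
            f"- % co-variance explained by mode 1 (eigenvalue convention): "
            f"{c['pct_covariance_eigen'][0]:.1f}%",
            f"- redundancy of cognition given brain, mode 1: "
            f"{c['redundancy_y_given_x'][0]:.1f}%",
            "",
        ]
    if report.meta:
        lines += ["## Cross-cohort meta-analysis", ""]

    rows = []
    for c in report.cohorts:
        for a in c["associations"]:
            rows.append(
                {
                    "scope": c["label"],
                    "term": a["term"],
                    "beta": a["beta"],
                    "se": a["se"],
                    "ci_low": a["ci_low"],
                    "ci_high": a["ci_high"],
                    "p": a["p"],
                    "q_fdr": "",
                    "method": a["method"],
                }
            )
    for m in report.meta:
        rows.append(
            {
                "scope": "meta",
                "term": m["term"],
                "beta": m["beta_meta"],
                "se": m["se_meta"],
                "ci_low": m["beta_meta"] - 1.959963984540054 * m["se_meta"],
                "ci_high": m["beta_meta"] + 1.959963984540054 * m["se_meta"],
                "p": m["p"],
                "q_fdr": m.get("q_fdr", ""),
                "method": "fixed_effect_meta",
            }
        )
    tsv_path = out_dir / "associations.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")

    # per-cohort first-mode loadings, one row per original variable
    load_rows = []
    for c in report.cohorts:
        for name, v in zip(c["x_names"], c["x_loadings_mode1"]):
            load_rows.append({"cohort": c["label"], "set": "brain", "variable": name, "loading_mode1": v})
        for name, v in zip(c["y_names"], c["y_loadings_mode1"]):
            load_rows.append({"cohort": c["label"], "set": "cognition", "variable": name, "loading_mode1": v})
    pd.DataFrame(load_rows).to_csv(out_dir / "loadings.tsv", sep="\t", index=False)

    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines))
    return md_path
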
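"""Synthetic multi-cohort data with the statistical structure the analysis
assumes, plus exact ground truth for parameter-recovery tests.

The generative model is a two-latent factor model per cohort.  A brain
latent b (higher = healthier) carries age, sex and genotype effects; a
cognition latent c mixes b with education, genotype resilience effects and
noise; both are unit variance.  Regional MRI measures load on b (volumes
additionally on intracranial volume, the white-matter hypointensity burden
is log-normal in -b), cognitive tests load on c (some emitted on inverted
scales, including a TMT-A/TMT-B completion-time pair with a correlated
ratio), scanner batches shift/scale measures, and missingness is MCAR at
configured rates.

Because all effects are declared on latent scales, the population
covariance of the post-preprocessing variables is available in closed
form, so the ground truth can state the *implied* population canonical
correlation and the implied regression coefficient of every association
term -- the oracle every recovery test compares against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cca import inv_sqrt_psd
from .cohort import CohortTable, write_cohort
from .manifest import VariableEntry, VariableManifest
from .results import register_result, write_results

DEFAULT_VERHAGE_YEARS = (5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0)

BRAIN_TAG_CYCLE = ("frontal", "parietal", "temporal", "occipital", "cingulate")
COG_TAG_CYCLE = ("memory", "executive", "attention", "language")

# log-scale parameters of the TMT completion-time pair
TMT_A0, TMT_A1, TMT_SA = 3.6, 0.35, 0.25
TMT_R0, TMT_R1, TMT_SR = 0.75, 0.15, 0.20
WM_LOG_MEAN = 7.5


class SyntheticError(ValueError):
    pass


@dataclass
class SNPSpec:
    """One locus: minor-allele frequency and latent-scale effects.

    ``phi`` acts on the cognition latent given the brain latent (a
    resilience effect), ``theta`` on the brain latent; both are per SD of
    dosage.  ``risk_coded=False`` marks loci a cohort emits on the
    protective orientation (dosage 2 - g) to exercise risk flipping.
    """

    id: str
    maf: float
    phi: float = 0.0
    theta: float = 0.0
    risk_coded: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise SyntheticError(f"SNP {self.id!r}: maf must be in (0, 0.5]")


@dataclass
class CohortSpec:
    """Dimensions and nuisance structure of one synthetic cohort."""

    label: str
    n: int
    n_thickness: int = 8
    n_volumes: int = 0
    q_cog: int = 6
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    batch_scale_range: tuple[float, float] = (1.0, 1.0)
    age_mean: float = 70.0
    age_sd: float = 7.0
    verhage_probs: tuple[float, ...] = (0.02, 0.08, 0.15, 0.25, 0.25, 0.15, 0.10)
    dx_props: tuple[float, float, float] = (0.25, 0.35, 0.40)  # CU, MCI, AD
    include_tmt: bool = False
    include_wm_hypo: bool = False
    missing_cognition: float = 0.0
    missing_volume: float = 0.0
    missing_tmtb: float = 0.0
    protective_coded_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 50:
            raise SyntheticError(f"cohort {self.label!r}: n must be >= 50")
        if abs(sum(self.verhage_probs) - 1.0) > 1e-8:
            raise SyntheticError("verhage_probs must sum to 1")
        if abs(sum(self.dx_props) - 1.0) > 1e-8:
            raise SyntheticError("dx_props must sum to 1")
        if self.include_tmt and self.q_cog < 4:
            raise SyntheticError("TMT pair needs q_cog >= 4")


@dataclass
class SyntheticConfig:
    """Full study design: cohorts plus shared population parameters."""

    cohorts: list[CohortSpec]
    rho_latent: float = 0.75
    beta_edu: float = 0.15
    gamma_age: float = -0.35
    gamma_sex: float = 0.05
    snp_panel: list[SNPSpec] = field(default_factory=list)
    mri_loadings: tuple[float, float] = (0.5, 0.85)
    cog_loadings: tuple[float, float] = (0.5, 0.9)
    icv_coupling: tuple[float, float] = (0.3, 0.5)
    wm_coupling: float = 0.5
    wm_noise: float = 0.5
    interaction_effect: float = 0.0
    verhage_years: tuple[float, ...] = DEFAULT_VERHAGE_YEARS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_latent <= 1.0):
            raise SyntheticError("rho_latent must lie in [0, 1]")
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise SyntheticError(f"duplicate cohort labels: {labels}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@register_result
@dataclass
class GroundTruth:
    """Per-cohort latents plus model-implied oracle quantities."""

    cohort_label: str
    b: np.ndarray
    c: np.ndarray
    config: dict
    implied_population_cca: float
    implied_regression_betas: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# deterministic structural parameters
# ---------------------------------------------------------------------------

def _structure(config: SyntheticConfig, spec: CohortSpec) -> dict:
    """Deterministic loadings/couplings for one cohort (no RNG involved)."""
    lo, hi = config.mri_loadings
    lam_thick = np.linspace(hi, lo, spec.n_thickness) if spec.n_thickness else np.empty(0)
    lam_vol = (
        np.linspace(hi * 0.9, lo * 0.9, spec.n_volumes) if spec.n_volumes else np.empty(0)
    )
    eta = (
        np.linspace(config.icv_coupling[0], config.icv_coupling[1], spec.n_volumes)
        if spec.n_volumes
        else np.empty(0)
    )
    bad = lam_vol**2 + eta**2 >= 1.0
    if bad.any():
        raise SyntheticError("volume loading^2 + icv coupling^2 must stay below 1")

    n_special = (2 if spec.include_tmt else 0)
    n_linear = spec.q_cog - n_special
    klo, khi = config.cog_loadings
    kappa = np.linspace(khi, klo, spec.q_cog)
    # one inverted linear test whenever the battery is large enough
    stroop_ix = n_linear - 1 if n_linear >= 5 else None

    weights = np.round(np.linspace(0.5, 2.0, spec.n_thickness), 3) if spec.n_thickness else np.empty(0)
    return {
        "lam_thick": lam_thick,
        "lam_vol": lam_vol,
        "eta": eta,
        "kappa": kappa,
        "n_linear": n_linear,
        "stroop_ix": stroop_ix,
        "region_weights": weights,
    }


def _latent_budget(config: SyntheticConfig) -> tuple[float, float]:
    """Residual SDs of the two latents; fatal if the budget is infeasible."""
    theta = np.array([s.theta for s in config.snp_panel])
    phi = np.array([s.phi for s in config.snp_panel])
    var_b_sys = config.gamma_age**2 + config.gamma_sex**2 + float(np.sum(theta**2))
    if var_b_sys > 1.0 + 1e-12:
        raise SyntheticError(
            f"brain-latent variance budget infeasible: systematic variance {var_b_sys:.3f} > 1"
        )
    rho = config.rho_latent
    var_c_sys = (
        rho**2
        + config.beta_edu**2
        + float(np.sum(phi**2))
        + 2.0 * rho * float(np.sum(theta * phi))
        + config.interaction_effect**2
    )
    if var_c_sys > 1.0 + 1e-12:
        raise SyntheticError(
            f"cognition-latent variance budget infeasible: systematic variance {var_c_sys:.3f} > 1"
        )
    return (
        float(np.sqrt(max(1.0 - var_b_sys, 0.0))),
        float(np.sqrt(max(1.0 - var_c_sys, 0.0))),
    )


def _edu_moments(config: SyntheticConfig, spec: CohortSpec) -> tuple[float, float]:
    years = np.asarray(config.verhage_years, dtype=float)
    p = np.asarray(spec.verhage_probs, dtype=float)
    mean = float(np.sum(p * years))
    var = float(np.sum(p * years**2) - mean**2)
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# implied (population) quantities
# ---------------------------------------------------------------------------

def _factor_model(config: SyntheticConfig, spec: CohortSpec) -> dict:
    """Loadings of every post-preprocessing variable on the orthonormal
    factor basis [age, sex, edu, SNPs..., (b x edu), eps_b, eps_c, icv].

    Volumetric columns are represented after ICV adjustment and all columns
    after z-scoring, i.e. exactly what enters the CCA.  The TMT pair is
    linearized through the exact log-normal correlation with the cognition
    latent; its shared ratio noise is approximated as independent.
    """
    st = _structure(config, spec)
    sigma_b, sigma_c = _latent_budget(config)
    snps = config.snp_panel
    factors = (
        ["age", "sex", "edu"]
        + [s.id for s in snps]
        + ["bxedu", "eps_b", "eps_c", "icv"]
    )
    fi = {f: i for i, f in enumerate(factors)}
    F = len(factors)

    b = np.zeros(F)
    b[fi["age"]] = config.gamma_age
    b[fi["sex"]] = config.gamma_sex
    for s in snps:
        b[fi[s.id]] = s.theta
    b[fi["eps_b"]] = sigma_b

    c = config.rho_latent * b.copy()
    c[fi["edu"]] += config.beta_edu
    for s in snps:
        c[fi[s.id]] += s.phi
    c[fi["bxedu"]] = config.interaction_effect
    c[fi["eps_c"]] = sigma_c

    x_rows, x_unique, x_names = [], [], []
    for j, lam in enumerate(st["lam_thick"]):
        x_rows.append(lam * b)
        x_unique.append(1.0 - lam**2)
        x_names.append(f"thick_{BRAIN_TAG_CYCLE[j % len(BRAIN_TAG_CYCLE)]}_{j + 1:02d}")
    for j, (lam, eta) in enumerate(zip(st["lam_vol"], st["eta"])):
        lam_adj = lam / np.sqrt(1.0 - eta**2)  # after ICV adjustment + rescale
        x_rows.append(lam_adj * b)
        x_unique.append(1.0 - lam_adj**2)
        x_names.append(f"vol_{j + 1:02d}")
    if spec.n_volumes or spec.include_wm_hypo:
        icv_row = np.zeros(F)
        icv_row[fi["icv"]] = 1.0
        x_rows.append(icv_row)
        x_unique.append(0.0)
        x_names.append("icv")
    if spec.include_wm_hypo:
        lam_wm = config.wm_coupling / np.sqrt(config.wm_coupling**2 + config.wm_noise**2)
        x_rows.append(lam_wm * b)
        x_unique.append(1.0 - lam_wm**2)
        x_names.append("wm_hypo")

    y_rows, y_unique, y_names = [], [], []
    kappa = st["kappa"]
    for t in range(st["n_linear"]):
        y_rows.append(kappa[t] * c)
        y_unique.append(1.0 - kappa[t] ** 2)
        if t == 0:
            y_names.append("mmse")
        elif t == st["stroop_ix"]:
            y_names.append("stroop_cw")
        else:
            y_names.append(f"cog_{COG_TAG_CYCLE[(t - 1) % len(COG_TAG_CYCLE)]}_{t + 1:02d}")
    if spec.include_tmt:
        k_a = TMT_A1 / np.sqrt(np.exp(TMT_A1**2 + TMT_SA**2) - 1.0)
        su2 = (TMT_A1 + TMT_R1) ** 2 + TMT_SA**2 + TMT_SR**2
        k_b = (TMT_A1 + TMT_R1) / np.sqrt(np.exp(su2) - 1.0)
        for name, k in (("tmt_a", k_a), ("tmt_b", k_b)):
            y_rows.append(k * c)
            y_unique.append(1.0 - k**2)
            y_names.append(name)

    return {
        "factors": factors,
        "fi": fi,
        "b": b,
        "c": c,
        "Lx": np.array(x_rows),
        "ux": np.array(x_unique),
        "x_names": x_names,
        "Ly": np.array(y_rows),
        "uy": np.array(y_unique),
        "y_names": y_names,
    }


def implied_covariances(config: SyntheticConfig, spec: CohortSpec) -> dict:
    """Population covariance blocks of the CCA input variables."""
    fm = _factor_model(config, spec)
    Lx, Ly = fm["Lx"], fm["Ly"]
    Cxx = Lx @ Lx.T + np.diag(fm["ux"])
    Cyy = Ly @ Ly.T + np.diag(fm["uy"])
    Cxy = Lx @ Ly.T
    return {**fm, "Cxx": Cxx, "Cyy": Cyy, "Cxy": Cxy}


def population_cca(Cxx: np.ndarray, Cyy: np.ndarray, Cxy: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """First population canonical correlation and weight pair from a
    covariance model (whitened-SVD route, no ridge)."""
    Wx, _ = inv_sqrt_psd(Cxx, 0.0)
    Wy, _ = inv_sqrt_psd(Cyy, 0.0)
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    wx = Wx @ U[:, 0]
    wy = Wy @ Vt[0]
    return float(np.clip(s[0], 0.0, 1.0)), wx, wy


def compute_ground_truth_implied(config: SyntheticConfig, spec: CohortSpec) -> dict:
    """Implied first canonical correlation and association coefficients.

    The implied regression coefficients answer: in the population, what is
    the coefficient of each term in OLS of the first cognition variate on
    [X1, age, sex, term]?  Education is per SD; SNPs are per risk allele
    (raw dosage); APOE-like terms are per carriership.
    """
    cov = implied_covariances(config, spec)
    r1, wx, wy = population_cca(cov["Cxx"], cov["Cyy"], cov["Cxy"])
    # orient: mean y-loading positive
    y_load = cov["Cyy"] @ wy
    if y_load.mean() < 0:
        wx, wy = -wx, -wy

    fi = cov["fi"]
    # factor coefficients of the population variates
    y1 = cov["Ly"].T @ wy
    x1 = cov["Lx"].T @ wx
    uy1 = float(np.sum(wy**2 * cov["uy"]))  # unique variance in Y1

    def cov_with(coefs: np.ndarray, term: str) -> float:
        """Covariance of a variate with a term variable."""
        if term in ("age", "sex", "edu"):
            return float(coefs[fi[term]])
        raise KeyError(term)

    def solve_beta(term_cov_x1: float, term_cov_y1: float, term_var: float) -> float:
        # predictors: X1, age_z, sex_z, term
        names = ["x1", "age", "sex"]
        C = np.zeros((4, 4))
        C[0, 0] = 1.0
        C[1, 1] = C[2, 2] = 1.0
        C[3, 3] = term_var
        C[0, 1] = C[1, 0] = x1[fi["age"]]
        C[0, 2] = C[2, 0] = x1[fi["sex"]]
        C[0, 3] = C[3, 0] = term_cov_x1
        v = np.array(
            [
                float(x1 @ y1) + 0.0,  # Cov(Y1, X1): shared factors only
                y1[fi["age"]],
                y1[fi["sex"]],
                term_cov_y1,
            ]
        )
        return float(np.linalg.solve(C, v)[3])

    betas: dict[str, float] = {}
    betas["education"] = solve_beta(0.0, float(y1[fi["edu"]]), 1.0)
    for s in config.snp_panel:
        sd_g = float(np.sqrt(2.0 * s.maf * (1.0 - s.maf)))
        betas[s.id] = solve_beta(
            float(x1[fi[s.id]]) * sd_g, float(y1[fi[s.id]]) * sd_g, sd_g**2
        )
        # carriership coding (dosage > 0)
        p_c = 1.0 - (1.0 - s.maf) ** 2
        cov_gz_carrier = 2.0 * s.maf * (1.0 - s.maf) ** 2 / sd_g
        betas[f"{s.id}_carrier"] = solve_beta(
            float(x1[fi[s.id]]) * cov_gz_carrier,
            float(y1[fi[s.id]]) * cov_gz_carrier,
            p_c * (1.0 - p_c),
        )
    _ = uy1, cov_with
    return {"implied_population_cca": r1, "implied_regression_betas": betas}


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _build_manifest(config: SyntheticConfig, spec: CohortSpec, fm: dict) -> VariableManifest:
    st = _structure(config, spec)
    entries = [VariableEntry(name="subject_id", role="id")]
    if spec.n_batches > 1:
        entries.append(VariableEntry(name="scanner", role="batch"))
    entries.append(VariableEntry(name="diagnosis", role="diagnosis"))
    for name in ("age", "sex", "education"):
        entries.append(VariableEntry(name=name, role="covariate"))
    for k in range(1, 6):
        entries.append(VariableEntry(name=f"pc{k}", role="genetic_pc"))
    for s in config.snp_panel:
        orientation = (
            "protective_coded" if s.id in spec.protective_coded_snps else "risk_coded"
        )
        entries.append(
            VariableEntry(name=s.id, role="genotype", risk_orientation=orientation)
        )
    thick_names = [n for n in fm["x_names"] if n.startswith("thick_")]
    for j, name in enumerate(thick_names):
        tag = name.split("_")[1]
        entries.append(
            VariableEntry(
                name=name,
                role="mri_thickness",
                domain_tag=tag,
                direction="higher_is_better",
                region_weight=float(st["region_weights"][j]),
            )
        )
    for name in fm["x_names"]:
        if name.startswith("vol_"):
            entries.append(
                VariableEntry(
                    name=name,
                    role="mri_volume",
                    domain_tag="subcortical",
                    direction="higher_is_better",
                )
            )
    if "icv" in fm["x_names"]:
        entries.append(
            VariableEntry(
                name="icv", role="mri_global", domain_tag="global_brain",
                direction="higher_is_better",
            )
        )
    if "wm_hypo" in fm["x_names"]:
        entries.append(
            VariableEntry(
                name="wm_hypo",
                role="mri_global",
                domain_tag="global_brain",
                direction="lower_is_better",
                transform="negate_log1p",
            )
        )
    for name in fm["y_names"]:
        if name == "mmse":
            tag, direction = "global_cognition", "higher_is_better"
        elif name == "stroop_cw":
            tag, direction = "attention", "lower_is_better"
        elif name == "tmt_a":
            tag, direction = "attention", "lower_is_better"
        elif name == "tmt_b":
            tag, direction = "executive", "lower_is_better"
        else:
            tag, direction = name.split("_")[1], "higher_is_better"
        entries.append(
            VariableEntry(name=name, role="cognition", domain_tag=tag, direction=direction)
        )
    return VariableManifest(entries=entries)


def simulate_cohort(
    config: SyntheticConfig, cohort_index: int
) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth; bit-reproducible given the
    config seed and cohort index."""
    spec = config.cohorts[cohort_index]
    st = _structure(config, spec)
    fm = _factor_model(config, spec)
    sigma_b, sigma_c = _latent_budget(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), cohort_index]))
    n = spec.n

    age_z = rng.standard_normal(n)
    sex = rng.binomial(1, 0.5, n).astype(float)
    sex_z = (sex - 0.5) * 2.0
    levels = rng.choice(len(spec.verhage_probs), size=n, p=spec.verhage_probs)
    years = np.asarray(config.verhage_years)[levels]
    edu_mean, edu_sd = _edu_moments(config, spec)
    edu_z = (years - edu_mean) / edu_sd
    pcs = rng.standard_normal((n, 5))
    icv_z = rng.standard_normal(n)

    snps = config.snp_panel
    G = np.column_stack(
        [rng.binomial(2, s.maf, n).astype(float) for s in snps]
    ) if snps else np.empty((n, 0))
    Gz = np.column_stack(
        [(G[:, j] - 2 * s.maf) / np.sqrt(2 * s.maf * (1 - s.maf)) for j, s in enumerate(snps)]
    ) if snps else np.empty((n, 0))
    theta = np.array([s.theta for s in snps])
    phi = np.array([s.phi for s in snps])

    b = (
        config.gamma_age * age_z
        + config.gamma_sex * sex_z
        + (Gz @ theta if snps else 0.0)
        + sigma_b * rng.standard_normal(n)
    )
    c = (
        config.rho_latent * b
        + config.beta_edu * edu_z
        + (Gz @ phi if snps else 0.0)
        + config.interaction_effect * b * edu_z
        + sigma_c * rng.standard_normal(n)
    )

    # diagnosis from the cognition latent (low c = AD)
    p_cu, p_mci, p_ad = spec.dx_props
    t_ad = stats.norm.ppf(p_ad)
    t_mci = stats.norm.ppf(p_ad + p_mci)
    dx = np.where(c < t_ad, 2.0, np.where(c < t_mci, 1.0, 0.0))

    data: dict[str, np.ndarray] = {}
    data["age"] = spec.age_mean + spec.age_sd * age_z
    data["sex"] = sex
    data["education"] = years.astype(float)
    data["diagnosis"] = dx
    for k in range(5):
        data[f"pc{k + 1}"] = pcs[:, k]
    for j, s in enumerate(snps):
        g = G[:, j]
        if s.id in spec.protective_coded_snps:
            g = 2.0 - g
        data[s.id] = g

    if spec.n_batches > 1:
        batch = np.arange(n) % spec.n_batches
        data["scanner"] = batch.astype(float)
        shift = rng.normal(0.0, spec.batch_shift_sd, size=(spec.n_batches, 1))
        lo_s, hi_s = spec.batch_scale_range
        scale = rng.uniform(lo_s, hi_s, size=(spec.n_batches, 1))
    else:
        batch = np.zeros(n, dtype=int)
        shift = np.zeros((1, 1))
        scale = np.ones((1, 1))

    def batch_noise(std_noise: np.ndarray, col: int) -> np.ndarray:
        return shift[batch, 0] * _batch_sign(col) + scale[batch, 0] * std_noise

    def _batch_sign(col: int) -> float:
        # alternate shift direction across variables so shifts do not mimic
        # a global offset
        return 1.0 if col % 2 == 0 else -1.0

    thick_means = np.linspace(2.2, 2.8, spec.n_thickness) if spec.n_thickness else np.empty(0)
    for j, lam in enumerate(st["lam_thick"]):
        noise = np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        std_col = lam * b + batch_noise(noise, j)
        data[fm["x_names"][j]] = thick_means[j] + 0.15 * std_col

    vol_means = np.linspace(1500.0, 7500.0, spec.n_volumes) if spec.n_volumes else np.empty(0)
    for j, (lam, eta) in enumerate(zip(st["lam_vol"], st["eta"])):
        noise = np.sqrt(1.0 - lam**2 - eta**2) * rng.standard_normal(n)
        std_col = lam * b + eta * icv_z + batch_noise(noise, spec.n_thickness + j)
        data[f"vol_{j + 1:02d}"] = vol_means[j] + 0.12 * vol_means[j] * std_col

    if spec.n_volumes or spec.include_wm_hypo:
        data["icv"] = 1.45e6 + 1.55e5 * icv_z
    if spec.include_wm_hypo:
        wm_log = WM_LOG_MEAN - config.wm_coupling * b + config.wm_noise * rng.standard_normal(n)
        data["wm_hypo"] = np.exp(wm_log)

    kappa = st["kappa"]
    cog_means = np.linspace(25.0, 40.0, st["n_linear"]) if st["n_linear"] else np.empty(0)
    for t in range(st["n_linear"]):
        name = fm["y_names"][t]
        std_col = kappa[t] * c + np.sqrt(1.0 - kappa[t] ** 2) * rng.standard_normal(n)
        sign = -1.0 if name == "stroop_cw" else 1.0
        data[name] = cog_means[t] + 5.0 * sign * std_col
    if spec.include_tmt:
        eps_a = rng.standard_normal(n)
        eps_r = rng.standard_normal(n)
        tmt_a = np.exp(TMT_A0 - TMT_A1 * c + TMT_SA * eps_a)
        ratio = np.exp(TMT_R0 - TMT_R1 * c + TMT_SR * eps_r)
        data["tmt_a"] = tmt_a
        data["tmt_b"] = tmt_a * ratio

    # MCAR missingness
    cog_names = fm["y_names"]
    for name in cog_names:
        if spec.missing_cognition > 0:
            mask = rng.random(n) < spec.missing_cognition
            data[name] = np.where(mask, np.nan, data[name])
    if spec.missing_tmtb > 0 and spec.include_tmt:
        extra = (rng.random(n) < spec.missing_tmtb) & ~np.isnan(data["tmt_a"])
        data["tmt_b"] = np.where(extra, np.nan, data["tmt_b"])
    if spec.missing_volume > 0:
        for j in range(spec.n_volumes):
            name = f"vol_{j + 1:02d}"
            mask = rng.random(n) < spec.missing_volume
            data[name] = np.where(mask, np.nan, data[name])

    ids = [f"{spec.label}_{i + 1:05d}" for i in range(n)]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
    manifest = _build_manifest(config, spec, fm)
    order = [e.name for e in manifest.entries if e.name != "subject_id"]
    cohort = CohortTable(cohort_label=spec.label, data=frame[order], manifest=manifest)

    implied = compute_ground_truth_implied(config, spec)
    truth = GroundTruth(
        cohort_label=spec.label,
        b=b,
        c=c,
        config=config.to_dict(),
        implied_population_cca=implied["implied_population_cca"],
        implied_regression_betas=implied["implied_regression_betas"],
    )
    return cohort, truth


def simulate_study(
    config: SyntheticConfig, out_dir: Optional[str | Path] = None
) -> list[tuple[CohortTable, GroundTruth]]:
    """Simulate every cohort of a study; optionally write CSV + manifest +
    ground-truth JSON per cohort."""
    out = [simulate_cohort(config, i) for i in range(len(config.cohorts))]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cohort, truth in out:
            write_cohort(
                cohort,
                out_dir / f"{cohort.cohort_label}.csv",
                out_dir / f"{cohort.cohort_label}.manifest.yaml",
            )
            write_results(truth, out_dir / f"{cohort.cohort_label}.truth.json")
    return out


# ---------------------------------------------------------------------------
# default study
# ---------------------------------------------------------------------------

def default_snp_panel() -> list[SNPSpec]:
    """APOE-like pair plus an 83-locus panel with five planted resilience
    effects (the rest null)."""
    panel = [
        SNPSpec(id="apoe4", maf=0.45, phi=-0.06, theta=-0.12),
        SNPSpec(id="apoe2", maf=0.03, phi=0.02, theta=0.03),
    ]
    mafs = np.round(np.linspace(0.05, 0.5, 83), 3)
    planted = {4: -0.09, 20: -0.08, 38: 0.08, 56: -0.08, 72: 0.09}
    for j in range(83):
        panel.append(
            SNPSpec(id=f"snp{j + 1:03d}", maf=float(mafs[j]), phi=planted.get(j + 1, 0.0))
        )
    return panel


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """Two-cohort study at realistic scale: a large memory-clinic cohort
    with a 16-test battery and a smaller multi-site cohort with 11 tests,
    sharing the SNP panel (three loci protective-coded in the second
    cohort to exercise risk orientation)."""
    cohort_a = CohortSpec(
        label="cohort_a",
        n=1036,
        n_thickness=68,
        n_volumes=16,
        q_cog=16,
        n_batches=10,
        batch_shift_sd=0.08,
        batch_scale_range=(0.9, 1.1),
        age_mean=65.9,
        age_sd=6.8,
        verhage_probs=(0.02, 0.08, 0.15, 0.25, 0.25, 0.15, 0.10),
        dx_props=(0.108, 0.211, 0.681),
        include_tmt=True,
        include_wm_hypo=True,
        missing_cognition=0.04,
        missing_volume=0.03,
        missing_tmtb=0.08,
    )
    cohort_b = replace(
        cohort_a,
        label="cohort_b",
        n=685,
        q_cog=11,
        n_batches=21,
        age_mean=75.0,
        age_sd=7.25,
        verhage_probs=(0.0, 0.0, 0.05, 0.10, 0.20, 0.30, 0.35),
        dx_props=(0.273, 0.418, 0.309),
        protective_coded_snps=("snp010", "snp030", "snp050"),
    )
    return SyntheticConfig(
        cohorts=[cohort_a, cohort_b],
        rho_latent=0.75,
        beta_edu=0.15,
        snp_panel=default_snp_panel(),
        seed=seed,
    )
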
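"""Variable-level preparation of cohort tables before modeling.

The chain, in fixed order (each step optional via the orchestrator):

1.  TMT-B imputation from TMT-A via a diagnostic-group ratio
2.  directionality alignment (higher output = better/healthier)
3.  sparsity exclusions (subjects with too few tests; near-empty tests)
4.  outlier QC of volumetric measures within diagnostic group
5.  chained predictive-mean-matching (PMM) imputation
6.  ICV adjustment of volumetric measures
7.  location/scale batch harmonization with protected covariates
8.  regional composites (weighted / unweighted means)
9.  genotype orientation to risk coding
10. reference z-scoring over the whole cohort

Every step returns a fresh :class:`~resilcca.cohort.CohortTable` and a log
record; nothing mutates its input.  Only the sparsity step may change the
number of rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .manifest import VariableEntry
from .results import register_result

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Raised on fatal preprocessing problems."""


@dataclass
class StepRecord:
    step_name: str
    variables_touched: list[str] = field(default_factory=list)
    subjects_excluded: list[str] = field(default_factory=list)
    values_imputed_or_set_missing: int = 0
    parameters: dict = field(default_factory=dict)


@register_result
@dataclass
class PreprocessLog:
    """Ordered record of the preprocessing steps actually executed."""

    steps: list[StepRecord] = field(default_factory=list)

    def add(self, record: StepRecord) -> None:
        self.steps.append(record)

    def to_dict(self) -> dict:
        return {"steps": [asdict(s) for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessLog":
        return cls(steps=[StepRecord(**s) for s in d["steps"]])


# ---------------------------------------------------------------------------
# 1. TMT-B imputation
# ---------------------------------------------------------------------------

def impute_tmtb(cohort: CohortTable, tmta: str, tmtb: str, group: str) -> CohortTable:
    """Fill missing TMT-B from TMT-A and a diagnostic-group time ratio.

    Applied to raw (pre-inversion) completion times.  For each diagnostic
    group, the ratio is the median of tmtb/tmta over subjects with both
    scores; subjects missing TMT-B but not TMT-A get ``tmta * ratio``.
    Subjects missing both stay missing, as do subjects in groups without
    any complete case (with a warning).
    """
    out = cohort.copy()
    df = out.data
    a = df[tmta].to_numpy(dtype=float)
    b = df[tmtb].to_numpy(dtype=float)
    g = df[group].to_numpy()
    filled = 0
    for level in pd.unique(g[~pd.isna(g)]):
        in_g = g == level
        complete = in_g & ~np.isnan(a) & ~np.isnan(b) & (a != 0)
        needs = in_g & ~np.isnan(a) & np.isnan(b)
        if not needs.any():
            continue
        if not complete.any():
            warnings.warn(
                f"no complete TMT-A/TMT-B cases in group {level!r}; "
                f"{int(needs.sum())} subject(s) left missing",
                stacklevel=2,
            )
            continue
        ratio = float(np.median(b[complete] / a[complete]))
        b[needs] = a[needs] * ratio
        filled += int(needs.sum())
    df[tmtb] = b
    log.info("impute_tmtb: filled %d TMT-B value(s)", filled)
    return out


# ---------------------------------------------------------------------------
# 2. directionality
# ---------------------------------------------------------------------------

def apply_directionality(cohort: CohortTable) -> CohortTable:
    """Align every scored variable so that higher means better/healthier.

    Per manifest entry: ``negate_log1p`` maps x to -log(1+x) (for
    right-skewed burden measures such as WM-hypo); ``log1p`` maps to
    log(1+x), negated when the variable is lower-is-better; ``none`` simply
    negates lower-is-better scores (e.g., completion times).  Transformed
    entries are re-declared higher-is-better with no pending transform, so
    the step is idempotent.
    """
    out = cohort.copy()
    for entry in out.manifest.entries:
        if entry.direction is None:
            continue
        x = out.data[entry.name].to_numpy(dtype=float)
        lower_better = entry.direction == "lower_is_better"
        if entry.transform in ("log1p", "negate_log1p"):
            if np.nanmin(x, initial=np.inf) < 0:
                raise PreprocessError(
                    f"negative input to log transform of variable {entry.name!r}"
                )
        if entry.transform == "negate_log1p":
            if not lower_better:
                raise PreprocessError(
                    f"negate_log1p on higher_is_better variable {entry.name!r} "
                    "would invert its direction"
                )
            x = -np.log1p(x)
        elif entry.transform == "log1p":
            x = np.log1p(x)
            if lower_better:
                x = -x
        else:
            if lower_better:
                x = -x
        out.data[entry.name] = x
        entry.direction = "higher_is_better"
        entry.transform = "none"
    return out


# ---------------------------------------------------------------------------
# 3. sparsity exclusions
# ---------------------------------------------------------------------------

def exclude_sparse(
    cohort: CohortTable,
    min_tests: int = 3,
    max_var_missing: float = 0.5,
) -> tuple[CohortTable, PreprocessLog]:
    """Drop under-tested subjects, then near-empty cognitive tests.

    Subjects with fewer than ``min_tests`` non-missing cognitive scores are
    excluded (strict ``<``); afterwards, cognitive variables missing in
    strictly more than ``max_var_missing`` of the remaining subjects are
    dropped (a variable missing in exactly the boundary fraction is kept).
    """
    out = cohort.copy()
    plog = PreprocessLog()
    cog = out.manifest.cognition_columns()
    if not cog:
        return out, plog

    n_present = out.data[cog].notna().sum(axis=1)
    drop_rows = out.data.index[n_present < min_tests]
    if len(drop_rows):
        out.data = out.data.drop(index=drop_rows)
    drop_vars = []
    if out.n:
        frac = out.data[cog].isna().mean(axis=0)
        drop_vars = [c for c in cog if frac[c] > max_var_missing]
    if len(drop_vars) == len(cog):
        raise PreprocessError("sparsity exclusion dropped every cognitive variable")
    if drop_vars:
        out.data = out.data.drop(columns=drop_vars)
        out.manifest.entries = [e for e in out.manifest.entries if e.name not in drop_vars]
    if len(drop_rows) or drop_vars:
        plog.add(
            StepRecord(
                step_name="exclude_sparse",
                variables_touched=drop_vars,
                subjects_excluded=[str(i) for i in drop_rows],
                parameters={"min_tests": min_tests, "max_var_missing": max_var_missing},
            )
        )
    return out, plog


# ---------------------------------------------------------------------------
# 4. outlier QC
# ---------------------------------------------------------------------------

def qc_outliers(
    cohort: CohortTable,
    vars: Sequence[str],
    group: str,
    k_sd: float = 2.0,
) -> CohortTable:
    """Set values outside mean +/- k_sd standard deviations (within
    diagnostic group) to missing.

    Boundary values are retained (strict inequality).  Groups with fewer
    than 3 observed values for a variable are left untouched with a
    warning.
    """
    out = cohort.copy()
    g = out.data[group].to_numpy()
    n_removed = 0
    for v in vars:
        x = out.data[v].to_numpy(dtype=float)
        for level in pd.unique(g[~pd.isna(g)]):
            in_g = (g == level) & ~np.isnan(x)
            if in_g.sum() < 3:
                warnings.warn(
                    f"group {level!r} has <3 observed values for {v!r}; QC skipped",
                    stacklevel=2,
                )
                continue
            m = x[in_g].mean()
            s = x[in_g].std(ddof=1)
            outside = in_g & ((x < m - k_sd * s) | (x > m + k_sd * s))
            n_removed += int(outside.sum())
            x[outside] = np.nan
        out.data[v] = x
    log.info("qc_outliers: set %d value(s) to missing", n_removed)
    return out


def flag_surface_holes(values: np.ndarray) -> np.ndarray:
    """One-sided segmentation-quality flag: value > median + 3 * IQR.

    Larger hole counts indicate poor cortical segmentation, so only the
    upper tail is flagged; a value exactly at the threshold is not flagged.
    Missing values are never flagged.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 4:
        raise PreprocessError("flag_surface_holes needs at least 4 values")
    med = np.median(obs)
    q75, q25 = np.percentile(obs, [75, 25])
    threshold = med + 3.0 * (q75 - q25)
    flags = np.zeros(x.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags[~np.isnan(x)] = x[~np.isnan(x)] > threshold
    return flags


# ---------------------------------------------------------------------------
# 5. PMM imputation
# ---------------------------------------------------------------------------

def _pmm_impute_frame(
    frame: pd.DataFrame,
    targets: Sequence[str],
    predictors: Sequence[str],
    k_donors: int,
    cycles: int,
    seed: int,
) -> pd.DataFrame:
    """Chained PMM on a plain frame; returns a copy with targets filled."""
    targets = [t for t in targets if t in frame.columns]
    work_cols = list(dict.fromkeys(list(predictors) + list(targets)))
    M = frame[work_cols].to_numpy(dtype=float).copy()
    col_ix = {c: j for j, c in enumerate(work_cols)}

    obs_mask = ~np.isnan(M)
    for t in targets:
        if not obs_mask[:, col_ix[t]].any():
            raise PreprocessError(f"target {t!r} has zero observed values")

    # mean-initialize every missing cell in the working matrix
    col_means = np.nanmean(M, axis=0)
    for j in range(M.shape[1]):
        M[np.isnan(M[:, j]), j] = col_means[j]

    rng = np.random.default_rng(seed)
    n_imputed = 0
    for _cycle in range(cycles):
        for t in targets:
            j = col_ix[t]
            obs = obs_mask[:, j]
            mis = ~obs
            if not mis.any():
                continue
            pred_cols = [col_ix[p] for p in work_cols if p != t]
            D = np.column_stack([np.ones(M.shape[0]), M[:, pred_cols]])
            coef, _, rank, _ = np.linalg.lstsq(D[obs], M[obs, j], rcond=None)
            if rank < D.shape[1]:
                warnings.warn(
                    f"collinear predictors while imputing {t!r}; "
                    "using minimum-norm least squares",
                    stacklevel=2,
                )
            yhat = D @ coef
            obs_idx = np.where(obs)[0]
            for i in np.where(mis)[0]:
                d = np.abs(yhat[obs_idx] - yhat[i])
                k = min(k_donors, obs_idx.size)
                nearest = obs_idx[np.argpartition(d, k - 1)[:k]]
                donor = rng.choice(nearest)
                M[i, j] = M[donor, j]
                n_imputed += 1
    out = frame.copy()
    for t in targets:
        out[t] = M[:, col_ix[t]]
    log.info("pmm: drew %d donor value(s) over %d cycle(s)", n_imputed, cycles)
    return out


def pmm_impute(
    cohort: CohortTable,
    targets: Sequence[str],
    predictors: Sequence[str],
    k_donors: int = 5,
    cycles: int = 5,
    seed: int = 0,
) -> CohortTable:
    """Single imputation by chained predictive mean matching.

    Missing targets are mean-initialized, then for ``cycles`` sweeps each
    target is regressed (least squares) on the current predictor values of
    its observed rows, predictions are computed for every row, and each
    missing row copies the observed value of a donor drawn uniformly among
    the ``k_donors`` observed rows with the nearest prediction (type-0
    matching).  Consequences: every imputed value equals some observed
    value of the same variable, and the result is deterministic given
    ``seed``.
    """
    out = cohort.copy()
    out.data = _pmm_impute_frame(out.data, targets, predictors, k_donors, cycles, seed)
    return out


# ---------------------------------------------------------------------------
# 6. ICV adjustment
# ---------------------------------------------------------------------------

def adjust_icv(cohort: CohortTable, volume_vars: Sequence[str], icv: str) -> CohortTable:
    """Regress intracranial volume out of each volumetric variable.

    Each volume is replaced by the residual of a least-squares fit on
    [1, ICV] plus the variable's original mean, so the scale (and
    downstream z-scoring) is unaffected while the sample correlation with
    ICV becomes zero.  Requires imputation to have run first.
    """
    out = cohort.copy()
    icv_vals = out.data[icv].to_numpy(dtype=float)
    if np.isnan(icv_vals).any():
        raise PreprocessError("ICV has missing values; impute before adjustment")
    if np.std(icv_vals) == 0:
        raise PreprocessError("ICV is constant; cannot adjust")
    D = np.column_stack([np.ones(len(icv_vals)), icv_vals])
    for v in volume_vars:
        x = out.data[v].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise PreprocessError(f"volume {v!r} has missing values; impute before adjustment")
        coef, *_ = np.linalg.lstsq(D, x, rcond=None)
        out.data[v] = x - D @ coef + x.mean()
    return out


# ---------------------------------------------------------------------------
# 7. batch harmonization
# ---------------------------------------------------------------------------

def _protected_design(cohort: CohortTable, protect: Sequence[str]) -> np.ndarray:
    """Intercept + protected covariates; diagnosis expands to dummies."""
    cols = [np.ones(cohort.n)]
    dx_col = cohort.manifest.diagnosis_column
    for p in protect:
        x = cohort.data[p].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise PreprocessError(f"protected covariate {p!r} has missing values")
        if p == dx_col:
            levels = np.unique(x)
            for level in levels[1:]:
                cols.append((x == level).astype(float))
        else:
            cols.append(x)
    return np.column_stack(cols)


def harmonize_batches(
    cohort: CohortTable,
    vars: Sequence[str],
    batch: str,
    protect: Sequence[str],
) -> CohortTable:
    """Location/scale harmonization across scanner batches.

    Per variable: fit least squares on the protected-covariate design plus
    sum-to-zero batch offsets, then rescale each batch's residuals to the
    pooled residual SD and drop the batch offsets:

        out = protected fit + (residual - batch offset) * pooled_sd / batch_sd

    Batch means and variances of the residuals are removed while the
    variance explained by the protected biological covariates (age, sex,
    diagnosis) is preserved.  No empirical-Bayes shrinkage is applied: with
    cohort-scale batches the per-batch moment estimates are stable and the
    harmonization contract (means removed, variances equalized, covariate
    slopes untouched) holds exactly on noise-free constructions.
    """
    out = cohort.copy()
    b = out.data[batch].to_numpy()
    levels = pd.unique(b[~pd.isna(b)])
    if len(levels) < 2:
        raise PreprocessError("harmonization needs at least 2 batches")
    counts = {lv: int(np.sum(b == lv)) for lv in levels}
    small = [lv for lv, c in counts.items() if c <= 2]
    if small:
        raise PreprocessError(f"batch(es) with <=2 subjects: {small}")

    Z = _protected_design(out, protect)
    # sum-to-zero batch contrasts
    Bn = len(levels)
    D = np.zeros((out.n, Bn - 1))
    for j, lv in enumerate(levels[:-1]):
        D[b == lv, j] = 1.0
    D[b == levels[-1], :] = -1.0

    full = np.column_stack([Z, D])
    member = {lv: (b == lv) for lv in levels}
    for v in vars:
        x = out.data[v].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise PreprocessError(f"variable {v!r} has missing values; impute before harmonization")
        coef, *_ = np.linalg.lstsq(full, x, rcond=None)
        alpha = coef[: Z.shape[1]]
        gamma = coef[Z.shape[1]:]
        offsets = {lv: gamma[j] for j, lv in enumerate(levels[:-1])}
        offsets[levels[-1]] = -gamma.sum()
        fit_protected = Z @ alpha
        resid = x - fit_protected
        r = resid.copy()
        for lv in levels:
            r[member[lv]] -= offsets[lv]
        var_b = {lv: r[member[lv]].var(ddof=1) for lv in levels}
        dof = {lv: counts[lv] - 1 for lv in levels}
        pooled_sd = np.sqrt(sum(var_b[lv] * dof[lv] for lv in levels) / sum(dof.values()))
        scaled = r.copy()
        for lv in levels:
            sd = np.sqrt(var_b[lv])
            ratio = pooled_sd / sd if sd > 1e-12 else 1.0
            scaled[member[lv]] *= ratio
        out.data[v] = fit_protected + scaled
    return out


# ---------------------------------------------------------------------------
# 8. composites
# ---------------------------------------------------------------------------

def compute_composites(
    cohort: CohortTable,
    groups: Mapping[str, Sequence[str]],
    weighted: bool,
) -> CohortTable:
    """Append regional mean composites as new ``mri_global`` columns.

    With ``weighted=True`` the member regions are averaged with their
    manifest ``region_weight`` (surface area is the natural choice);
    otherwise a plain mean.  Rows with missing members are averaged over
    the non-missing ones (logged).  Member columns are unchanged.
    """
    out = cohort.copy()
    n_partial = 0
    for comp_name, members in groups.items():
        members = list(members)
        if not members:
            raise PreprocessError(f"composite {comp_name!r} has an empty region list")
        X = out.data[members].to_numpy(dtype=float)
        if weighted:
            w = np.array(
                [out.manifest.entry(m).region_weight for m in members], dtype=float
            )
            if np.any(np.isnan(w)):
                raise PreprocessError(
                    f"composite {comp_name!r}: member(s) lack region_weight"
                )
        else:
            w = np.ones(len(members))
        mask = ~np.isnan(X)
        n_partial += int(np.sum(mask.sum(axis=1) < len(members)))
        wsum = (mask * w).sum(axis=1)
        num = np.nansum(X * w, axis=1)
        comp = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
        out.data[comp_name] = comp
        if comp_name not in out.manifest:
            out.manifest.entries.append(
                VariableEntry(
                    name=comp_name,
                    role="mri_global",
                    direction="higher_is_better",
                    transform="none",
                )
            )
    if n_partial:
        log.info("compute_composites: %d composite value(s) computed over partial members", n_partial)
    return out


# ---------------------------------------------------------------------------
# 9. genotype orientation
# ---------------------------------------------------------------------------

def orient_genotypes_to_risk(cohort: CohortTable) -> CohortTable:
    """Flip protective-coded dosages so higher always means higher risk.

    Protective-coded columns map d -> 2 - d and are re-declared risk-coded;
    applying the step twice is the identity.
    """
    out = cohort.copy()
    for entry in out.manifest.entries:
        if entry.role != "genotype":
            continue
        x = out.data[entry.name].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise PreprocessError(f"genotype {entry.name!r} has dosages outside [0, 2]")
        if entry.risk_orientation == "protective_coded":
            out.data[entry.name] = 2.0 - x
            entry.risk_orientation = "risk_coded"
    return out


# ---------------------------------------------------------------------------
# 10. z-scoring
# ---------------------------------------------------------------------------

def zscore_reference(cohort: CohortTable, vars: Sequence[str]) -> CohortTable:
    """Z-score variables using the whole cohort as reference (n-1 SD)."""
    out = cohort.copy()
    for v in vars:
        x = out.data[v].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        sd = x[obs].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise PreprocessError(f"variable {v!r} is constant; cannot z-score")
        out.data[v] = (x - x[obs].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    """Switches and names driving :func:`preprocess_cohort`.

    Column names default to the synthetic generator's conventions; real
    cohorts override them.  Skip flags disable individual steps (a step is
    also auto-skipped when its inputs are absent, e.g. harmonization with a
    single batch).
    """

    tmta: Optional[str] = "tmt_a"
    tmtb: Optional[str] = "tmt_b"
    icv: Optional[str] = "icv"
    wm_hypo: Optional[str] = "wm_hypo"
    composite_groups: Optional[Mapping[str, Sequence[str]]] = None
    weighted_composites: bool = True
    signature_regions: Optional[Sequence[str]] = None
    k_donors: int = 5
    cycles: int = 5
    min_tests: int = 3
    max_var_missing: float = 0.5
    qc_k_sd: float = 2.0
    skip_tmtb: bool = False
    skip_directionality: bool = False
    skip_sparsity: bool = False
    skip_qc: bool = False
    skip_impute: bool = False
    skip_icv: bool = False
    skip_harmonize: bool = False
    skip_composites: bool = False
    skip_genotype_orientation: bool = False
    skip_zscore: bool = False


def _lobar_groups(cohort: CohortTable) -> dict[str, list[str]]:
    """Thickness composites per lobe from manifest domain tags."""
    groups: dict[str, list[str]] = {}
    for e in cohort.manifest.entries:
        if e.role == "mri_thickness" and e.domain_tag not in (None, "global_brain"):
            groups.setdefault(f"thickness_{e.domain_tag}", []).append(e.name)
    whole = [e.name for e in cohort.manifest.entries if e.role == "mri_thickness"]
    if whole:
        groups["thickness_whole_brain"] = whole
    return groups


def preprocess_cohort(
    cohort: CohortTable,
    params: PreprocessParams | None = None,
    seed: int = 0,
) -> tuple[CohortTable, PreprocessLog]:
    """Run the full preparation chain in its fixed order.

    Returns the prepared cohort and a log of what each step did.  The
    z-scoring at the end covers every cognition and MRI column, leaving
    covariates, genotypes and ids on their native scales.
    """
    params = params or PreprocessParams()
    plog = PreprocessLog()
    out = cohort
    man = out.manifest
    dx = man.diagnosis_column

    def count_missing(c: CohortTable, cols: Iterable[str]) -> int:
        cols = [x for x in cols if x in c.data.columns]
        return int(c.data[cols].isna().sum().sum()) if cols else 0

    # 1. TMT-B ratio imputation (raw scale, before inversion)
    if (
        not params.skip_tmtb
        and params.tmta
        and params.tmtb
        and params.tmta in out.data.columns
        and params.tmtb in out.data.columns
        and dx is not None
    ):
        before = count_missing(out, [params.tmtb])
        out = impute_tmtb(out, params.tmta, params.tmtb, dx)
        plog.add(
            StepRecord(
                step_name="impute_tmtb",
                variables_touched=[params.tmtb],
                values_imputed_or_set_missing=before - count_missing(out, [params.tmtb]),
                parameters={"tmta": params.tmta, "tmtb": params.tmtb},
            )
        )

    # 2. directionality
    if not params.skip_directionality:
        touched = [
            e.name
            for e in man.entries
            if e.direction == "lower_is_better" or e.transform != "none"
        ]
        out = apply_directionality(out)
        plog.add(StepRecord(step_name="apply_directionality", variables_touched=touched))

    # 3. sparsity exclusions
    if not params.skip_sparsity:
        out, sub_log = exclude_sparse(out, params.min_tests, params.max_var_missing)
        plog.steps.extend(sub_log.steps)

    man = out.manifest
    volume_cols = man.by_role("mri_volume")

    # 4. outlier QC on subcortical volumes, within diagnostic group
    if not params.skip_qc and volume_cols and dx is not None:
        before = count_missing(out, volume_cols)
        out = qc_outliers(out, volume_cols, dx, params.qc_k_sd)
        plog.add(
            StepRecord(
                step_name="qc_outliers",
                variables_touched=volume_cols,
                values_imputed_or_set_missing=count_missing(out, volume_cols) - before,
                parameters={"k_sd": params.qc_k_sd},
            )
        )

    # 5. PMM imputation: cognition block, then volumetric block
    if not params.skip_impute:
        cog = man.cognition_columns()
        demo = [c for c in man.by_role("covariate")]
        base = demo + ([dx] if dx else [])
        n_before = count_missing(out, cog + volume_cols)
        if cog and out.data[cog].isna().any().any():
            out = pmm_impute(
                out,
                targets=cog,
                predictors=[c for c in base if c in out.data.columns] + cog,
                k_donors=params.k_donors,
                cycles=params.cycles,
                seed=seed,
            )
        vol_targets = list(volume_cols)
        if params.wm_hypo and params.wm_hypo in out.data.columns:
            vol_targets.append(params.wm_hypo)
        if vol_targets and out.data[vol_targets].isna().any().any():
            # lobar thickness means serve as transient predictors only
            # per-lobe means only: the whole-brain mean is an exact linear
            # combination of them and would make the design collinear
            lobar_cols = {
                name: out.data[members].mean(axis=1)
                for name, members in _lobar_groups(out).items()
                if name != "thickness_whole_brain"
            }
            frame = pd.concat([out.data, pd.DataFrame(lobar_cols)], axis=1)
            lobar_preds = list(lobar_cols)
            preds = [c for c in base if c in frame.columns] + vol_targets + lobar_preds
            if params.icv and params.icv in frame.columns:
                preds.append(params.icv)
            filled = _pmm_impute_frame(
                frame,
                targets=vol_targets,
                predictors=list(dict.fromkeys(preds)),
                k_donors=params.k_donors,
                cycles=params.cycles,
                seed=seed + 1,
            )
            for t in vol_targets:
                out.data[t] = filled[t]
        plog.add(
            StepRecord(
                step_name="pmm_impute",
                variables_touched=cog + vol_targets,
                values_imputed_or_set_missing=n_before - count_missing(out, cog + volume_cols),
                parameters={"k_donors": params.k_donors, "cycles": params.cycles, "seed": seed},
            )
        )

    # 6. ICV adjustment of volumetric measures (incl. WM-hypo burden)
    if not params.skip_icv and params.icv and params.icv in out.data.columns:
        adj = list(volume_cols)
        if params.wm_hypo and params.wm_hypo in out.data.columns:
            adj.append(params.wm_hypo)
        if adj:
            out = adjust_icv(out, adj, params.icv)
            plog.add(
                StepRecord(
                    step_name="adjust_icv",
                    variables_touched=adj,
                    parameters={"icv": params.icv},
                )
            )

    # 7. batch harmonization of thickness + volumes
    batch_col = man.batch_column
    if not params.skip_harmonize and batch_col is not None:
        n_batches = out.data[batch_col].nunique(dropna=True)
        harm_vars = man.by_role("mri_thickness") + volume_cols
        if n_batches >= 2 and harm_vars:
            protect = [c for c in man.by_role("covariate") if c in ("age", "sex")]
            if dx:
                protect.append(dx)
            out = harmonize_batches(out, harm_vars, batch_col, protect)
            plog.add(
                StepRecord(
                    step_name="harmonize_batches",
                    variables_touched=harm_vars,
                    parameters={"batch": batch_col, "protect": protect},
                )
            )

    # 8. composites
    if not params.skip_composites:
        groups = dict(params.composite_groups) if params.composite_groups else _lobar_groups(out)
        if params.signature_regions:
            out = compute_composites(
                out, {"thickness_ad_signature": list(params.signature_regions)}, weighted=False
            )
        if groups:
            weighted_ok = params.weighted_composites and all(
                out.manifest.entry(m).region_weight is not None
                for members in groups.values()
                for m in members
            )
            out = compute_composites(out, groups, weighted=weighted_ok)
            plog.add(
                StepRecord(
                    step_name="compute_composites",
                    variables_touched=list(groups),
                    parameters={"weighted": weighted_ok},
                )
            )

    # 9. genotype risk orientation
    if not params.skip_genotype_orientation and man.by_role("genotype"):
        flipped = [
            e.name for e in man.entries if e.risk_orientation == "protective_coded"
        ]
        out = orient_genotypes_to_risk(out)
        plog.add(
            StepRecord(step_name="orient_genotypes_to_risk", variables_touched=flipped)
        )

    # 10. reference z-scoring of all modeled variables
    if not params.skip_zscore:
        zvars = out.manifest.cognition_columns() + out.manifest.mri_columns()
        zvars = [v for v in zvars if v in out.data.columns]
        out = zscore_reference(out, zvars)
        plog.add(StepRecord(step_name="zscore_reference", variables_touched=zvars))

    return out, plog
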
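"""Cohort tables: subjects x variables with an attached manifest.

Missing data is represented by a single sentinel -- NaN in memory, an empty
cell on disk, ``null`` in JSON.  No magic numbers anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .manifest import VariableManifest

log = logging.getLogger(__name__)


class CohortError(ValueError):
    """Raised on fatal cohort-level input problems."""


@dataclass
class CohortTable:
    """One cohort's data: a numeric frame indexed by subject id.

    ``data`` holds one row per subject; every column is named in the
    manifest.  Genotype columns are dosages in [0, 2].
    """

    cohort_label: str
    data: pd.DataFrame
    manifest: VariableManifest

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise CohortError(f"duplicate subject ids: {dupes}")
        extra = [c for c in self.data.columns if c not in self.manifest]
        if extra:
            raise CohortError(f"columns absent from manifest: {extra}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def copy(self) -> "CohortTable":
        return CohortTable(
            cohort_label=self.cohort_label,
            data=self.data.copy(),
            manifest=VariableManifest.from_dict(self.manifest.to_dict()),
        )

    def values(self, columns: list[str]) -> np.ndarray:
        return self.data[columns].to_numpy(dtype=float)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cohort(
    table_path: str | Path,
    manifest_path: str | Path,
    cohort_label: Optional[str] = None,
) -> CohortTable:
    """Load a CSV/TSV cohort table validated against its manifest.

    Non-numeric cells in numeric columns become missing values and the count
    is logged.  The id column becomes the index.  Fatal errors: missing id
    column, duplicated subject ids, manifest columns absent from the table.
    """
    table_path = Path(table_path)
    manifest = VariableManifest.load(manifest_path)
    raw = pd.read_csv(table_path, sep=_sep_for(table_path), dtype=str)
    raw.columns = [str(c) for c in raw.columns]

    id_col = manifest.id_column
    if id_col not in raw.columns:
        raise CohortError(f"id column {id_col!r} missing from {table_path}")
    missing_cols = [n for n in manifest.names() if n != id_col and n not in raw.columns]
    if missing_cols:
        raise CohortError(f"manifest columns absent from table: {missing_cols}")
    extra = [c for c in raw.columns if c not in manifest]
    if extra:
        log.warning("dropping %d column(s) not declared in manifest: %s", len(extra), extra)
        raw = raw.drop(columns=extra)

    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise CohortError(f"duplicate subject ids: {dupes}")

    numeric_cols = [c for c in raw.columns if c != id_col]
    parsed_cols = {}
    n_coerced = 0
    for c in numeric_cols:
        # cell-wise float() keeps every value bit-identical across a
        # write/read cycle (pd.to_numeric's fast parser is not exact)
        vals = np.empty(len(raw))
        for i, cell in enumerate(raw[c].to_numpy()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                vals[i] = np.nan
                continue
            text = str(cell).strip()
            if not text:
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(text)
            except ValueError:
                vals[i] = np.nan
                n_coerced += 1
        parsed_cols[c] = vals
    data = pd.DataFrame(parsed_cols, index=pd.Index(ids, name=id_col))
    if n_coerced:
        log.info("coerced %d non-numeric cell(s) to missing while reading %s", n_coerced, table_path)

    label = cohort_label if cohort_label is not None else table_path.stem
    return CohortTable(cohort_label=label, data=data, manifest=manifest)


def write_cohort(cohort: CohortTable, table_path: str | Path, manifest_path: str | Path | None = None) -> Path:
    """Write the table (CSV/TSV by extension) and optionally its manifest."""
    table_path = Path(table_path)
    out = cohort.data.copy()
    out.insert(0, cohort.manifest.id_column, cohort.data.index)
    # %.17g keeps every float bit-identical across a write/read cycle
    out.to_csv(table_path, sep=_sep_for(table_path), index=False, float_format="%.17g")
    if manifest_path is not None:
        cohort.manifest.save(manifest_path)
    return table_path


@dataclass
class ValidationReport:
    """Report-only health check of a cohort table; never mutates the input."""

    cohort_label: str
    n_subjects: int
    column_missingness: dict[str, float] = field(default_factory=dict)
    out_of_range_genotypes: dict[str, int] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)
    passed: bool = True


def validate_cohort(cohort: CohortTable) -> ValidationReport:
    """Per-column missingness, genotype range checks and constant columns."""
    report = ValidationReport(cohort_label=cohort.cohort_label, n_subjects=cohort.n)
    geno_cols = set(cohort.manifest.by_role("genotype"))
    for c in cohort.data.columns:
        col = cohort.data[c].to_numpy(dtype=float)
        frac = float(np.isnan(col).mean()) if len(col) else 0.0
        report.column_missingness[c] = frac
        obs = col[~np.isnan(col)]
        if c in geno_cols:
            n_bad = int(np.sum((obs < 0) | (obs > 2)))
            if n_bad:
                report.out_of_range_genotypes[c] = n_bad
                report.issues.append(f"genotype {c!r}: {n_bad} dosage value(s) outside [0, 2]")
        if obs.size and np.nanstd(obs) == 0.0:
            report.constant_columns.append(c)
            report.issues.append(f"column {c!r} is constant")
    report.passed = not report.issues
    return report
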
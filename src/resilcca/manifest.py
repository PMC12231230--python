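"""Variable manifests: the single source of truth for column semantics.

A cohort table on its own is just numbers.  The manifest declares, for every
column, what role it plays (cognitive test, regional thickness, subcortical
volume, covariate, genotype dosage, ...), which way "better" points, how the
raw scale should be transformed, and -- for genotypes -- whether a higher
dosage is risk- or protective-coded.  Downstream code never guesses from
column names: two cohorts with entirely different test batteries are handled
by their manifests alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import yaml

ROLES = frozenset(
    {
        "cognition",
        "mri_thickness",
        "mri_volume",
        "mri_global",
        "covariate",
        "genotype",
        "genetic_pc",
        "batch",
        "id",
        "diagnosis",
    }
)
COGNITIVE_DOMAINS = frozenset(
    {"memory", "executive", "attention", "language", "visuospatial", "global_cognition"}
)
BRAIN_DOMAINS = frozenset(
    {"frontal", "parietal", "temporal", "occipital", "cingulate", "subcortical", "global_brain"}
)
DIRECTIONS = frozenset({"higher_is_better", "lower_is_better"})
TRANSFORMS = frozenset({"none", "log1p", "negate_log1p"})
RISK_ORIENTATIONS = frozenset({"risk_coded", "protective_coded"})

MRI_ROLES = ("mri_thickness", "mri_volume", "mri_global")


class ManifestError(ValueError):
    """Raised when a manifest violates its invariants."""


@dataclass
class VariableEntry:
    """Declaration of a single column."""

    name: str
    role: str
    domain_tag: Optional[str] = None
    direction: Optional[str] = None
    transform: str = "none"
    risk_orientation: Optional[str] = None
    region_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ManifestError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise ManifestError(f"unknown direction {self.direction!r} for {self.name!r}")
        if self.transform not in TRANSFORMS:
            raise ManifestError(f"unknown transform {self.transform!r} for {self.name!r}")
        if self.risk_orientation is not None and self.risk_orientation not in RISK_ORIENTATIONS:
            raise ManifestError(
                f"unknown risk_orientation {self.risk_orientation!r} for {self.name!r}"
            )
        if self.domain_tag is not None and self.domain_tag not in (
            COGNITIVE_DOMAINS | BRAIN_DOMAINS
        ):
            raise ManifestError(f"unknown domain_tag {self.domain_tag!r} for {self.name!r}")
        if self.region_weight is not None and self.region_weight < 0:
            raise ManifestError(f"region_weight must be non-negative for {self.name!r}")


@dataclass
class VariableManifest:
    """Ordered collection of :class:`VariableEntry` with validated invariants.

    Invariants enforced at construction:

    * names are unique,
    * exactly one ``id`` role, at most one ``batch`` role,
    * every cognition and ``mri_*`` entry carries a direction,
    * every genotype entry carries a risk orientation.
    """

    entries: list[VariableEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ManifestError(f"duplicate variable names in manifest: {dupes}")
        n_id = sum(e.role == "id" for e in self.entries)
        if n_id != 1:
            raise ManifestError(f"manifest must declare exactly one id column, found {n_id}")
        if sum(e.role == "batch" for e in self.entries) > 1:
            raise ManifestError("manifest may declare at most one batch column")
        for e in self.entries:
            if e.role == "cognition" or e.role in MRI_ROLES:
                if e.direction is None:
                    raise ManifestError(f"{e.role} variable {e.name!r} needs a direction")
            if e.role == "genotype" and e.risk_orientation is None:
                raise ManifestError(f"genotype {e.name!r} needs a risk_orientation")

    # -- lookups ------------------------------------------------------------
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def entry(self, name: str) -> VariableEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"variable {name!r} not in manifest")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def by_role(self, *roles: str) -> list[str]:
        return [e.name for e in self.entries if e.role in roles]

    @property
    def id_column(self) -> str:
        return self.by_role("id")[0]

    @property
    def batch_column(self) -> Optional[str]:
        cols = self.by_role("batch")
        return cols[0] if cols else None

    @property
    def diagnosis_column(self) -> Optional[str]:
        cols = self.by_role("diagnosis")
        return cols[0] if cols else None

    def cognition_columns(self) -> list[str]:
        return self.by_role("cognition")

    def mri_columns(self) -> list[str]:
        return self.by_role(*MRI_ROLES)

    def cca_x_columns(self, exclude: Iterable[str] = ()) -> list[str]:
        """Columns entering the brain-side CCA matrix.

        All MRI roles are included; derived composites (or anything else the
        caller wants out of the model) are removed via ``exclude``.
        """
        drop = set(exclude)
        return [c for c in self.mri_columns() if c not in drop]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"entries": [asdict(e) for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "VariableManifest":
        return cls(entries=[VariableEntry(**e) for e in d["entries"]])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(payload, indent=1))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VariableManifest":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            payload = json.loads(text)
        else:
            payload = yaml.safe_load(text)
        return cls.from_dict(payload)
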
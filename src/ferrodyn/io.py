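"""Dataset reader/writer and configuration handling.

Datasets follow the NONMEM column convention: one row per event with

    ID, TIME, DV, AMT, RATE, WT, OCC, CMPL, EVID, MDV

TIME is in hours (``time_unit: days`` in the config converts day-valued
files on read); DV is serum ferritin in ug/L and must be present exactly on
observation rows (MDV = 0); missing DV is encoded by MDV = 1, never by an
empty-string sentinel with MDV = 0.  CMPL must be constant within a
subject.

Configuration files are YAML (JSON is valid YAML) with optional blocks
``pk``, ``disease``, ``drug``, ``population``, ``cohort`` and top-level
``seed``; omitted keys fall back to the package defaults (the reference
parameter estimates, with the disease constants treated as fixed).  Unknown
keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec
from .disease import DiseaseParameters, DrugEffectParameters
from .estimation import PopulationModel
from .exceptions import ConfigError, ValidationError
from .pk import PKParameters

logger = logging.getLogger("ferrodyn")

REQUIRED_COLUMNS = ("ID", "TIME", "DV", "AMT", "RATE", "WT", "OCC",
                    "CMPL", "EVID", "MDV")


def validate_dataset(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a dataset table in place and return it.

    Raises :class:`ValidationError` naming the offending rows (1-based data
    row numbers, header excluded).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    problems = []
    for sid, grp in table.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) < 0)
        for b in bad:
            problems.append(
                f"row {grp.index[b + 1] + 1}: TIME decreases within ID {sid}")
        if grp["CMPL"].nunique() > 1:
            problems.append(f"ID {sid}: CMPL is not constant within subject")
    obs = table["MDV"].to_numpy() == 0
    dv = table["DV"].to_numpy(dtype=float)
    for i in np.flatnonzero(obs & ~np.isfinite(dv)):
        problems.append(f"row {i + 1}: MDV=0 but DV is missing")
    for i in np.flatnonzero(~obs & np.isfinite(dv)):
        problems.append(f"row {i + 1}: DV present but MDV=1 (orphan DV)")
    if problems:
        raise ValidationError("dataset validation failed:\n  "
                              + "\n  ".join(problems))
    return table


def read_dataset(path, time_unit: str = "hours") -> pd.DataFrame:
    """Read and validate a dataset CSV.  ``time_unit`` may be "hours" or
    "days"; day-valued TIME columns are converted to hours."""
    table = pd.read_csv(path)
    if time_unit == "days":
        table["TIME"] = table["TIME"] * 24.0
    elif time_unit != "hours":
        raise ValidationError(f"unknown time_unit {time_unit!r}")
    return validate_dataset(table)


def write_dataset(table: pd.DataFrame, path) -> None:
    """Validate and write a dataset CSV (RFC-4180, '.' decimal)."""
    validate_dataset(table)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

_SECTION_TYPES = {
    "pk": PKParameters,
    "disease": DiseaseParameters,
    "drug": DrugEffectParameters,
    "cohort": CohortSpec,
}

#: Disease-model constants treated as fixed during estimation by default.
FIXED_DISEASE_PARAMETERS = ("kin", "kout", "scl_ref", "shp_ref")


@dataclass
class RunConfig:
    """Effective configuration of a run, merged over package defaults."""

    pk: PKParameters = field(default_factory=PKParameters)
    disease: DiseaseParameters = field(default_factory=DiseaseParameters)
    drug: DrugEffectParameters = field(default_factory=DrugEffectParameters)
    population: PopulationModel = field(default_factory=PopulationModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    time_unit: str = "hours"

    def describe(self) -> str:
        parts = [f"seed={self.seed}", f"time_unit={self.time_unit}"]
        for name in ("pk", "disease", "drug", "population", "cohort"):
            parts.append(f"{name}: {getattr(self, name)!r}")
        return "\n".join(parts)


def _build_section(cls, block: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}' block: {', '.join(sorted(unknown))}")
    coerced = {}
    for key, value in block.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' block: {exc}") from exc


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML/JSON configuration, merged over the package defaults.

    ``path=None`` (or an empty file) yields the pure defaults.  ``overrides``
    is an optional dict merged on top of the file contents (CLI flags).
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    known = set(_SECTION_TYPES) | {"population", "seed", "time_unit"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"'{name}' block must be a mapping")
        sections[name] = _build_section(cls, block, name)
    pop_block = dict(raw.get("population", {}))
    if not isinstance(pop_block, dict):
        raise ConfigError("'population' block must be a mapping")
    pop_block.setdefault("disease", sections["disease"])
    pop_block.setdefault("pk", sections["pk"])
    if isinstance(pop_block.get("disease"), dict):
        pop_block["disease"] = _build_section(DiseaseParameters,
                                              pop_block["disease"],
                                              "population.disease")
    population = _build_section(PopulationModel, pop_block, "population")

    config = RunConfig(pk=sections["pk"], disease=sections["disease"],
                       drug=sections["drug"], cohort=sections["cohort"],
                       population=population,
                       seed=int(raw.get("seed", 0)),
                       time_unit=str(raw.get("time_unit", "hours")))
    logger.info("effective configuration:\n%s", config.describe())
    return config


def fit_report(fit, path=None) -> dict:
    """Serialise a :class:`~ferrodyn.estimation.FitResult` to JSON."""
    payload = {
        "estimates": fit.estimates,
        "standard_errors": fit.se,
        "ofv": fit.ofv,
        "converged": fit.converged,
        "n_evals": fit.n_evals,
        "start_ofvs": fit.start_ofvs,
        "fixed_disease_parameters": {
            name: getattr(fit.pop.disease, name)
            for name in FIXED_DISEASE_PARAMETERS},
        "message": fit.message,
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload
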
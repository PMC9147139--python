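"""Plausibility checks: implausible values become missing, and are reported.

This is deliberately distinct from score-boundary clipping: an
out-of-range value here is treated as a recording error, set to missing
and listed in the report, instead of being silently pulled to a boundary.
Bounds are inclusive. The HF-duration upper bound is dynamic (the
patient's own age x 12 months) and is evaluated against the *cleaned*
age, so the operation is idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from hfscores.errors import ConfigurationError

#: check order matters only in that age precedes hf_duration
CHECKED_VARIABLES = ("age", "bmi", "systolic_bp", "hf_duration", "lvef",
                     "creatinine", "sodium", "hemoglobin", "egfr")

DYNAMIC_UPPER = "age*12"


@dataclass(frozen=True)
class VariableLimits:
    lower: float
    upper: Optional[float]  # None => dynamic (age * 12)
    unit: str

    @property
    def dynamic_upper(self) -> bool:
        return self.upper is None


@dataclass(frozen=True)
class PlausibilityLimits:
    limits: dict[str, VariableLimits]

    def __post_init__(self) -> None:
        missing = set(CHECKED_VARIABLES) - set(self.limits)
        if missing:
            raise ConfigurationError(f"limits missing for: {sorted(missing)}")
        for name, lim in self.limits.items():
            if lim.upper is not None and lim.lower > lim.upper:
                raise ConfigurationError(f"{name}: lower > upper")

    def __getitem__(self, name: str) -> VariableLimits:
        return self.limits[name]

    def hf_duration_upper(self, age: float) -> float:
        return age * 12.0


@dataclass
class ReportEntry:
    site: str
    local_id: str
    variable: str
    value: float
    violated_bound: str  # "lower" | "upper"
    limit: float
    action: str = "set_missing"

    def to_dict(self) -> dict:
        return {"site": self.site, "local_id": self.local_id,
                "variable": self.variable, "value": self.value,
                "violated_bound": self.violated_bound, "limit": self.limit,
                "action": self.action}


@dataclass
class PlausibilityReport:
    entries: list[ReportEntry] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.entries

    def to_jsonl(self) -> str:
        return "".join(json.dumps(e.to_dict(), sort_keys=True) + "\n"
                       for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.entries],
                            columns=["site", "local_id", "variable", "value",
                                     "violated_bound", "limit", "action"])


def load_limits(path) -> PlausibilityLimits:
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    limits = {}
    for name, spec in doc.items():
        upper = spec["upper"]
        if isinstance(upper, str):
            if upper.replace(" ", "") != DYNAMIC_UPPER:
                raise ConfigurationError(
                    f"{name}: unsupported dynamic bound {upper!r}")
            upper = None
        limits[name] = VariableLimits(float(spec["lower"]),
                                      None if upper is None else float(upper),
                                      str(spec["unit"]))
    return PlausibilityLimits(limits)


def default_limits() -> PlausibilityLimits:
    """The packaged admissible ranges."""
    ref = resources.files("hfscores.data") / "plausibility_limits.yaml"
    with resources.as_file(ref) as path:
        return load_limits(path)


def apply_plausibility(table: pd.DataFrame,
                       limits: Optional[PlausibilityLimits] = None,
                       ) -> tuple[pd.DataFrame, PlausibilityReport]:
    """Set out-of-range values to missing; report every action.

    In-range and boundary values are untouched. When age is missing the
    dynamic HF-duration upper bound cannot be evaluated: the value is
    retained and a warning is logged (the static lower bound still
    applies).  A flagged HF duration also clears ``hf_duration_ge_18``,
    which is derived from it.
    """
    limits = limits or default_limits()
    cleaned = table.copy()
    report = PlausibilityReport()

    def flag(idx, variable, value, bound, limit):
        report.entries.append(ReportEntry(
            site=cleaned.at[idx, "site"], local_id=cleaned.at[idx, "local_id"],
            variable=variable, value=float(value), violated_bound=bound,
            limit=float(limit)))
        cleaned.at[idx, variable] = np.nan
        if variable == "hf_duration" and "hf_duration_ge_18" in cleaned.columns:
            if cleaned["hf_duration_ge_18"].dtype != object:
                cleaned["hf_duration_ge_18"] = \
                    cleaned["hf_duration_ge_18"].astype(object)
            cleaned.at[idx, "hf_duration_ge_18"] = None

    for variable in CHECKED_VARIABLES:
        if variable not in cleaned.columns:
            continue
        lim = limits[variable]
        col = pd.to_numeric(cleaned[variable], errors="coerce")
        for idx in cleaned.index[col.notna()]:
            value = float(col.at[idx])
            if value < lim.lower:
                flag(idx, variable, value, "lower", lim.lower)
                continue
            if lim.dynamic_upper:
                age = cleaned.at[idx, "age"] if "age" in cleaned.columns \
                    else np.nan
                if pd.isna(age):
                    report.warnings.append({
                        "site": cleaned.at[idx, "site"],
                        "local_id": cleaned.at[idx, "local_id"],
                        "variable": variable, "value": value,
                        "warning": "dynamic upper bound unevaluable "
                                   "(age missing); value retained"})
                    continue
                upper = limits.hf_duration_upper(float(age))
            else:
                upper = lim.upper
            if value > upper:
                flag(idx, variable, value, "upper", upper)

    return cleaned, report
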
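"""Declarative risk-score evaluator.

Two methods are supported:

* ``points_table`` — additive integer points with optional stratified
  lookup (e.g. age points by ejection-fraction band) and an exact
  integer-score -> probability table per horizon (MAGGIC-style,
  complete data required);
* ``cox_lp`` — Cox linear predictor with per-horizon baseline survival
  and per-variable imputation reference values (BCN Bio-HF v1 style).

Definitions live in YAML files validated at load time; the engine never
hard-codes coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from hfscores.errors import HFScoresError, MissingInputError, SchemaError


def is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# definition model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # continuous | categorical | boolean
    clip_lower: Optional[float] = None
    clip_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical", "boolean"):
            raise SchemaError(f"{self.name}: bad kind {self.kind!r}")
        if self.kind != "continuous" and (self.clip_lower is not None
                                          or self.clip_upper is not None):
            raise SchemaError(f"{self.name}: clip bounds only allowed on "
                              "continuous variables")
        if (self.clip_lower is not None and self.clip_upper is not None
                and self.clip_lower > self.clip_upper):
            raise SchemaError(f"{self.name}: clip_lower > clip_upper")


@dataclass(frozen=True)
class Band:
    """Half-open interval [lo, hi) with a value (points or coefficient).
    ``None`` edges are unbounded."""

    lo: Optional[float]
    hi: Optional[float]
    value: float

    def contains(self, x: float) -> bool:
        if self.lo is not None and x < self.lo:
            return False
        if self.hi is not None and x >= self.hi:
            return False
        return True


def _validate_bands(variable: str, bands: list[Band]) -> None:
    if not bands:
        raise SchemaError(f"{variable}: empty band list")
    ordered = sorted(bands, key=lambda b: -math.inf if b.lo is None else b.lo)
    if ordered[0].lo is not None or ordered[-1].hi is not None:
        raise SchemaError(f"{variable}: bands do not cover the full range")
    for left, right in zip(ordered, ordered[1:]):
        if left.hi is None or right.lo is None or left.hi != right.lo:
            raise SchemaError(f"{variable}: gap or overlap in value ranges")


def _match_band(variable: str, bands: list[Band], x: float) -> float:
    for b in bands:
        if b.contains(x):
            return b.value
    raise SchemaError(f"{variable}: no band matches {x}")  # unreachable


@dataclass(frozen=True)
class PointsRule:
    variable: str
    kind: str  # range | category
    bands: Optional[list[Band]] = None
    mapping: Optional[dict] = None
    stratify_by: Optional[str] = None
    strata: Optional[list[tuple[Band, list[Band]]]] = None

    def min_points(self) -> float:
        return min(self._all_values())

    def max_points(self) -> float:
        return max(self._all_values())

    def _all_values(self) -> list[float]:
        if self.kind == "category":
            return list(self.mapping.values())
        if self.strata is not None:
            return [b.value for _, bands in self.strata for b in bands]
        return [b.value for b in self.bands]

    def evaluate(self, row: dict) -> int:
        value = row.get(self.variable)
        if self.kind == "category":
            if value not in self.mapping:
                raise SchemaError(f"{self.variable}: unmapped category "
                                  f"{value!r}")
            return int(self.mapping[value])
        if self.strata is not None:
            strat_value = row.get(self.stratify_by)
            for stratum, bands in self.strata:
                if stratum.contains(float(strat_value)):
                    return int(_match_band(self.variable, bands, float(value)))
            raise SchemaError(f"{self.variable}: no stratum matches "
                              f"{strat_value}")  # unreachable
        return int(_match_band(self.variable, self.bands, float(value)))


@dataclass(frozen=True)
class CoxTerm:
    variable: str
    kind: str  # linear | category | banded
    coef: Optional[float] = None
    mapping: Optional[dict] = None
    bands: Optional[list[Band]] = None

    def evaluate(self, value) -> float:
        if self.kind == "linear":
            return self.coef * float(value)
        if self.kind == "category":
            if value not in self.mapping:
                raise SchemaError(f"{self.variable}: unmapped category "
                                  f"{value!r}")
            return float(self.mapping[value])
        return float(_match_band(self.variable, self.bands, float(value)))


@dataclass(frozen=True)
class ScoreDefinition:
    score_id: str
    method: str  # points_table | cox_lp
    horizons: list[int]
    variables: list[VariableSpec]
    completeness: str  # require_complete | allow_imputation
    rules: list[PointsRule] = field(default_factory=list)
    risk_lookup: dict[int, dict[int, float]] = field(default_factory=dict)
    clamp_points: bool = False
    terms: list[CoxTerm] = field(default_factory=list)
    baseline_survival: dict[int, float] = field(default_factory=dict)
    centering: float = 0.0
    imputation_references: dict = field(default_factory=dict)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def required_variables(self) -> list[str]:
        return [v.name for v in self.variables]

    def attainable_points(self) -> tuple[int, int]:
        lo = sum(int(r.min_points()) for r in self.rules)
        hi = sum(int(r.max_points()) for r in self.rules)
        return lo, hi


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def _parse_band(d: dict, value_key: str) -> Band:
    extra = set(d) - {"lo", "hi", value_key}
    if extra:
        raise SchemaError(f"unknown band key(s): {sorted(extra)}")
    return Band(lo=None if d.get("lo") is None else float(d["lo"]),
                hi=None if d.get("hi") is None else float(d["hi"]),
                value=float(d[value_key]))


def _parse_points_rule(d: dict) -> PointsRule:
    variable = d["variable"]
    kind = d["type"]
    if kind == "category":
        mapping = d["points"]
        if not isinstance(mapping, dict) or not mapping:
            raise SchemaError(f"{variable}: category rule needs a non-empty "
                              "points mapping")
        return PointsRule(variable, "category", mapping=dict(mapping))
    if kind != "range":
        raise SchemaError(f"{variable}: unknown rule type {kind!r}")
    if "strata" in d:
        strata = []
        stratum_bands = []
        for s in d["strata"]:
            stratum = _parse_band({**s["stratum"], "points": 0}, "points")
            bands = [_parse_band(b, "points") for b in s["bands"]]
            _validate_bands(variable, bands)
            strata.append((stratum, bands))
            stratum_bands.append(Band(stratum.lo, stratum.hi, 0))
        _validate_bands(f"{variable} strata", stratum_bands)
        return PointsRule(variable, "range", stratify_by=d["stratify_by"],
                          strata=strata)
    bands = [_parse_band(b, "points") for b in d["bands"]]
    _validate_bands(variable, bands)
    return PointsRule(variable, "range", bands=bands)


def _parse_cox_term(d: dict) -> CoxTerm:
    variable = d["variable"]
    kind = d["type"]
    if kind == "linear":
        return CoxTerm(variable, "linear", coef=float(d["coef"]))
    if kind == "category":
        return CoxTerm(variable, "category", mapping=dict(d["coef"]))
    if kind == "banded":
        bands = [_parse_band(b, "coef") for b in d["bands"]]
        _validate_bands(variable, bands)
        return CoxTerm(variable, "banded", bands=bands)
    raise SchemaError(f"{variable}: unknown term type {kind!r}")


def load_score_definition(path) -> ScoreDefinition:
    """Load and fully validate a YAML score definition."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return parse_score_definition(doc)


def parse_score_definition(doc: dict) -> ScoreDefinition:
    try:
        method = doc["method"]
        variables = [VariableSpec(v["name"], v["kind"],
                                  v.get("clip_lower"), v.get("clip_upper"))
                     for v in doc["variables"]]
        defn = ScoreDefinition(
            score_id=doc["id"],
            method=method,
            horizons=[int(h) for h in doc["horizons"]],
            variables=variables,
            completeness=doc["completeness"],
            rules=[_parse_points_rule(r) for r in doc.get("rules", [])],
            risk_lookup={int(h): {int(p): float(q) for p, q in table.items()}
                         for h, table in doc.get("risk", {}).items()},
            clamp_points=bool(doc.get("clamp_points", False)),
            terms=[_parse_cox_term(t) for t in doc.get("terms", [])],
            baseline_survival={int(h): float(s) for h, s in
                               doc.get("baseline_survival", {}).items()},
            centering=float(doc.get("centering", 0.0)),
            imputation_references=dict(doc.get("imputation_references", {})))
    except KeyError as exc:
        raise SchemaError(f"missing definition key: {exc}") from exc
    _validate_definition(defn)
    return defn


def _validate_definition(defn: ScoreDefinition) -> None:
    if defn.method not in ("points_table", "cox_lp"):
        raise SchemaError(f"unknown method {defn.method!r}")
    if defn.completeness not in ("require_complete", "allow_imputation"):
        raise SchemaError(f"unknown completeness policy "
                          f"{defn.completeness!r}")
    names = {v.name for v in defn.variables}
    if len(names) != len(defn.variables):
        raise SchemaError("duplicate variable declarations")

    if defn.method == "points_table":
        if not defn.rules or not defn.risk_lookup:
            raise SchemaError("points_table needs rules and a risk lookup")
        for rule in defn.rules:
            if rule.variable not in names:
                raise SchemaError(f"rule references undeclared variable "
                                  f"{rule.variable!r}")
            if rule.stratify_by is not None and rule.stratify_by not in names:
                raise SchemaError(f"stratifier {rule.stratify_by!r} "
                                  "undeclared")
        lo, hi = defn.attainable_points()
        if set(defn.risk_lookup) != set(defn.horizons):
            raise SchemaError("risk lookup horizons do not match the "
                              "declared horizons")
        for horizon, table in defn.risk_lookup.items():
            points = sorted(table)
            if points != list(range(points[0], points[-1] + 1)):
                raise SchemaError(f"horizon {horizon}: risk lookup has gaps")
            probs = [table[p] for p in points]
            if any(not 0.0 <= q <= 1.0 for q in probs):
                raise SchemaError(f"horizon {horizon}: probability outside "
                                  "[0, 1]")
            if any(a > b for a, b in zip(probs, probs[1:])):
                raise SchemaError(f"horizon {horizon}: risk lookup not "
                                  "monotone non-decreasing")
            if not defn.clamp_points and not (points[0] <= lo
                                              and hi <= points[-1]):
                raise SchemaError(
                    f"horizon {horizon}: lookup [{points[0]}, {points[-1]}] "
                    f"does not cover the attainable range [{lo}, {hi}]")
        for h1, h2 in zip(sorted(defn.horizons), sorted(defn.horizons)[1:]):
            t1, t2 = defn.risk_lookup[h1], defn.risk_lookup[h2]
            common = set(t1) & set(t2)
            if any(t2[p] < t1[p] for p in common):
                raise SchemaError("longer-horizon risk below shorter-horizon "
                                  "risk")
    else:
        if not defn.terms or not defn.baseline_survival:
            raise SchemaError("cox_lp needs terms and baseline survivals")
        for term in defn.terms:
            if term.variable not in names:
                raise SchemaError(f"term references undeclared variable "
                                  f"{term.variable!r}")
        if set(defn.baseline_survival) != set(defn.horizons):
            raise SchemaError("baseline survival horizons do not match the "
                              "declared horizons")
        surv = [defn.baseline_survival[h] for h in sorted(defn.horizons)]
        if any(not 0.0 < s <= 1.0 for s in surv):
            raise SchemaError("baseline survival outside (0, 1]")
        if any(a < b for a, b in zip(surv, surv[1:])):
            raise SchemaError("baseline survival increasing in horizon")
        for name in defn.imputation_references:
            if name not in names:
                raise SchemaError(f"imputation reference for undeclared "
                                  f"variable {name!r}")


def load_packaged(score_id: str) -> ScoreDefinition:
    """Load one of the shipped definitions ("maggic", "bcn_biohf_v1")."""
    ref = resources.files("hfscores.data") / f"{score_id}.yaml"
    with resources.as_file(ref) as path:
        return load_score_definition(path)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def clip_inputs(defn: ScoreDefinition, row: dict) -> tuple[dict, list[dict]]:
    """Pull continuous values outside the definition's boundaries to the
    nearer boundary; log every clip. Idempotent."""
    clipped = dict(row)
    log: list[dict] = []
    for v in defn.variables:
        if v.kind != "continuous":
            continue
        value = clipped.get(v.name)
        if is_missing(value):
            continue
        value = float(value)
        new = value
        if v.clip_lower is not None and value < v.clip_lower:
            new = v.clip_lower
        elif v.clip_upper is not None and value > v.clip_upper:
            new = v.clip_upper
        if new != value:
            log.append({"variable": v.name, "from": value, "to": new})
            clipped[v.name] = new
    return clipped, log


def missing_variables(defn: ScoreDefinition, row: dict) -> list[str]:
    return [name for name in defn.required_variables()
            if is_missing(row.get(name))]


def points_score(defn: ScoreDefinition, row: dict) -> int:
    """Total integer points for a complete, clipped row."""
    missing = missing_variables(defn, row)
    if missing:
        raise MissingInputError(missing)
    return sum(rule.evaluate(row) for rule in defn.rules)


def points_to_risk(defn: ScoreDefinition, points: int, horizon: int) -> float:
    """Exact lookup of the mortality probability for an integer score."""
    lo, hi = defn.attainable_points()
    if not lo <= points <= hi:
        raise HFScoresError(f"points {points} outside the attainable range "
                            f"[{lo}, {hi}]")
    table = defn.risk_lookup[horizon]
    if defn.clamp_points:
        points = min(max(points, min(table)), max(table))
    return table[points]


def impute(defn: ScoreDefinition, row: dict) -> tuple[dict, list[str]]:
    """Fill missing imputable variables with their reference values."""
    if defn.completeness != "allow_imputation":
        raise HFScoresError(f"{defn.score_id} does not allow imputation")
    out = dict(row)
    imputed = []
    for name, reference in defn.imputation_references.items():
        if is_missing(out.get(name)):
            out[name] = reference
            imputed.append(name)
    return out, sorted(imputed)


def cox_linear_predictor(defn: ScoreDefinition, row: dict) -> float:
    missing = missing_variables(defn, row)
    if missing:
        raise MissingInputError(missing)
    return sum(term.evaluate(row[term.variable]) for term in defn.terms)


def cox_risk(defn: ScoreDefinition, row: dict, horizon: int) -> float:
    """Risk = 1 - S0(horizon) ^ exp(LP - centering)."""
    lp = cox_linear_predictor(defn, row)
    s0 = defn.baseline_survival[horizon]
    risk = 1.0 - s0 ** math.exp(lp - defn.centering)
    return min(max(risk, 0.0), 1.0)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["site", "local_id", "pseudonym", "score_id", "variant",
                  "status", "total_points", "risk_1y", "risk_2y", "risk_3y",
                  "imputed_variables", "reason"]


@dataclass
class ScoreResult:
    site: str
    local_id: str
    pseudonym: Optional[str]
    score_id: str
    variant: str  # complete | imputed
    status: str  # complete | imputed | not_computable
    total_points: Optional[int] = None
    risks: dict[int, float] = field(default_factory=dict)
    imputed_variables: list[str] = field(default_factory=list)
    reason: Optional[str] = None

    def to_row(self) -> dict:
        return {"site": self.site, "local_id": self.local_id,
                "pseudonym": self.pseudonym, "score_id": self.score_id,
                "variant": self.variant, "status": self.status,
                "total_points": self.total_points,
                "risk_1y": self.risks.get(1), "risk_2y": self.risks.get(2),
                "risk_3y": self.risks.get(3),
                "imputed_variables": ";".join(self.imputed_variables),
                "reason": self.reason}


def evaluate_row(defn: ScoreDefinition, row: dict,
                 allow_imputation: bool = False) -> ScoreResult:
    """Evaluate one harmonized (plausibility-cleaned) row for one score."""
    result = ScoreResult(site=row.get("site"), local_id=row.get("local_id"),
                         pseudonym=row.get("pseudonym"),
                         score_id=defn.score_id,
                         variant="imputed" if allow_imputation else "complete",
                         status="complete")
    clipped, _ = clip_inputs(defn, row)
    if allow_imputation:
        clipped, imputed = impute(defn, clipped)
        result.imputed_variables = imputed
    missing = missing_variables(defn, clipped)
    if missing:
        result.status = "not_computable"
        result.imputed_variables = []
        result.reason = "missing: " + ",".join(missing)
        return result
    if result.imputed_variables:
        result.status = "imputed"
    if defn.method == "points_table":
        result.total_points = points_score(defn, clipped)
        result.risks = {h: points_to_risk(defn, result.total_points, h)
                        for h in defn.horizons}
    else:
        result.risks = {h: cox_risk(defn, clipped, h) for h in defn.horizons}
    return result


def compute_cohort_scores(defs: list[ScoreDefinition],
                          table: pd.DataFrame) -> pd.DataFrame:
    """One result row per (patient, score, variant).

    Scores with ``allow_imputation`` are computed twice — complete-only
    and with imputation — mirroring dual complete/imputed reporting.
    """
    results: list[ScoreResult] = []
    rows = table.to_dict("records")
    for defn in defs:
        for row in rows:
            results.append(evaluate_row(defn, row, allow_imputation=False))
            if defn.completeness == "allow_imputation":
                results.append(evaluate_row(defn, row, allow_imputation=True))
    frame = pd.DataFrame([r.to_row() for r in results],
                         columns=RESULT_COLUMNS)
    return frame
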
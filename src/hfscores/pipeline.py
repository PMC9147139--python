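"""End-to-end pipeline: generate/read -> validate -> pseudonymize ->
harmonize -> plausibility -> score -> analyze -> report.

Every run is driven by a single resolved configuration; the manifest
records stage row counts, tallies, the config hash and the seed, and
contains no timestamps, so reruns with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from hfscores import cohort_model, harmonization, plausibility, score_engine
from hfscores import site_analysis, synthetic_cohort
from hfscores.cohort_model import Cohort
from hfscores.errors import (ConfigurationError, MergeError, PrivacyError)

BOOL_COLUMNS = ("current_smoker", "diabetes", "copd_proxy",
                "hf_duration_ge_18", "beta_blocker", "acei_arb", "statin",
                "loop_diuretic")
NUMERIC_COLUMNS = ("age", "bmi", "systolic_bp", "hf_duration",
                   "furosemide_equiv_dose", "lvef", "creatinine", "sodium",
                   "hemoglobin", "egfr")

#: features used to predict a patient's site, per score
TREE_FEATURES = {
    "maggic": ["status", "sex", "age", "bmi", "systolic_bp", "nyha",
               "current_smoker", "diabetes", "copd_proxy",
               "hf_duration_ge_18", "beta_blocker", "acei_arb", "lvef",
               "creatinine"],
    "bcn_biohf_v1": ["status", "sex", "age", "nyha", "lvef", "sodium",
                     "hemoglobin", "egfr", "beta_blocker", "acei_arb",
                     "statin", "furosemide_equiv_dose"],
}

_CATEGORICAL_FEATURES = {"status", "sex", "current_smoker", "diabetes",
                         "copd_proxy", "hf_duration_ge_18", "beta_blocker",
                         "acei_arb", "statin", "loop_diuretic"}


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: Optional[int] = None
    mode: str = "synthetic"  # synthetic | files
    profiles_path: Optional[Path] = None
    input_dirs: list[Path] = field(default_factory=list)
    score_definition_paths: list[Path] = field(default_factory=list)
    limits_path: Optional[Path] = None
    alpha: float = 0.05
    n_perm: int = 999
    min_node: int = 20
    default_furosemide_dose: float = 40.0
    torasemide_to_furosemide: float = 4.0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic":
            if self.seed is None:
                raise ConfigurationError("seed is mandatory in synthetic mode")
            if self.profiles_path is None:
                raise ConfigurationError("synthetic mode needs profiles_path")
            if not Path(self.profiles_path).exists():
                raise ConfigurationError(
                    f"profiles file not found: {self.profiles_path}")
        else:
            if not self.input_dirs:
                raise ConfigurationError("files mode needs input_dirs")
            for d in self.input_dirs:
                if not Path(d).is_dir():
                    raise ConfigurationError(f"input dir not found: {d}")
        for p in self.score_definition_paths:
            if not Path(p).exists():
                raise ConfigurationError(f"score definition not found: {p}")
        if self.limits_path is not None and not Path(self.limits_path).exists():
            raise ConfigurationError(f"limits file not found: {self.limits_path}")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError(f"alpha outside (0, 1]: {self.alpha}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        for key in ("out_dir", "profiles_path", "limits_path"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        kwargs["input_dirs"] = [Path(p) for p in kwargs.get("input_dirs", [])]
        kwargs["score_definition_paths"] = [
            Path(p) for p in kwargs.get("score_definition_paths", [])]
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, Path):
                d[key] = str(value)
        d["input_dirs"] = [str(p) for p in d["input_dirs"]]
        d["score_definition_paths"] = [str(p)
                                       for p in d["score_definition_paths"]]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# harmonized table CSV round trip
# ---------------------------------------------------------------------------


def write_harmonized_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False, lineterminator="\n", na_rep="")


def read_harmonized_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in NUMERIC_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col].replace("", np.nan))
    for col in BOOL_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map(
                {"true": True, "false": False}).astype(object)
    for col in ("nyha", "sex", "pseudonym"):
        if col in table.columns:
            table[col] = table[col].replace("", np.nan).astype(object)
    return table


def _write_jsonl(entries, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# analysis helpers
# ---------------------------------------------------------------------------


def tree_feature_frame(cleaned: pd.DataFrame, feature_names: list[str],
                       ) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Numeric feature matrix + labels for the conditional tree
    (complete-case rows only)."""
    encoded = pd.DataFrame(index=cleaned.index)
    kinds: dict[str, str] = {}
    for name in feature_names:
        col = cleaned[name]
        if name == "status":
            encoded[name] = col.map({"outpatient": 0.0, "inpatient": 1.0})
        elif name == "sex":
            encoded[name] = col.map({"female": 0.0, "male": 1.0})
        elif name == "nyha":
            encoded[name] = col.map({"I": 1.0, "II": 2.0, "III": 3.0,
                                     "IV": 4.0})
        elif name in BOOL_COLUMNS:
            encoded[name] = col.map({False: 0.0, True: 1.0})
        else:
            encoded[name] = pd.to_numeric(col)
        kinds[name] = ("categorical" if name in _CATEGORICAL_FEATURES
                       else "continuous")
    complete = encoded.notna().all(axis=1)
    return (encoded[complete].reset_index(drop=True),
            cleaned.loc[complete, "site"].reset_index(drop=True), kinds)


def run_analysis(cleaned: pd.DataFrame, results: pd.DataFrame,
                 config: PipelineConfig) -> dict:
    """Score-distribution comparisons across sites plus the conditional
    tree; degenerate inputs are recorded as skipped, not fatal."""
    analysis: dict = {}

    maggic = results[(results["score_id"] == "maggic")
                     & (results["status"] == "complete")]
    groups = [sub["total_points"].to_numpy(dtype=float)
              for _, sub in maggic.groupby("site") if len(sub) > 0]
    if len(groups) >= 2:
        h, p = site_analysis.compare_sites_kw(groups)
        analysis["kruskal_wallis_maggic"] = {"H": h, "p": p,
                                             "n_sites": len(groups)}
    else:
        analysis["kruskal_wallis_maggic"] = {"skipped":
                                             "fewer than two sites with "
                                             "computed MAGGIC scores"}

    bcn = results[results["score_id"] == "bcn_biohf_v1"]
    wilcoxon = {}
    for site in sorted(bcn["site"].unique()):
        complete = bcn[(bcn["site"] == site) & (bcn["variant"] == "complete")
                       & (bcn["status"] == "complete")]["risk_1y"].dropna()
        imputed = bcn[(bcn["site"] == site) & (bcn["variant"] == "imputed")
                      & (bcn["status"] == "imputed")]["risk_1y"].dropna()
        if len(complete) >= 5 and len(imputed) >= 5:
            z, p, direction = site_analysis.compare_imputed_complete(
                complete.to_numpy(), imputed.to_numpy())
            wilcoxon[site] = {"z": z, "p": p, "direction": direction,
                              "n_complete": int(len(complete)),
                              "n_imputed": int(len(imputed))}
        else:
            wilcoxon[site] = {"skipped": "fewer than 5 scores per arm"}
    analysis["wilcoxon_imputed_vs_complete"] = wilcoxon

    features, labels, kinds = tree_feature_frame(cleaned,
                                                 TREE_FEATURES["maggic"])
    if len(features) >= config.min_node and labels.nunique() >= 2:
        tree = site_analysis.grow_conditional_tree(
            features, labels, kinds=kinds, alpha=config.alpha,
            n_perm=config.n_perm, seed=config.seed or 0,
            min_node=config.min_node)
        analysis["tree"] = tree.to_dict()
        analysis["tree_text"] = tree.to_text()
    else:
        analysis["tree"] = {"skipped": "not enough complete-case rows"}
    return analysis


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _load_definitions(config: PipelineConfig):
    if config.score_definition_paths:
        return [score_engine.load_score_definition(p)
                for p in config.score_definition_paths]
    return [score_engine.load_packaged("maggic"),
            score_engine.load_packaged("bcn_biohf_v1")]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output
    directory). On any fatal stage error, files written by this run are
    removed before the error propagates."""
    config.validate()
    defs = _load_definitions(config)
    limits = (plausibility.load_limits(config.limits_path)
              if config.limits_path else plausibility.default_limits())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        if config.mode == "synthetic":
            profiles = synthetic_cohort.load_profiles(config.profiles_path)
            cohorts = synthetic_cohort.generate_multisite(profiles,
                                                          config.seed)
            for cohort in cohorts:
                site = cohort.enrollments[0].patient.site if \
                    cohort.enrollments else "empty"
                site_dir = out / "input" / f"site_{site}"
                cohort_model.write_cohort(cohort, site_dir)
                for filename, _ in cohort_model.TEMPLATES.values():
                    track(site_dir / filename)
        else:
            cohorts = [cohort_model.read_cohort(d) for d in config.input_dirs]

        validation_entries = []
        for cohort in cohorts:
            validation_entries.extend(
                cohort_model.validate_cohort(cohort).entries())
        _write_jsonl(validation_entries, track(out / "validation_report.jsonl"))

        key_rows = []
        pseudonymized = []
        for cohort in cohorts:
            p_cohort, key_table = cohort_model.pseudonymize(cohort)
            pseudonymized.append(p_cohort)
            key_rows.extend(key_table)
        cohort_model.write_key_table(key_rows,
                                     track(out / "private" / "key_table.csv"))

        merged = Cohort()
        for cohort in pseudonymized:
            for attr in ("enrollments", "personal", "history", "medication",
                         "echo", "labs"):
                getattr(merged, attr).extend(getattr(cohort, attr))

        hconfig = harmonization.HarmonizationConfig(
            default_furosemide_dose=config.default_furosemide_dose,
            torasemide_to_furosemide=config.torasemide_to_furosemide)
        harmonized = harmonization.build_harmonized(merged, hconfig)
        write_harmonized_csv(harmonized.table, track(out / "harmonized.csv"))
        _write_jsonl(harmonized.log, track(out / "preparation_log.jsonl"))

        cleaned, report = plausibility.apply_plausibility(harmonized.table,
                                                          limits)
        write_harmonized_csv(cleaned, track(out / "harmonized_clean.csv"))
        track(out / "plausibility_report.jsonl").write_text(
            report.to_jsonl(), encoding="utf-8")

        results = score_engine.compute_cohort_scores(defs, cleaned)
        shared = results.drop(columns=["local_id"])  # pseudonymized output
        shared.to_csv(track(out / "scores.csv"), index=False,
                      lineterminator="\n", na_rep="")

        availability = site_analysis.availability_counts(cleaned, results)
        availability.items.to_csv(track(out / "availability_items.csv"),
                                  index=False, lineterminator="\n")
        availability.scores.to_csv(track(out / "availability_scores.csv"),
                                   index=False, lineterminator="\n")

        analysis = run_analysis(cleaned, results, config)
        track(out / "analysis.json").write_text(
            json.dumps(analysis, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")

        manifest = {
            "seed": config.seed,
            "config": config.to_jsonable(),
            "config_hash": config.config_hash(),
            "stages": {
                "enrolled": len(merged.enrollments),
                "validation_findings": len(validation_entries),
                "harmonized_rows": int(len(harmonized.table)),
                "plausibility_flags": len(report.entries),
                "plausibility_warnings": len(report.warnings),
                "score_rows": int(len(results)),
                "not_computable": int((results["status"]
                                       == "not_computable").sum()),
                "imputed": int((results["status"] == "imputed").sum()),
                "complete": int((results["status"] == "complete").sum()),
            },
        }
        track(out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# merging pseudonymized site results
# ---------------------------------------------------------------------------


def merge_sites(result_dirs: list) -> pd.DataFrame:
    """Pool pseudonymized score tables from several result directories.

    Refuses tables that still carry local identifiers and site-code
    collisions across inputs."""
    seen_sites: set[str] = set()
    frames = []
    for d in result_dirs:
        d = Path(d)
        path = d / "scores.csv"
        if not path.exists():
            raise ConfigurationError(f"no scores.csv in {d}")
        frame = pd.read_csv(path, dtype={"site": str}, keep_default_na=False,
                            na_values=[""])
        if "local_id" in frame.columns:
            raise PrivacyError(f"{path} contains a local_id column; refusing "
                               "to merge non-pseudonymized results")
        sites = set(frame["site"].unique())
        overlap = sites & seen_sites
        if overlap:
            raise MergeError(f"site code collision: {sorted(overlap)}")
        seen_sites |= sites
        frame = frame.copy()
        frame["source"] = d.name
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
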
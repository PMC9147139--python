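# hfscores

Multi-site heart-failure risk-score pipeline. Ingests clinical tables
shaped after six openEHR-style templates (personal data, patient
history, medication, echocardiography, laboratory, enrollment),
harmonizes them into one row per patient, applies plausibility checks,
computes two mortality risk scores — the MAGGIC integer points score and
the BCN Bio-HF v1 Cox score — and compares score distributions across
sites. A seeded synthetic-cohort generator with configurable per-site
distributions, missingness and reduced date precision stands in for
clinical data.

## Layout

| Module | Purpose |
| --- | --- |
| `hfscores.cohort_model` | Domain types for the six template tables, CSV dialect readers/writers, referential-integrity validation, pseudonymization |
| `hfscores.synthetic_cohort` | Seeded multi-site cohort generator (site profiles in YAML) |
| `hfscores.harmonization` | Mid-period date completion, age/BMI/HF-duration derivation, closest-record selection, medication mapping with furosemide equivalents |
| `hfscores.plausibility` | Admissible-range checks; out-of-range values become missing and are reported |
| `hfscores.score_engine` | Declarative score evaluator (points tables with stratified lookup; Cox linear predictor with imputation references); shipped definitions in `hfscores/data/` |
| `hfscores.site_analysis` | Availability accounting, Kruskal–Wallis / Wilcoxon rank tests, permutation-based conditional inference tree |
| `hfscores.pipeline` / `hfscores.cli` | End-to-end orchestration, manifests, pooled merging of pseudonymized site results |

## CLI

```sh
# generate synthetic per-site template tables
hfscores generate --profiles profiles.yaml --seed 7 --out data/

# full pipeline from a YAML config (synthetic or existing files)
hfscores run --config config.yaml

# rescore an existing cleaned harmonized table
hfscores score --harmonized out/harmonized_clean.csv --out rescored.csv

# availability + rank tests + conditional tree on existing outputs
hfscores analyze --harmonized out/harmonized_clean.csv \
    --scores out/scores.csv --out analysis/

# pool pseudonymized score tables from several site runs
hfscores merge site_a_out site_b_out --out pooled.csv
```

A minimal run config:

```yaml
out_dir: out
seed: 7
mode: synthetic          # or "files" with input_dirs: [...]
profiles_path: profiles.yaml
alpha: 0.05
n_perm: 999
min_node: 20
```

Example profiles ship in `src/hfscores/data/default_profiles.yaml`.
Exit codes distinguish configuration (2), data-format (3), privacy (4)
and merge (5) errors.

## Scores

Score definitions are versioned YAML files, never hard-coded. The
MAGGIC definition transcribes the published integer points tables and
the integer-score → 1-/3-year mortality lookup; it requires complete
data. The BCN Bio-HF v1 definition is a Cox linear predictor with
per-horizon baseline survival and cohort-independent imputation
reference values; its coefficients are best-effort transcriptions
calibrated to the published effect directions (see the header comment in
`src/hfscores/data/bcn_biohf_v1.yaml`) and can be replaced by exact
site-validated values without touching code.

Plausibility checking (implausible → missing, reported) is deliberately
distinct from score-boundary clipping (out-of-range → boundary, logged);
the former runs first.

## Tests and acceptance report

```sh
python -m pytest -q                # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the worked-example targets (the
bounds actually applied by the packaged plausibility configuration) by
pushing out-of-range probe values through the pipeline and reporting the
limit cited in the resulting report entries.
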
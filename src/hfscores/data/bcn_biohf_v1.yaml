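# BCN Bio-HF v1 (clinical model without biomarkers): Cox linear
# predictor over 11 variables with baseline survival per horizon.
# Risk(h) = 1 - S0(h) ^ exp(LP - centering).
#
# The source publication (Lupon et al. 2014) prints hazard ratios and a
# calculator rather than a machine-readable coefficient table; the
# log-hazard coefficients, centering constant, baseline survivals and
# clip bounds below are best-effort transcriptions calibrated to the
# published effect directions and magnitudes. They are versioned here,
# never hard-coded, so a site can replace them with an exact transcription.
#
# Supports imputation: per-variable reference values are cohort-independent.
id: bcn_biohf_v1
method: cox_lp
horizons: [1, 2, 3]
completeness: allow_imputation
variables:
  - {name: age, kind: continuous, clip_lower: 18, clip_upper: 100}
  - {name: sex, kind: categorical}
  - {name: nyha, kind: categorical}
  - {name: lvef, kind: continuous, clip_lower: 5, clip_upper: 80}
  - {name: sodium, kind: continuous, clip_lower: 125, clip_upper: 148}
  - {name: hemoglobin, kind: continuous, clip_lower: 7, clip_upper: 17}
  - {name: egfr, kind: continuous, clip_lower: 5, clip_upper: 120}
  - {name: beta_blocker, kind: boolean}
  - {name: acei_arb, kind: boolean}
  - {name: statin, kind: boolean}
  - {name: furosemide_equiv_dose, kind: continuous, clip_lower: 0, clip_upper: 500}
terms:
  - {variable: age, type: linear, coef: 0.04}
  - {variable: sex, type: category, coef: {male: 0.0, female: -0.45}}
  - {variable: nyha, type: category, coef: {I: 0.0, II: 0.35, III: 0.80, IV: 1.20}}
  - {variable: lvef, type: linear, coef: -0.02}
  - {variable: sodium, type: linear, coef: -0.045}
  - {variable: hemoglobin, type: linear, coef: -0.12}
  - {variable: egfr, type: linear, coef: -0.01}
  - {variable: beta_blocker, type: category, coef: {false: 0.0, true: -0.40}}
  - {variable: acei_arb, type: category, coef: {false: 0.0, true: -0.30}}
  - {variable: statin, type: category, coef: {false: 0.0, true: -0.35}}
  - variable: furosemide_equiv_dose
    type: banded
    bands:
      - {hi: 1, coef: 0.0}
      - {lo: 1, hi: 41, coef: 0.30}
      - {lo: 41, coef: 0.70}
# linear predictor of the reference patient: age 67, male, NYHA II,
# LVEF 35, sodium 139, hemoglobin 13, eGFR 65, on beta blocker,
# ACEi/ARB and statin, furosemide-equivalent 40 mg/day
centering: -6.885
baseline_survival: {1: 0.91, 2: 0.84, 3: 0.78}
imputation_references:
  lvef: 35.0
  sodium: 139.0
  hemoglobin: 13.2
  egfr: 65.0
  nyha: II
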
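# Two-site demonstration profiles with heterogeneous inpatient mixes,
# missingness and date precision. All rates are artifact choices: the
# study reports per-site availability only graphically.
sites:
  - site: G
    n_patients: 150
    inpatient_fraction: 0.25
    year_only_birth_fraction: 0.6
    year_only_hf_onset_fraction: 0.5
    implausible_rate: 0.01
    missingness:
      hf_first_diagnosis: 0.35
      lvef: 0.10
      sodium: 0.15
      hemoglobin: 0.15
      egfr: 0.20
      current_smoker: 0.20
      diabetes: 0.05
      chronic_lung_disease: 0.10
  - site: H
    n_patients: 150
    inpatient_fraction: 0.85
    year_only_birth_fraction: 0.4
    year_only_hf_onset_fraction: 0.6
    implausible_rate: 0.01
    systolic_bp: {mean: 118, sd: 18, lo: 71, hi: 249}
    lvef: {mean: 33, sd: 11, lo: 5, hi: 80}
    missingness:
      hf_first_diagnosis: 0.55
      lvef: 0.05
      weight: 0.10
      height: 0.10
      systolic_bp: 0.05
      nyha: 0.10
      current_smoker: 0.30
      creatinine: 0.05
      egfr: 0.10
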
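# MAGGIC integer points score, transcribed from the published score
# (Pocock et al., Eur Heart J 2013) and its companion risk calculator.
# Additive integer points over 13 variables; age and systolic blood
# pressure points are stratified by ejection-fraction band.  The
# integer-score -> mortality lookup is tabulated for scores 0..50; higher
# attainable totals saturate at the score-50 risk (clamp_points).
# Requires complete data: no imputation.
id: maggic
method: points_table
horizons: [1, 3]
completeness: require_complete
variables:
  - {name: lvef, kind: continuous}
  - {name: age, kind: continuous}
  - {name: systolic_bp, kind: continuous}
  - {name: bmi, kind: continuous}
  - {name: creatinine, kind: continuous}
  - {name: nyha, kind: categorical}
  - {name: sex, kind: categorical}
  - {name: current_smoker, kind: boolean}
  - {name: diabetes, kind: boolean}
  - {name: copd_proxy, kind: boolean}
  - {name: hf_duration_ge_18, kind: boolean}
  - {name: beta_blocker, kind: boolean}
  - {name: acei_arb, kind: boolean}
rules:
  - variable: lvef
    type: range
    bands:
      - {hi: 20, points: 7}
      - {lo: 20, hi: 25, points: 6}
      - {lo: 25, hi: 30, points: 5}
      - {lo: 30, hi: 35, points: 3}
      - {lo: 35, hi: 40, points: 2}
      - {lo: 40, points: 0}
  - variable: age
    type: range
    stratify_by: lvef
    strata:
      - stratum: {hi: 30}
        bands:
          - {hi: 55, points: 0}
          - {lo: 55, hi: 60, points: 1}
          - {lo: 60, hi: 65, points: 2}
          - {lo: 65, hi: 70, points: 4}
          - {lo: 70, hi: 75, points: 6}
          - {lo: 75, hi: 80, points: 8}
          - {lo: 80, points: 10}
      - stratum: {lo: 30, hi: 40}
        bands:
          - {hi: 55, points: 0}
          - {lo: 55, hi: 60, points: 2}
          - {lo: 60, hi: 65, points: 4}
          - {lo: 65, hi: 70, points: 6}
          - {lo: 70, hi: 75, points: 8}
          - {lo: 75, hi: 80, points: 10}
          - {lo: 80, points: 13}
      - stratum: {lo: 40}
        bands:
          - {hi: 55, points: 0}
          - {lo: 55, hi: 60, points: 3}
          - {lo: 60, hi: 65, points: 5}
          - {lo: 65, hi: 70, points: 7}
          - {lo: 70, hi: 75, points: 9}
          - {lo: 75, hi: 80, points: 12}
          - {lo: 80, points: 15}
  - variable: systolic_bp
    type: range
    stratify_by: lvef
    strata:
      - stratum: {hi: 30}
        bands:
          - {hi: 110, points: 5}
          - {lo: 110, hi: 120, points: 4}
          - {lo: 120, hi: 130, points: 3}
          - {lo: 130, hi: 140, points: 2}
          - {lo: 140, hi: 150, points: 1}
          - {lo: 150, points: 0}
      - stratum: {lo: 30, hi: 40}
        bands:
          - {hi: 110, points: 3}
          - {lo: 110, hi: 120, points: 2}
          - {lo: 120, hi: 130, points: 1}
          - {lo: 130, hi: 140, points: 1}
          - {lo: 140, hi: 150, points: 0}
          - {lo: 150, points: 0}
      - stratum: {lo: 40}
        bands:
          - {hi: 110, points: 2}
          - {lo: 110, hi: 120, points: 1}
          - {lo: 120, hi: 130, points: 1}
          - {lo: 130, hi: 140, points: 0}
          - {lo: 140, hi: 150, points: 0}
          - {lo: 150, points: 0}
  - variable: bmi
    type: range
    bands:
      - {hi: 15, points: 6}
      - {lo: 15, hi: 20, points: 5}
      - {lo: 20, hi: 25, points: 3}
      - {lo: 25, hi: 30, points: 2}
      - {lo: 30, points: 0}
  - variable: creatinine
    type: range
    bands:
      - {hi: 90, points: 0}
      - {lo: 90, hi: 110, points: 1}
      - {lo: 110, hi: 130, points: 2}
      - {lo: 130, hi: 150, points: 3}
      - {lo: 150, hi: 170, points: 4}
      - {lo: 170, hi: 210, points: 5}
      - {lo: 210, hi: 250, points: 6}
      - {lo: 250, points: 8}
  - variable: nyha
    type: category
    points: {I: 0, II: 2, III: 6, IV: 8}
  - variable: sex
    type: category
    points: {female: 0, male: 1}
  - variable: current_smoker
    type: category
    points: {false: 0, true: 1}
  - variable: diabetes
    type: category
    points: {false: 0, true: 3}
  - variable: copd_proxy
    type: category
    points: {false: 0, true: 2}
  - variable: hf_duration_ge_18
    type: category
    points: {false: 0, true: 2}
  - variable: beta_blocker
    type: category
    points: {false: 3, true: 0}
  - variable: acei_arb
    type: category
    points: {false: 1, true: 0}
clamp_points: true
risk:
  1:
    0: 0.015
    1: 0.016
    2: 0.018
    3: 0.020
    4: 0.022
    5: 0.024
    6: 0.027
    7: 0.029
    8: 0.032
    9: 0.036
    10: 0.039
    11: 0.043
    12: 0.048
    13: 0.052
    14: 0.058
    15: 0.063
    16: 0.070
    17: 0.077
    18: 0.084
    19: 0.093
    20: 0.102
    21: 0.111
    22: 0.122
    23: 0.134
    24: 0.147
    25: 0.160
    26: 0.175
    27: 0.191
    28: 0.209
    29: 0.227
    30: 0.247
    31: 0.269
    32: 0.292
    33: 0.316
    34: 0.342
    35: 0.369
    36: 0.398
    37: 0.427
    38: 0.458
    39: 0.490
    40: 0.523
    41: 0.556
    42: 0.590
    43: 0.625
    44: 0.658
    45: 0.692
    46: 0.725
    47: 0.756
    48: 0.787
    49: 0.815
    50: 0.842
  3:
    0: 0.039
    1: 0.043
    2: 0.048
    3: 0.052
    4: 0.058
    5: 0.063
    6: 0.070
    7: 0.077
    8: 0.084
    9: 0.093
    10: 0.102
    11: 0.111
    12: 0.122
    13: 0.134
    14: 0.147
    15: 0.160
    16: 0.175
    17: 0.191
    18: 0.209
    19: 0.227
    20: 0.247
    21: 0.269
    22: 0.292
    23: 0.316
    24: 0.342
    25: 0.369
    26: 0.398
    27: 0.427
    28: 0.458
    29: 0.490
    30: 0.523
    31: 0.556
    32: 0.590
    33: 0.625
    34: 0.658
    35: 0.692
    36: 0.725
    37: 0.756
    38: 0.787
    39: 0.815
    40: 0.842
    41: 0.866
    42: 0.889
    43: 0.908
    44: 0.926
    45: 0.941
    46: 0.953
    47: 0.964
    48: 0.973
    49: 0.980
    50: 0.985
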
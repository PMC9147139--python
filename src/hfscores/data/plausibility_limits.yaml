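# Admissible ranges for continuous variables, checked before score
# calculation. Bounds are inclusive. The HF-duration upper bound is
# dynamic: the patient's own age in years times 12.
age: {lower: 18, upper: 110, unit: years}
bmi: {lower: 14, upper: 60, unit: kg/m^2}
systolic_bp: {lower: 70, upper: 250, unit: mm Hg}
hf_duration: {lower: 0, upper: age*12, unit: months}
lvef: {lower: 4, upper: 85, unit: "%"}
creatinine: {lower: 26.526, upper: 1326.3, unit: µmol/L}
sodium: {lower: 120, upper: 150, unit: mmol/L}
hemoglobin: {lower: 5, upper: 20, unit: g/dL}
egfr: {lower: 5, upper: 120, unit: mL/min/1.73}
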
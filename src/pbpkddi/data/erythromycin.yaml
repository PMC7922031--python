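# Example perpetrator config: erythromycin (mechanism-based CYP3A4 inhibitor
# and CYP3A4 substrate).
#
# APPROXIMATE VALUES. This file is a usable example assembled from commonly
# cited literature ranges (not from any specific published PBPK model).
# Replace with your own parameterisation for quantitative work.
name: erythromycin
physchem:
  molecular_weight: 733.93
  lipophilicity: 2.48
  solubility: 1000.0        # µg/mL, administered as soluble salt
  fraction_unbound: 0.29
  intestinal_permeability: 2.0e-4   # cm/s
processes:
  - kind: michaelis-menten
    enzyme: CYP3A4
    K_m: 88.0               # µM, N-demethylation
    k_cat: 10.0             # 1/min, adjusted to a ~2 h elimination half-life
  - kind: renal-filtration
    gfr_fraction: 1.0
interactions:
  - kind: inhibition
    target_enzyme: CYP3A4
    mode: mechanism-based
    K_I: 60.0               # µM unbound, mid literature range
    k_inact: 0.04           # 1/min
formulations:
  tablet:
    - kind: dissolved
  solution:
    - kind: dissolved
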
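# Example victim config: simvastatin (high-extraction CYP3A4 substrate,
# weak competitive CYP3A4 inhibitor).
#
# APPROXIMATE VALUES assembled from commonly cited literature ranges; replace
# for quantitative work.
name: simvastatin
physchem:
  molecular_weight: 418.57
  lipophilicity: 4.68
  solubility: 30.0          # µg/mL
  fraction_unbound: 0.05
  intestinal_permeability: 3.0e-4
processes:
  - kind: michaelis-menten
    enzyme: CYP3A4
    K_m: 35.0
    k_cat: 250.0            # 1/min, high intrinsic clearance (F ~ 5-10%)
interactions:
  - kind: inhibition
    target_enzyme: CYP3A4
    mode: competitive
    K_i: 10.0               # µM unbound
formulations:
  tablet:
    - kind: weibull
      t_50: 30.0
      shape: 1.2
      lag: 5.0
      food_state: fasted
  solution:
    - kind: dissolved
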
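# Example victim config: bupropion (CYP2B6 substrate, hydroxylation).
#
# APPROXIMATE VALUES assembled from commonly cited literature ranges; replace
# for quantitative work.
name: bupropion
physchem:
  molecular_weight: 239.74
  lipophilicity: 3.0
  solubility: 1000.0        # µg/mL, HCl salt
  fraction_unbound: 0.16
  intestinal_permeability: 4.0e-4
processes:
  - kind: michaelis-menten
    enzyme: CYP2B6
    K_m: 89.0               # µM, hydroxylation
    k_cat: 200.0            # 1/min, moderate-to-high hepatic extraction
  - kind: hepatic-clearance
    CL_spec: 0.002          # 1/min, minor non-CYP2B6 routes
formulations:
  tablet:
    - kind: dissolved
  solution:
    - kind: dissolved
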
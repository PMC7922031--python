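# Example config: efavirenz (CYP2B6 substrate and CYP3A4/CYP2B6 inducer;
# CYP3A4 metabolism plays a minor role).
#
# APPROXIMATE VALUES assembled from commonly cited literature ranges; replace
# for quantitative work.
name: efavirenz
physchem:
  molecular_weight: 315.68
  lipophilicity: 4.2
  solubility: 90.0          # µg/mL, formulation-assisted effective solubility
  fraction_unbound: 0.01
  intestinal_permeability: 2.5e-4
processes:
  - kind: michaelis-menten
    enzyme: CYP2B6
    K_m: 10.0               # µM, 8-hydroxylation; in vivo fm ~ 40-50% here
    k_cat: 20.0             # 1/min
  - kind: michaelis-menten
    enzyme: CYP3A4
    K_m: 20.0
    k_cat: 1.0              # 1/min, minor pathway
  - kind: hepatic-clearance
    CL_spec: 5.5            # 1/min, lumped accessory oxidation/glucuronidation
interactions:
  - kind: induction
    target_enzyme: CYP3A4
    EC_50: 0.3              # µM unbound
    E_max: 3.0
  - kind: induction
    target_enzyme: CYP2B6
    EC_50: 0.3              # µM unbound
    E_max: 3.0
formulations:
  tablet:
    - kind: dissolved
  solution:
    - kind: dissolved
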
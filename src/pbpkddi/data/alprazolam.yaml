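# Example victim config: alprazolam (low-extraction CYP3A4 substrate).
#
# APPROXIMATE VALUES assembled from commonly cited literature ranges; replace
# for quantitative work.
name: alprazolam
physchem:
  molecular_weight: 308.77
  lipophilicity: 2.12
  solubility: 73.0          # µg/mL
  fraction_unbound: 0.29
  intestinal_permeability: 3.0e-4
processes:
  - kind: michaelis-menten
    enzyme: CYP3A4
    K_m: 269.0
    k_cat: 7.3              # 1/min, adjusted to a ~11 h half-life
  - kind: renal-filtration
    gfr_fraction: 0.2
formulations:
  tablet:
    - kind: dissolved
  solution:
    - kind: dissolved
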
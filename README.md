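# pbpkddi

Whole-body parent–metabolite PBPK (physiologically based pharmacokinetic)
model of carbamazepine and its active metabolite carbamazepine-10,11-epoxide,
with CYP3A4/CYP2B6/EPHX1 enzyme (auto-)induction, mechanism-based and
competitive inhibition, formulation-dependent oral absorption, renal
filtration, drug–drug interaction (DDI) co-simulation, model-performance
statistics, parameter fitting, and a synthetic clinical-dataset generator.

## Layout

| module | contents |
| --- | --- |
| `pbpkddi.physiology` | virtual individuals: organ volumes/flows, tissue composition, GFR, enzyme expression, allometric scaling |
| `pbpkddi.engine` | rate laws (Michaelis–Menten, specific clearance, Emax induction, MBI, competitive inhibition, GFR filtration, Weibull release), neutral-species tissue:plasma partitioning, whole-body ODE assembly and stiff integration with dose events |
| `pbpkddi.drugs` | packaged carbamazepine / epoxide parameter sets, parent→metabolite coupling, YAML drug-config loader, example perpetrator configs |
| `pbpkddi.trials` | study/DDI protocols, co-simulation, plasma/saliva/urine-fraction observables, AUC_last, Cmax, DDI ratios |
| `pbpkddi.evaluation` | MRD, GMFE, 2-fold fraction, observed-ratio-dependent DDI prediction-success limits, report generation |
| `pbpkddi.fitting` | multistart (Monte-Carlo + local least-squares) estimation on log-scale residuals, parameter paths, sensitivity utility |
| `pbpkddi.synthetic` | synthetic observed datasets with lognormal residual noise, inter-individual variability, mean ± SD reporting |

Internal units are min / L / µmol / µM; public interfaces use hours and mg.

## CLI

```bash
# simulate a protocol (YAML) and write the profile CSV
pbpkddi simulate --protocol protocol.yaml --out profile.csv

# DDI co-simulation: victim protocol + perpetrator event list
pbpkddi ddi --victim victim.yaml --perpetrator perp.yaml --out report.json

# predicted-vs-observed statistics
pbpkddi evaluate --pred pred.csv --obs obs.csv --out report.json

# synthetic observed data
pbpkddi synth --protocol protocol.yaml --sigma 0.15 --seed 7 --out obs.csv

# parameter estimation
pbpkddi fit --spec fitspec.yaml --out fit.json
```

Protocol schema (note: quote drug names containing commas in flow-style
YAML):

```yaml
events:
  - {drug: carbamazepine, amount_mg: 400, time_h: 0, formulation: solution}
sampling_times_h: [0.5, 1, 2, 4, 8, 12, 24, 48]
analytes:
  - {drug: carbamazepine, matrix: plasma}
  - {drug: "carbamazepine-10,11-epoxide", matrix: plasma}
```

Drugs resolve by packaged name (`carbamazepine`,
`carbamazepine-10,11-epoxide`), by example-config name (`erythromycin`,
`alprazolam`, `simvastatin`, `bupropion`, `efavirenz`) or by config file
path. The example perpetrator configs under `src/pbpkddi/data/` carry
approximate literature-informed values and are meant as usable templates —
replace them with your own parameterisation for quantitative work.
Physiology overrides: `--physiology physiology.yaml`.

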
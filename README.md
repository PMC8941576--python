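# suamr

Sex-stratified serum-uric-acid (SUA) / fatty-liver association modelling and
one-sample Mendelian-randomization (MR) triangulation, packaged with a
synthetic cohort generator so the entire analysis is testable end to end
without any external data.

The toolkit covers:

- **`suamr.synthetic_cohort`** — seeded cohort + genotype generation under a
  *causal* scenario (SUA raises fatty-liver odds directly) or a *marker*
  scenario (the association is driven entirely by a shared latent
  confounder, so genetic analyses see a null).
- **`suamr.cohort_core`** — participant records, the two-stage exclusion
  cascade, APRI/FIB-4 fibrosis scores, elevated-marker cutoffs, unit
  conversion (59.5 μmol/l per mg/dl) and BMI categorisation.
- **`suamr.observational_association`** — per-sex SUA quartile schemes,
  logistic quartile odds ratios (crude / age-sex / model 1 / model 2),
  ordinal trend tests, per-unit ORs and sex/BMI-stratified analyses.
- **`suamr.progression_markers`** — among incident cases: covariance-adjusted
  mean differences in ALT/GGT/APRI/FIB-4 across SUA quartiles, and logistic
  ORs of elevated markers (FIB-4 models never adjust for age, since age sits
  inside the score).
- **`suamr.genetic_instruments`** — Hardy–Weinberg testing,
  additive/dominant/codominant coding, per-allele SUA regressions with
  variance explained, the unweighted 0–4 allele score, confounder-balance
  checks, and a minimal VCF importer.
- **`suamr.mr_triangulation`** — expected genetic effect (βGB × ln OR per
  mg/dl), observed per-allele logistic effect, the Altman–Bland interaction
  test between them, and an approximate per-allele power calculation.
- **`suamr.cli_reporting`** / **`suamr.cli`** — a seeded pipeline producing
  tidy CSV tables, a forest-plot CSV and a JSON summary.

## Command line

```bash
# full pipeline on a simulated cohort
suamr all --seed 1 --scenario marker --out out/

# or stage by stage
suamr simulate --seed 1 --n 8429 --out data/
suamr filter --cohort data/cohort.csv --out data/filtered/
suamr associate --cohort data/filtered/cohort_filtered.csv --model model2 --out out/assoc.csv
suamr genetics --cohort data/cohort.csv --genotypes data/genotypes.csv --out out/instruments.csv
```

`out/summary.json` contains every estimate in the report; the CSVs
(`table2.csv`, `table3.csv`, `table4.csv`, `instruments.csv`,
`mr_forest.csv`) are rendered from the same numbers.

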
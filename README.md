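# cpdtools

Compensated pathogenic deviations (CPDs) are missense variants that cause
disease in humans while the very same residue is the wild type in another
species, where its effect is suppressed by compensatory changes elsewhere
in the protein. `cpdtools` implements the full analysis pipeline for
studying CPDs in the coagulation factors FVIII and FIX (hemophilia A/B) and
their genetic background:

* **CPD classification** — map each variant's 1-based protein position to
  its column in an ortholog multiple sequence alignment and call the
  variant a CPD iff at least one non-human row carries the mutant residue
  (an existential, threshold-free criterion);
* **molecular impact** — attach four per-variant measures: the stability
  change upon mutation ΔΔG (kcal/mol, destabilising positive, from a FoldX
  style table), relative solvent accessibility (percent, from a NACCESS
  style table), the BLOSUM62 substitution score, and the Shannon entropy
  H = −Σᵢ pᵢ log₂ pᵢ of the variant's alignment column (bits; 0 for a
  fully conserved site, log₂ 20 ≈ 4.322 for a maximally variable one);
* **association statistics** — a two-sided Fisher exact test for
  severity × compensation contingency tables and Mood's median test
  (exact or χ² backend) for group comparisons of impact properties;
* **genetic background** — per-individual missense burden over a 19-gene
  hemostasis panel in a male population cohort: mutated-protein and
  variant-count distributions, per-gene prevalence, pathogenic/neutral
  composition, cis/trans labelling, and per-variant background ranges
  across carriers;
* **synthetic data** — a seeded generator producing ortholog MSAs with
  planted compensations, variant/property tables with group-specific ΔΔG
  and logistic severity coupling, and a population cohort with per-gene
  allele-frequency spectra — every pipeline stage is testable against
  recorded ground truth without any external downloads.

The intended users are computational biologists studying compensated
variation, genotype–phenotype mapping in hemophilia, or the modulating
role of genetic background.

## Worked example

Simulate a study-scale dataset (971 pathogenic FVIII-like variants, 122 of
them compensated; a 1233-male cohort over the 19-gene panel) and run the
whole pipeline:

```python
from cpdtools import (SimulationConfig, simulate_all, classify_dataset,
                      severity_contingency, severe_fraction, fisher_exact_2x2,
                      build_impact_table, compare_cpd_vs_nocpd,
                      individual_burdens, pathogenic_composition_summary)

config = SimulationConfig(seed=1)          # study-scale defaults
sim = simulate_all(config, out_dir="demo")

calls = classify_dataset(sim.variants, sim.alignments)
table = severity_contingency(calls)
print("CPD/noCPD x mild/severe counts:", table.table.tolist())
print("severe fraction (CPD):", severe_fraction(table, "CPD"), "%")
print("Fisher exact p:", f"{fisher_exact_2x2(table.table).p_value:.2g}")

records = build_impact_table(calls, sim.props, sim.alignments)
result = compare_cpd_vs_nocpd(records, "ddg")
print("ddg medians (CPD, noCPD):", tuple(round(m, 2) for m in result.medians))
print("Mood's median p:", f"{result.p_value:.2g}")

burdens = individual_burdens(sim.genotypes, sim.panel)
summary = pathogenic_composition_summary(burdens)
print("mean variants per individual:", round(burdens["n_variants_total"].mean(), 2))
print("pathogenic-carrier fraction:", round(summary.pathogenic_carrier_fraction, 3))
```

Output:

```
CPD/noCPD x mild/severe counts: [[67, 55], [426, 423]]
severe fraction (CPD): 45 %
Fisher exact p: 0.33
ddg medians (CPD, noCPD): (1.0, 1.83)
Mood's median p: 7.2e-12
mean variants per individual: 8.76
pathogenic-carrier fraction: 0.822
```

Reading: the classifier recovers exactly the 122 planted CPDs. The
generator couples severity to ΔΔG only weakly by default, so this seed's
severity table shows no significant association (p = 0.33), while the
planted 1.0 kcal/mol ΔΔG shift between the CPD and noCPD groups — CPDs
being the molecularly milder group — is detected overwhelmingly
(medians 1.0 vs 1.83 kcal/mol, p ≈ 7 × 10⁻¹²). In the cohort, individuals
carry ~9 panel variants on average and 82% carry at least one
pathogenic-annotated variant.

The same steps are available from a shell via the `cpd` entry point
(`cpd simulate`, `cpd classify`, `cpd entropy`, `cpd compare`,
`cpd background`); see `cpd --help`.

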
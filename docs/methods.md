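# Methods

## The classification model

A variant is described by its gene, 1-based position in the human protein
sequence, wild-type and mutant residues, and a binary clinical severity
label (mild/severe; anything else is treated as unknown and excluded from
severity analyses, keeping the contingency tables strictly binary — labels
such as "moderate" are normalised to unknown, case- and
whitespace-insensitively).

Classification is purely positional: the variant's position is mapped to
the alignment column holding the corresponding non-gap character of the
human row, and the variant is a CPD iff at least one non-human row carries
the mutant residue at that column. Matching is exact single-letter
equality, case-insensitive; gaps (`-`, `.`) and ambiguous letters
(X/B/Z/U) never match. One supporting species suffices. When the human MSA
row disagrees with the table's wild-type residue the call is still emitted
but flagged (`human_residue_check = "mismatch"`) and excluded from
statistics by default — variant databases and canonical ortholog sequences
occasionally disagree, and aborting the run would discard the rest of the
dataset. No renumbering between legacy/mature-chain and sequence
coordinates is attempted; positions are taken as indices into the human
sequence as provided.

## Conservation and impact measures

Column profiles count canonical residues over **all** rows, human
included (the conservation of a site is a property of the whole family);
gaps and ambiguous letters contribute neither to counts nor to the
denominator. Shannon entropy is computed in bits, −Σᵢ pᵢ log₂ pᵢ, so the
maximum over 20 amino acids is log₂ 20 ≈ 4.322; an all-gap column has
undefined entropy and raises rather than returning 0, which would be
indistinguishable from perfect conservation. Columns are 0-based
internally and 1-based in all user-facing output.

BLOSUM62 is embedded as a module constant (the canonical 20×20 block) and
verified entry-for-entry against biopython's vendored copy in the test
suite. ΔΔG and relative solvent accessibility are opaque inputs joined by
(gene, wt, pos, mut); a variant missing one property is excluded pairwise
from tests on that property only, never dropped outright.

## Statistical tests

**Fisher's exact test (two-sided).** The p-value sums hypergeometric point
probabilities, over all 2×2 tables with the observed margins, that do not
exceed the observed table's probability. The comparison uses a 1e-7
relative slack so that mathematically tied tables are included despite
floating-point rounding; the test suite checks the implementation against
exact integer-arithmetic enumeration for every margin class with total
count ≤ 60, and against an independent library implementation on random
tables. Degenerate margins (an empty row or column) return p = 1 with a
warning rather than an error.

**Mood's median test.** Both samples are pooled, the grand median taken,
and each sample dichotomised into counts above vs not-above it. Values
equal to the grand median count as "≤ median" — the convention is stated
in every result's `note` field since different packages disagree. The
resulting 2×2 is tested with the exact test by default, so that small
samples (a dozen CPDs per group is realistic for FIX-sized data) are
handled honestly without asymptotic approximations; a Pearson χ² backend
without continuity correction is available by flag and matches
`scipy.stats.median_test(ties="below", correction=False)`. A pooled sample
with all values identical admits no dichotomy and returns p = 1 with a
warning. The exact backend is validated against a label-permutation
simulation (the permutation distribution of the above-median count is
hypergeometric, and with equal group sizes the probability-ordering and
distance-from-expectation two-sided rules coincide).

Group comparisons report both group medians and sizes alongside the
p-value; human-readable output rounds p to 2 significant figures, machine
output keeps full precision. No multiple-testing correction is applied.
`overlap_fraction(a, b)` reports the percentage of sample *b* strictly
below the median of *a*, the descriptive overlap measure used alongside
the tests.

Severe fractions are reported as half-up-rounded integer percentages,
matching how such percentages are conventionally printed.

## Background accounting

An individual's burden over the panel counts one unit per
(individual, gene, variant) triple — multi-allelic or repeated records
collapse to one, and zygosity is ignored (the emulated cohort is male, so
X-linked focal genes are effectively hemizygous). "Mutated protein" means
≥ 1 missense variant in that gene. Two totals are emitted per individual —
with and without focal-gene variants — so burden histograms are
recomputable under either inclusion convention. A focal variant's
background for one carrier is the carrier's panel variant count minus the
focal variant itself; other variants in the same gene (cis) stay included,
and both the all-variant and pathogenic-only background counts are always
reported. The `pathogenic_only` switch restricts the output rows to focal
variants themselves annotated pathogenic, mirroring the pathogenic-only
view of the per-variant range analysis. Variants with ≥ 2 carriers are
flagged, since only those span a non-trivial min–max range.

Unknown-pathogenicity variants count as neutral in the composition summary
by default — the emulated annotation source records pathogenic variants,
so absence of an annotation means "not annotated pathogenic" — with a
strict mode keeping them separate. The default 19-gene panel includes the
six genes with documented prevalence behaviour (F8, F9, VWF, F12, KNG1,
GP1BB) plus thirteen canonical hemostasis-cascade genes; it is a synthetic
stand-in roster, and any panel can be supplied as a one-symbol-per-line
file.

## The synthetic-data generator

The generator's defaults are the study conditions: one FVIII-scale gene
(2351 residues, 25 species, 971 pathogenic variants of which 122
compensated), a 1.0 kcal/mol ΔΔG shift between groups (CPD
~ 𝒩(0.8, 1.0²), noCPD ~ 𝒩(1.8, 1.2²), destabilising positive), severity
drawn from P(severe) = expit(0.9·ΔΔG − 1.5) so the overall severe fraction
sits near one half, RSA uniform on (15, 95) for CPDs vs (0, 75) for
noCPDs (CPDs more exposed), and a cohort of 1233 males across five
superpopulations with weights approximating the source population
(AFR 0.27, AMR 0.14, EAS 0.20, EUR 0.19, SAS 0.20).

Per-site conservation uses a two-state mixture: the human residue with
frequency q, the other 19 residues uniform, with q obtained by inverting
the mixture entropy on a grid; site target entropies default to
Uniform(0.3, 3.0). This matches a target entropy *profile* approximately —
realised column entropies fluctuate with the number of species — and is
deliberately simpler than simulating substitutions down a phylogeny:
generated columns have no tree-induced covariance between species, no
rate variation across lineages, and no correlated indel structure. Tests
passing on this generator therefore demonstrate correctness of the
*accounting* (mapping, counting, planting recovery, test calibration), not
robustness to real phylogenetic structure. Compensations are planted by
writing the mutant residue into 1–3 random ortholog rows at the variant's
column; for noCPD variants any chance occurrence of the mutant residue in
an ortholog row is scrubbed back to the wild type, making planted labels
exactly recoverable by construction — which is what lets classifier
precision/recall be asserted at exactly 1.0. Variant positions are unique
per gene so no two variants share a column. Insertion columns (human gap,
~3% of sites) exercise the position↔column mapping; ortholog rows also
carry ~1% random gaps.

The cohort generator assigns each panel gene a small allele-frequency
spectrum (VWF and F12 nearly always mutated, KNG1 and GP1BB rare,
intermediate genes at ~0.33 per-gene prevalence, chosen so the expected
per-individual burden lands in the observed 5–20 range with a mode near
6–7 mutated proteins); presence is an independent Bernoulli draw per
(individual, variant) — no linkage — and each roster variant is flagged
pathogenic with probability 0.25. All expectations used in tests are
computed from the recorded roster (frequencies and flags), not from
hard-coded numbers.

Determinism: every stage draws from `numpy` generators seeded by
`SeedSequence([seed, stream])` with a fixed stream id per stage, so a
configuration yields byte-identical output files across runs and
platforms, and regenerating one stage never perturbs another.

## Numerical and design notes

* The exact-test tie slack (1e-7 relative) only matters when two tables'
  point probabilities are mathematically equal; float pmf error (~1e-15
  relative) is far inside it.
* The half-up percent rounding uses `floor(x + 0.5)` rather than banker's
  rounding.
* Simulation sizes in the test suite: the exhaustive Fisher sweep covers
  canonical margin classes (r₁ ≤ r₂, c₁ ≤ c₂) up to total 60, ~150k
  tables; the permutation oracle uses 10⁵ label permutations at n = 30 per
  group; null calibration uses 200 simulations at n = 80–100 per group,
  where the exact tests' discreteness keeps the rejection rate at or below
  the nominal 5% — the assertion is one-sided-above plus a non-degeneracy
  floor. Pipeline-level checks run at the full study scale (971 variants,
  1233 individuals), which completes in seconds.
* Variant positions are trusted as sequence coordinates; reconciling
  database legacy numbering is the caller's responsibility.

## Known limitations

* The classifier is as good as the MSA: alignment errors or paralog
  contamination produce spurious compensation calls; no alignment-quality
  masking is applied.
* ΔΔG and RSA are consumed as given; the pipeline does not run stability
  or accessibility computations, and their known estimation error is not
  propagated into the tests.
* The generator's independence assumptions (no linkage, no phylogenetic
  covariance) make it unsuitable for studying those phenomena; it exists
  to validate the pipeline's bookkeeping and statistical calibration.
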
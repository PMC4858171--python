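# Methods

## Scope and data model

The package operates on tidy long-format tables of per-sample, per-gene
measurements keyed by (strain, condition, timepoint, replicate), with a
`value_kind` marker (`ct`, `relative_expression`, `fold_change`,
`log2_fold_change`). Missing measurements are absent rows, never sentinel
numbers; every downstream statistic uses pairwise-complete data and
reports the sample count it actually used. Every pipeline stage logs its
input/output row counts and exclusions so sample-count provenance is
auditable.

The default design is 9 strains (wild type 704; AI mutants cyg56, cdp1,
20.40, 54.10, 258.90, 259.89; CSA mutants N10, N24) × 4 nitrogen contexts
(NO₃ 4 mM; NH₄ 8 mM; NO₃ 4 mM + NH₄ 8 mM; NO₃ 4 mM + NH₄ 1 mM) × 4 harvest
times (0.5, 1, 3, 24 h) = 144 samples, assayed for a 12-gene panel with
CYG56 as the correlation reference and a ubiquitin-ligase transcript
(`UBQL`) as the qPCR internal standard. Condition labels are fixed
spellings (`NO3_4mM`, …) so tables are joinable; times are stored as
decimal hours so sorting is numeric. The panel's first subset contains two
configurable placeholder slots (`CG_A`, `CG_B`) whose identity the design
does not fix. The gene → mutant map is partial: genes identified in
mutants that were never profiled (e.g. 42.49CG1 in strain 42.49)
contribute no exclusions.

## Quantification

Ct values convert to relative expression via the comparative-Ct form
`x = E^(Ct_ref − Ct_target)` against the internal standard of the same
sample. Amplification efficiency is fixed at E = 2 (perfect doubling) by
default and exposed as a parameter in (1, 2]; no standard-curve or
multi-reference normalization is attempted. Normalization happens per
well; replicates are aggregated afterwards with the arithmetic mean and
the n−1 sample standard deviation (0 when n = 1). Cts are valid in
(0, 40]; non-detects above the cap are treated as missing.

## The co-expression screen

**Centring granularity.** Values are mean-centred per (gene, condition,
timepoint) cell, not per condition pooled over time: the aim is to remove
environmental variation, and pooled centring would leave the time signal
in place. The cell mean is the arithmetic mean of linear-scale relative
expression; the log2 transform happens strictly after centring. Cells
with fewer than two strains, or an all-zero mean, yield missing outputs
(with a logged warning). After centring, the across-strain mean of every
surviving cell is exactly 1 (asserted to 1e−12 in tests).

**Zero handling.** Fold changes below a configurable floor (default 2⁻¹⁰)
are floored before log2 rather than dropped, so knockout-level values in
non-excluded strains stay informative.

**Exclusions.** For the pair (g, reference), samples from g's own profiled
mutant and from the reference's own mutant are removed (`pair_exclusion=
"union"`, the default — a sample must be admissible for both members of
the pair; `"per_gene"` keeps the reference's mutant and is provided
because the per-gene reading is also defensible). A user leave-out set is
unioned in for leave-strain-out robustness checks. With the default
design and no missing data this gives n = 128 for a gene without a
profiled mutant and n = 112 when one strain is left out — consistent with
inverting the two-sided Pearson t-transform at a reported
(R² = 0.343, p = 2.24 × 10⁻¹¹) pair, which lands within ±0.007 of the
reported R² for n near 112. Because missing wells can change n, results
always carry their n explicitly rather than assuming a count.

**Statistics.** r is the sample Pearson coefficient (scipy); the
two-sided p comes from `t = r·√((n−2)/(1−r²))` on n−2 df. Two-sided is
the conservative default since sidedness is a reporting choice. |r| = 1
(and p-underflow) report the smallest representable positive double
rather than 0. No multiple-testing correction is applied across the
candidates — the screen reports raw per-pair p-values. Results are sorted
by r² descending with a lexicographic gene tie-break; per-gene
degeneracies (constant vector, n < 3) become flagged rows instead of
aborting the screen, and the reference-vs-itself pair is emitted as a
control row with r² = 1.

## Misregulation profiles

Per (mutant, gene), the arithmetic mean of the strain's linear fold
changes over all its condition × time samples (16 in the default design)
is compared to a threefold cutoff with strict inequalities: a mean
exactly at 3.0 is highlighted by neither flag (the cutoff is a highlight
zone, not a test). Averaging over all samples makes the profile robust to
misregulation confined to a single condition: corrupting one of 16
unit-valued points by any factor within [1/3, 3] can never flip a flag.
A geometric-mean option is provided (it is exactly symmetric under
v → 1/v, which the linear mean is not); linear is the default because the
screen averages data already expressed as fold change. The wild type is
excluded from profiles but included in the centring means. No
per-condition significance testing is attached; the profile screen is
descriptive.

## Response reporting

Percent-of-control is `100·value/control` (control > 0). The two-sample
comparison is the equal-variance Student t with pooled variance on
n_a + n_b − 2 df (Welch's form is an option), two-sided, with
significance recorded against α (default 0.05). The pooled form is the
default because it is the classical "Student t test" and tolerates a
single-observation comparison group; an exact permutation enumeration is
used as an oracle in the tests.

## Synthetic data

The generator draws, for each sample and gene,

    log2 x = baseline(g) + condition(g, c) + time(g, t) + genotype(g, s) + ε,
    ε ~ N(0, σ²),  x clipped below at the detection floor,

with one PRNG stream per dataset (sample-major, gene-minor draw order;
identical seed ⇒ bit-identical table). Gaussian log2 noise (multiplicative
lognormal) matches the log2 analysis space; heavier-tailed noise would be
a config extension, not the default. A gene in its own profiled mutant
ignores the model and sits, noise-free, at the knockout floor (2⁻¹⁰ by
default) — emulating transcript loss by insertion. The null generator
strips genotype effects and knockouts, leaving condition/time/noise only,
so no genotypic co-regulation exists by construction.

The shipped `paper_like.yaml` encodes the qualitative structure the
screen expects to resolve: ammonium induction of CYG56 and CDP1 (+2/+1.5/
+1 log2 by ammonium context, −1 at 24 h), a strong shared-regulator
downshift in strain 54.10 (−3 log2 on CYG56, CDP1 and 42.49CG1; −1 on
85.37CG), stable genes untouched, and knockouts for the four genes whose
own mutants are profiled. Directions are fixed by the biology being
emulated; the magnitudes and the noise σ = 0.5 log2 units are package
defaults chosen as plausible qRT-PCR-scale values, and recovery tests
treat σ as a free parameter. Under these defaults the three planted
co-regulated genes take the top three r² ranks and the 54.10 knockdown
is flagged down in ≥ 95 of 100 seeds.

**What the generator does not emulate:** pipetting/plate batch effects,
amplification-efficiency variation between genes, correlated noise across
genes within a sample beyond the planted structure, censoring at high Ct
(unless the Ct layer is used), or biological replicate structure in the
144-sample screen (the replicate dimension defaults to 1). Passing the
recovery and calibration tests therefore shows the pipeline's statistics
behave correctly under the model's assumptions, not that real data meet
them.

## Numerical and calibration notes

* Write-then-read of a table is bit-identity (floats serialized with
  `repr`, parsed in round-trip mode); `quantify ∘ ct_layer` is the
  identity on noise-free positive tables to 1e−12.
* Because cell-mean centring introduces a mild negative within-cell
  dependence (each 9-strain cell loses roughly one degree of freedom),
  nominal p-values on effect-free data are slightly anti-conservative:
  the fraction below 0.05 sits near 0.06, within the [0.03, 0.07] band
  asserted by the calibration test. Null calibration runs use several
  thousand null genes to keep the Monte-Carlo error of that fraction
  small relative to the band.
* Acceptance and calibration problem sizes (6000 null genes, 100 seeds,
  50 oracle tables) keep the whole suite in tens of seconds on one CPU.

## Known limitations

* The screen is pairwise-vs-reference only; no partial correlations or
  network inference.
* The comparative-Ct model assumes a single stable internal standard.
* Flags and correlations are not corrected for multiple testing; users
  comparing many panels should apply their own correction downstream.
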
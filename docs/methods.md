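# Methods

## Scientific setting

`hybridmorph` analyses body-size measurements in an admixed colony of
Chinese × Indian rhesus macaques (*Macaca mulatta*): 134 adults (92
female, 42 male) whose pedigree-recorded fraction of Chinese ancestry
*A* spans 0–1 in eighths, with 19 full-bred Indian, 13 full-bred Chinese
and 102 hybrid animals. Six raw measurements are analysed — weight (kg)
and crown-rump, humerus, radius, femur and tibia lengths (mm) — plus two
per-individual composites, forelimb = humerus + radius and hindlimb =
femur + tibia. The analytical question is whether hybrids show
transgressive size (heterosis or dysgenesis) or heightened variation
relative to the additive expectation implied by their ancestry.

## Pipeline

### Sex adjustment

Sexes are pooled to preserve ancestry-group sample sizes. Because the two
lineages differ in sexual dimorphism, the male−female mean difference is
computed separately in each full-bred group and in the pooled hybrids,
and added to every female value; males are untouched. After adjustment
female and male means coincide exactly within each adjustment group, and
recomputed offsets are identically zero (idempotence). Offsets are
computed on the raw measurements; composites are re-derived afterwards so
forelimb ≡ humerus + radius stays exact. A per-ancestry-bin scheme is
available but raises an error when a bin lacks one sex (several bins in
the modelled composition contain no males), rather than silently applying
a zero offset.

A statistical caveat this package measures rather than hides: lifting
all females by the estimated offset makes the adjusted group mean equal
the *male-only* mean algebraically, so its sampling variance is σ²/n_M,
not σ²/n. One-sample t tests that treat adjusted values as n independent
observations are therefore anticonservative by roughly √(n/n_M). See
"Calibration design" below.

### Additive expectation and parity

Under a polygenic model with many loci of equal, additive effect (no
dominance, no epistasis), an individual with Chinese-ancestry fraction A
carries a fraction ≈ A of Chinese-derived alleles at trait loci, so its
expectation is the ancestry-weighted mean of the full-bred means:

    E[y | A] = (1 − A) · x̄_Ind + A · x̄_Chi

Deviations (actual − expected) place each hybrid above or below the
parity line. Per measurement the package reports above/below/on counts,
the mean deviation, and — as an explicit extension beyond the graphical
comparison — a two-sided exact binomial sign test on the above/below
counts (ties excluded). Transgression is classified both against the
interval spanned by the two parental means and against the observed
parental min–max range, with closed intervals (boundary values classify
inward).

### Dispersion

V = 100·sd/mean (n−1 sd) with the small-sample correction
V* = (1 + 1/(4n))·V. CV equality between groups is tested on corrected
CVs as proportions, c = V*/100, with a t-type statistic. The default
variance is evaluated at the df-weighted pooled CV under the null
(Miller-type test):

    t = (c_a − c_b) / sqrt( c̄²(0.5 + c̄²)(1/(n_a−1) + 1/(n_b−1)) ),  df = n_a + n_b − 2.

A "separate" rule using each sample's own plug-in variance is provided
for comparison, but because each sample's plug-in variance co-varies with
the numerator it is badly tail-asymmetric at small n (measured one-tailed
type-I error ≈ 0.015 and ≈ 0.096 in the two directions at n = 13 vs 102,
versus 0.043/0.056 for the pooled rule, which is why pooled is the
default). Directions are always supplied a priori — the battery tests
"hybrids more variable", never the observed sign.

### Size battery

For each of the six raw measurements (composites excluded as linear
combinations), three one-tailed comparisons, Bonferroni-corrected within
each block at α/m with m = 6 (α = 0.05 → 0.0083):

1. hybrids vs the smaller full-bred mean (direction: smaller);
2. hybrids vs the larger full-bred mean (direction: smaller);
3. per-individual deviations from the additive expectation vs zero.

Blocks 1–2 run either as one-sample t tests against the parental mean
treated as a constant (df = n−1) or as independent two-sample tests
against the parental sample (pooled df = n_a + n_b − 2, or Welch);
both modes can be reported side by side, labelled. The mid-parental
block is always a one-sample test on deviations. Degrees of freedom are
printed explicitly in all reports. An option runs both tails and doubles
m. Cells that cannot be tested (n < 2, missing parental reference) are
reported with a note instead of failing the run.

## Synthetic colony generator

The simulator exists so that every pipeline stage can be tested and
calibrated against known truth. Each measurement is controlled by L loci
(default 100; the additive algebra scales exactly in L, and one test
exercises L = 10,000). Per individual, allele ancestries are assigned
deterministically (round(2LA) Chinese alleles, spread evenly across
loci) or stochastically (each allele Chinese with probability A —
"realized ancestry"). Allelic effects are drawn per allele from
N(a_lineage, allele_effect_sd); the additive parental means are
μ = 2L·a. Dominance adds d per heterospecific locus; with realized
ancestry the expected shift is 2A(1−A)·L·d (maximal at A = ½, zero in
full-breds), while the deterministic even spread gives min(C, 2L−C)
heterospecific loci. A lineage-specific male−female offset (interpolated
linearly in A; females are the baseline) and N(0, env_sd) environmental
noise complete the trait; non-positive draws are resampled and logged.

Defaults emulate the modelled colony: its exact bin-by-sex composition;
parental means taken from the published group-mean table; total
phenotypic sd calibrated so group CVs land near the published V* values
(target sd = mean published V* across groups × mid-parent mean), split
50/50 between allelic-effect spread and environmental variance. The
variance split and the dimorphism offsets (weight ≈ 2.4–3.2 kg, lengths
≈ 8–30 mm, Indian lineage slightly more dimorphic) are calibration
choices of this package — the underlying study publishes no
within-lineage allelic variance or per-lineage dimorphism — and are
fixed once here, not tuned per analysis.

What the generator does *not* emulate: cross-trait correlation (each
measurement draws independent loci), age structure, shared environments,
multi-generation pedigrees with linkage and recombination, and
antagonistic-QTL transgression via recombination (allelic heterogeneity
is present through `allele_effect_sd`, but recombination is not
modelled). Passing tests therefore validate the statistical machinery
under the stated model, not the biology of any particular colony.

## Calibration design

`power_analysis` plants dominance on a grid expressed as L·d in units of
each measurement's environmental sd (dominance has trait units, so a
shared scalar must be scaled per measurement), simulates colonies, and
measures how often the mid-parental battery block flags the planted
direction at the Bonferroni-adjusted level; the grid's zero entry is the
empirical type-I error. Two deliberate choices:

* The battery is evaluated against the **true** sex-specific additive
  expectations from the simulator, on unadjusted values. Estimated
  parental means (n = 19 and 13) contribute shared reference error with
  variance far exceeding σ²/102, and add-offset sex adjustment collapses
  the adjusted mean's variance to σ²/n_M (see above); either effect
  would swamp the test's intrinsic calibration. With the true reference
  the d = 0 family-wise rate matches the Bonferroni expectation
  1 − (1 − α/6)⁶ ≈ 0.049 (measured ≈ 0.046 at 2,000 replicates).
* Strongly planted effects are heterotic (d > 0) in calibration studies:
  a dysgenic shift of 10 environmental sd would push weight below zero
  (the trait floor), truncating the model. Dysgenesis recovery is
  exercised at milder magnitudes (|L·d| = 4–5 × env sd) where positivity
  is unaffected.

Monte-Carlo problem sizes used by the test suite and the acceptance
script — 2,000 null colonies, 500 planted-effect colonies, 10,000
CV-test replicates, 10,000 p-uniformity replicates — were chosen so
seeded rates have standard errors well below the decision margins
(e.g. SE ≈ 0.005 on the null family-wise rate against a [0.025, 0.1]
acceptance band). All stochastic checks fix seeds and use 2–3 SE
tolerances.

## Numerical conventions

* Standard deviations use the n−1 denominator throughout (required by
  the small-sample CV correction context); sd is undefined (NaN) for
  n = 1.
* Missingness is casewise per measurement, never listwise; composites
  are missing iff a component is missing.
* Ancestry is stored as a fraction; percent input columns
  (`chinese_ancestry_pct`) are auto-detected by name and rescaled.
  Ancestry values are not snapped to eighths — arbitrary fractions are
  accepted, so realized-ancestry simulations and future genomic
  estimates fit the same schema.
* Group labels derive from ancestry alone: exactly 0 → Indian, exactly
  1 → Chinese, otherwise hybrid.
* CSV reads use round-trip float parsing so that write → read is
  bit-exact; human-readable reports round to two decimals while all
  machine-readable outputs keep full precision. Report bundles contain
  no timestamps, making fixed-seed runs byte-identical.
* Boundary values in transgression classification are inward
  ("between"/"within"); parity ties count as "on" and are excluded from
  the sign test.

## Known limitations

* The one-sample battery inherits the reference-as-constant assumption;
  with small full-bred samples its nominal level is optimistic (measured
  and documented above, not corrected). The two-sample mode is the
  conservative alternative and is reported alongside on request.
* The CV-equality test is asymptotic and normal-theory; heavy-tailed
  data will distort its level.
* Pedigree ancestry is taken as given; discrepancy between pedigree and
  realized genomic ancestry is only representable through the
  simulator's realized-ancestry mode.
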
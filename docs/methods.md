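# Methods

This note documents the models implemented in `abatime`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user re-deriving results should
know about.

## Study design and data model

All statistics operate on an `ExpressionMatrix`: normalized log2
intensities, genes × samples, each sample annotated with condition
(`treated` vs. `control`), timepoint in minutes and replicate number.
The canonical design is 2 conditions × 3 timepoints (30/60/180 min) × 3
replicates.  Values must be finite after loading; the loader rejects
missing cells by default (per-gene mean imputation is available behind a
flag, because silently imputing hides data problems).  Gene identifiers
are opaque, case-sensitive strings; no normalization across naming schemes
is attempted.  Every statistical operation requires at least two
replicates per (condition, timepoint) group.  A time-0 anchor sample is
permitted by the data model but not required by any operation.

## Pairwise regularized t-test

Per-gene replicate variances at n = 3 are too unstable for a plain
t-test, so each group variance is shrunk toward a local background: genes
are ordered by the group's mean expression and the background σ²_bg is the
mean sample variance over a sliding window of `window_size` genes
(default 101).  At the edges the window slides within bounds (the
first/last full window), so it always covers exactly `window_size` genes;
with `window_size` equal to the gene count, every gene receives the global
mean variance.  The window is computed separately per
(condition, timepoint) group, since variance structure is group-specific.

The regularized variance uses a prior weight of ν₀ pseudo-observations
(default 10):

    s̃² = (ν₀·σ²_bg + (n−1)·s²)/(ν₀ + n − 2)    for ν₀ > 0.

At ν₀ = 0 the prior-free limit returns the ordinary sample variance s²,
so the statistic reduces exactly to the standard two-sample t-test
(identical to the pooled test for balanced groups); this limit is the
main correctness anchor in the tests.  The statistic and its reference
distribution are

    t = (m_t − m_c)/√(s̃²_t/n_t + s̃²_c/n_c),   df = n_t + n_c − 2 + 2ν₀.

If both regularized variances are zero the gene is flagged degenerate and
assigned p = 1 rather than raising.  Multiplicity: Benjamini–Hochberg
step-up per timepoint; q exactly at the cutoff counts as called (the
cutoff is read as ≤ 0.05).  Direction is the sign of the mean difference;
fold changes are reported for all genes at all timepoints in the signed
negative-reciprocal convention (r = 2^Δ if ≥ 1, else −1/r), so a value
never falls in the open interval (−1, 1).

Temporal classes are a pure function of the per-timepoint directions:
(up,up,up) early-sustained, (up,up,none) early-transient, (none,up,none)
mid-transient, (none,up,up) mid-sustained, (none,none,up) late-up,
(none,none,down) late-down, all-none none, and anything else `mixed` so
the classifier is total over all 3³ patterns.

## Nested polynomial ANOVA

For each gene, expression is modelled as a polynomial in time (raw
minutes, centered; an orthonormalized basis is used internally for
conditioning — the reported F is basis-independent).  The reduced model
pools both conditions into one degree-d curve (d+1 parameters); the full
model fits fully separate curves per condition (2(d+1) parameters,
including separate intercepts).  The requested degree (default 3) is
capped at T−1 for T distinct timepoints, since a cubic is rank-deficient
on three time levels; a time-0 anchor would raise T to 4 and enable the
full cubic.  The F statistic compares residual sums of squares with
(df_red − df_full, df_full) degrees of freedom; RSS_full ≈ 0 (below
1e−12) is flagged `exact_fit` with p = 0.  Replicates are treated as
independent observations; no replicate random effect is modelled.

FDR defaults to Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) over
λ ∈ {0.05, …, 0.95}, smoothed by a cubic polynomial and evaluated at the
largest λ, clipped into (0, 1] (degenerate estimates fall back to π₀ = 1
with a warning); q-values are the π₀-scaled step-up, so forcing π₀ = 1
reproduces BH exactly.  Time-course calls use a strict q < 0.001.

Under the study design (18 samples, 3 timepoints) the q < 0.001
time-course threshold is substantially harsher than the pairwise q ≤ 0.05,
so on strongly saturated planted effects the pairwise analysis can call
marginally more genes.  The time-course test's advantage — pooling
evidence across all timepoints with the gene's own variance — manifests at
moderate effect sizes with strongly heterogeneous gene variances, where
the regularized pairwise test shrinks away the evidence of low-noise
genes; the `moderate_effect_config` preset (0.75 log2FC effects, noise-SD
shape 3) encodes that comparative design.

## Global subset dynamics

Genes are ranked by the variance (ddof 1) of their treated per-timepoint
mean profile, strongest response first, ties broken lexicographically for
determinism.  Control samples do not enter the default ranking ("response
after stimulation"); a treated-minus-control variant is available and is
the right choice when sustained (flat but shifted) responses matter, since
a constant elevated profile has zero temporal variance.

The association profile of a gene set collects, for every ordered pair of
distinct (condition, timepoint) group-mean vectors (canonical order:
control before treated, timepoints ascending; 30 pairs in the full
design), the Pearson correlation and the mutual information across genes.
MI uses equal-frequency binning with ties resolved by stable rank (hence
invariance under strictly monotone transforms) and the plug-in joint
histogram estimator, in nats; bins default to max(4, ⌊√subset size⌋).
Constant vectors are degenerate and define MI = 0 (PC = 0) with a warning.
Subsets are canonicalized to matrix row order before computation, so the
profile is bit-identical under permutations of the subset.

The distance between a window's profile and the whole-transcriptome
profile is Euclidean over all pairs, with MI terms divided by log(bins)
(the maximal attainable MI at that resolution) to make them commensurate
with correlations; the normalization is configurable, including "none".
Because MI depends on the binning resolution, the all-gene reference is
recomputed at each window size's bin count.  Windows use the size grid
{50, 100, 200, 300, 400, 500} with stride size/2 (the tail of the ranking
is always covered); a least-squares polynomial trend in start rank
(degree 3) summarizes the curve.  Contributing genes are the union of the
top (1 − 0.9) fraction of the ranking and all genes of windows whose
distance lies below the 0.25 quantile of the fitted trend; both quantiles
are monotone (loosening never removes a gene).

Sample PCA centers genes and decomposes the samples × genes matrix by
SVD; scores and variance-explained fractions are returned.

## Synthetic data

The generator emulates the study design directly: per gene a baseline
drawn N(8, 2²) log2 units, one response archetype with per-timepoint log2
fold changes added to the treated condition only (defaults: ±2 log2
units; down-regulation only as a late archetype, matching the observed
asymmetry of early responses), and additive Gaussian noise with a
gene-specific SD drawn once per gene from a scaled inverse chi-square
(variance = scale²·shape/χ²_shape; defaults scale 0.25, shape 10, so
typical SDs sit near 0.25–0.3 with realistic gene-to-gene spread).
Heterogeneous variances are deliberate: they are exactly what the
regularized t-test exists for.  Archetype counts follow largest-remainder
apportionment of the configured fractions (default 25% responders, mix
loosely mirroring the reported class sizes); placement is randomized.
Identical seeds give bit-identical output.

Not emulated: probe-level array physics, dye/batch effects, missingness,
and between-gene noise correlation.  Passing tests therefore demonstrate
calibration and recovery under clean heteroscedastic Gaussian noise, not
robustness to array artifacts.

Two presets encode specific study designs.  `planted_dynamics_config`
(10% responders restricted to archetypes with non-flat treated profiles,
baseline SD 0.25) makes the planted responders dominate the concerted
transcriptome change, which is the regime the subset-distance statistic
is designed for — with a large baseline spread the global association
profile is dominated by baseline correlation and the direction of the
distance contrast is not identified.  `moderate_effect_config` is the
pairwise-vs-time-course comparison design described above.
`make_study_lists` derives external-study DEG lists from the truth with
configurable dropout and contamination for set-comparison tests.

## Set comparison and enrichment

Venn/UpSet partitions are exact exclusive-region memberships computed by
a per-element scan (2–8 sets).  Ortholog collapse consumes a two-column
single-best-hit map; outputs are the deduplicated image, the unmapped
inputs, and paralog groups (preimages of size ≥ 2).  The specificity
filter requires the minimum over target replicates to exceed the maximum
over all other samples.  Summary-statistics t-tests support pooled and
Welch variants; Welch is the default since printed group SDs typically
differ.  Degenerate zero-variance summaries return p = 1 (equal means) or
a flagged p = 0.

Enrichment tests each term's 2×2 table with the two-sided Fisher exact
test (sum of hypergeometric probabilities no larger than the observed
table's), covering over- and under-representation in one test; direction
is read off the fold enrichment (k/n)/(K/N).  One-sided alternatives are
exposed by flag.  The background defaults to the annotation universe and
can be replaced by the expression-matrix gene universe.  Terms need K ≥ 2
background genes and either k ≥ 1 or expected count ≥ 1.  Bonferroni
q = min(1, p·m) over the m tested terms, significant at q < 0.05.

## Pipeline

`run_pipeline` executes stages from one YAML config in dependency order
(simulate → deg → timecourse → dynamics → compare → enrich), writes TSVs
plus a JSON manifest (config snapshot, input digests, per-stage row
counts, seed), and fails fast naming the offending stage.  One global
seed expands into per-stage substreams via `SeedSequence([seed, stage
index])`, so stages re-run in isolation reproducibly and a fixed config
yields byte-identical outputs.

## Problem sizes and numerical choices

Tests and the acceptance script use 1,000–10,000-gene simulations: 2,000
genes for recovery suites, 10,000 null genes for ANOVA type-I
calibration, five to twenty seeds for the dynamics properties.  Numerical
tolerances: RSS comparisons at 1e−12 (exact-fit flag), prior-free t-test
equivalence at relative 1e−10, MI/PC permutation invariance exact by
canonical ordering.  BH and Storey q-values are computed by stable-sorted
step-up with clipping at 1; Fisher p-values delegate to the exact
hypergeometric routine and are verified against explicit enumeration in
tests.

## Known limitations

- The MI estimator is the binned plug-in; its positive bias
  (≈ (bins−1)²/2n nats) is acceptable at subset sizes 50–500 but the
  estimator is not suitable for very small subsets, hence the bins ≥ 4
  floor and the subset ≥ bins requirement.
- The temporal-response ranking is blind to sustained flat shifts by
  construction; use the treated-minus-control variant when those matter.
- No moderated-t alternatives, spline/autoregressive trajectory models,
  GO-graph propagation, or ortholog inference; external maps and
  pre-propagated annotations are consumed as files.
- The three-timepoint design caps the polynomial at degree 2; stated
  degree-3 behavior requires a fourth time level.
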
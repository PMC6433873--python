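# abatime

Analysis toolkit for two-condition time-course transcriptomics, built
around the early transcriptional response of the moss *Physcomitrella
patens* to the stress hormone abscisic acid (ABA).  Exogenous ABA drives
protonema cells toward thick-walled vegetative diaspores (brachycytes);
the decision is made within the first three hours, so the interesting
signal sits in a short time course: treated vs. mock control at 30, 60 and
180 min, three replicates each, measured as normalized log2 intensities.

The package is for computational biologists who want each stage of such an
analysis as a tested, reusable function: calling differentially expressed
genes (DEGs) per timepoint, classifying their temporal patterns, testing
whole-trajectory differences, quantifying how much of the global
transcriptome shift a ranked gene subset carries, comparing DEG sets
across studies and species, and running term enrichment — all exercisable
on synthetic data with planted ground truth.

## Methods at a glance

**Pairwise DEG calling** (`abatime.degcall`) uses a Bayesian-regularized
t-test in the Cyber-T style.  For each replicate group the sample variance
s² is shrunk toward a local background σ²_bg (mean sample variance of the
`window_size` genes nearest in mean expression):

    s̃² = (ν₀·σ²_bg + (n−1)·s²) / (ν₀ + n − 2),
    t  = (m_t − m_c) / √(s̃²_t/n_t + s̃²_c/n_c),   df = n_t + n_c − 2 + 2ν₀

with defaults window = 101, ν₀ = 10.  Benjamini–Hochberg FDR is applied
per timepoint (calls at q ≤ 0.05); the per-timepoint call pattern maps to
a temporal class (early sustained/transient, mid transient/sustained, late
up/down).  Fold changes use the signed negative-reciprocal convention
(−5.06 = 5.06-fold down), so |fc| ≥ 1 always.

**Time-course testing** (`abatime.timecourse`) fits nested polynomial
models in time per gene — reduced: one shared curve; full: separate curves
per condition — and compares them with the standard F statistic

    F = ((RSS_red − RSS_full)/(df_red − df_full)) / (RSS_full/df_full),

with the polynomial degree capped at T−1 for T distinct timepoints.
FDR uses Storey q-values (π₀ estimated by a smoother) or BH; calls at
q < 0.001.

**Global subset dynamics** (`abatime.dynamics`) ranks genes by the
variance of their treated per-timepoint profile, slides windows of 50–500
genes along the ranking, and computes each window's Euclidean distance to
the whole transcriptome in the space of pairwise Pearson correlations and
mutual information (equal-frequency-binned plug-in estimator, MI terms
scaled by log bins) between all (condition, timepoint) group-mean vectors.
Windows behaving like the whole transcriptome carry the concerted
response.  Sample-level structure is summarized by PCA.

**Set comparison and enrichment** (`abatime.compare`, `abatime.enrich`)
provide exact Venn/UpSet region partitions, many-to-one ortholog collapse
(paralogs merge onto their shared best hit), a strict group-specificity
filter, t-tests from printed summary statistics, and Fisher-exact term
enrichment with Bonferroni correction.

**Synthetic data** (`abatime.synthdata`) generates the full design with
planted response archetypes, gene-specific heteroscedastic noise and a
ground-truth table, so every stage is testable without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate.py` through `06_enrichment.py`),
writing tables under `results/`.  On the default design (2000 genes, 25%
responders at 2 log2FC, SD ≈ 0.25, seed 2024) the pairwise step prints:

```
pairwise DEG counts (q ≤ 0.05):
   30 min: 145 up, 0 down
   60 min: 328 up, 6 down
  180 min: 342 up, 44 down
recovery of planted responders: sensitivity 1.000, empirical FDR 0.038
```

i.e. every planted responder is recovered at its active timepoints and
3.8% of calls are false — within the q ≤ 0.05 target.  The time-course
step calls 477 genes at the much stricter q < 0.001 (sensitivity 0.954),
and the printed-table / morphometry re-analysis prints:

```
early-gene table: 14 sustained, 2 transient of 16 rows; 7 annotated Unknown
biosynthesis section: affected genes ['Phypa_173118', 'Phypa_57876']
cell-wall thickening: 43% (43.24%); Welch t = 3.901 (df 18.3), two-sided p = 1.02e-03
```

— the two ABA-inducible NCED genes are the only affected biosynthesis
entries, and the 53 ± 11 vs 37 ± 8 μm wall-thickness summaries (n = 11)
give a significant 43% increase.

The same stages run from one YAML config (`abatime run --config run.yaml`)
or as individual subcommands (`abatime simulate|deg|timecourse|dynamics|
venn|orthologs|specific|enrich`).

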
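# Methods

This note documents the models and procedures implemented in `microstab`,
the assumptions behind the synthetic-study generator, the defaults that
matter, and the numerical choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being emulated

A two-arm dietary intervention in gestating sows: control (CON) vs
fibre-supplemented (DF), 16 subjects per arm, faecal 16S profiles at six
timepoints — gestation days 0/30/90/109 and lactation days 3/14 — with
per-sow litter outcomes (total born, born alive, healthy). All analyses
operate on genus-level count tables; taxonomy handling (rank collapsing,
`un_f__…` buckets for unresolved assignments) follows the conventions of
common amplicon exports.

## Synthetic-data generator

`simulate_study` draws, per sample,

1. log basis abundances `μ + L z + b_{s} + e_{a,t}` where
   - `μ` are per-taxon log means drawn once per configuration from
     N(0, 1.5²) — a heavy spread producing the strong dominance structure
     (few abundant, many rare genera) typical of gut communities;
   - `L` is the Cholesky factor of the planted basis correlation matrix
     (identity plus `n_correlated_pairs` disjoint off-diagonal pairs at
     `pair_rho`; positive definite for |ρ| < 1 since each 2×2 block has
     eigenvalues 1 ± ρ);
   - `b_s` are per-subject, per-taxon random intercepts with SD
     `subject_sd` (default 0.3). A scalar per-subject shift common to all
     taxa would cancel exactly under closure and leave nothing for the
     mixed model's random intercept to absorb, so the intercepts are
     taxon-specific; `GroundTruth.subject_effects` stores the full
     subjects × taxa matrix;
   - `e_{a,t}` are the planted arm × timepoint effects, specified in log2
     units and applied on the natural-log scale;
2. closure to fractions, then multinomial counts at a depth drawn
   log-normally around `depth_mean` (default 30,000 reads, log-SD 0.3,
   emulating Illumina depth variation; zero dispersion yields exact
   depths). Zeros arise naturally from multinomial sampling — there is no
   explicit zero-inflation term, which is sufficient to exercise
   pseudocount handling downstream.

Outcomes are per-subject linear combinations of the subject's mean **log**
relative abundances of designated taxa at a designated timepoint (default
G109, matching the late-gestation association analyses) plus Gaussian
noise; they are continuous surrogates for litter counts.

One global seed expands into fixed per-stage child seeds
(`SeedSequence(entropy=seed, spawn_key=(stage,))`), so stages can be rerun
independently and identical configurations are bit-reproducible.

What the generator does **not** emulate: read-level error/chimeras,
phylogenetic structure, zero inflation beyond sampling, overdispersion
beyond the log-normal layer, or time-series autocorrelation beyond the
subject intercept. Passing recovery tests therefore demonstrate
correctness of the inference machinery under a known compositional model,
not robustness to every pathology of real amplicon data.

## Module notes

### Rarefaction and coverage

Rarefaction is a multivariate hypergeometric draw (subsampling without
replacement) to an exact depth; samples below the target depth are dropped
and logged — a contract, not an error. Good's coverage is 1 − F₁/n.
Whether downstream stages run on rarefied counts is the caller's choice;
the documented default pipeline rarefies once and feeds every stage from
the same table.

### Diversity and ordination

Shannon uses natural log (a `base` flag is available); Chao1 is the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), robust when no doubletons
occur (classic form behind a flag). Bray–Curtis is computed on counts.
PCoA is classical scaling of the Gower-centred −d²/2 matrix; negative
eigenvalues are reported but excluded from coordinates (no
Cailliez/Lingoes correction by default), and each axis is flipped so its
largest-|coordinate| sample is positive, removing the sign indeterminacy.
PERMANOVA is one-way with free permutation of labels and
p = (1 + #{F* ≥ F})/(1 + n_perm); the repeated-measures design is handled
by invoking it per timepoint, not by restricted permutations.

### SparCC

The variation matrix is computed from the covariance of log fractions
(t_ij = C_ii + C_jj − 2C_ij, sample covariance with n−1). The basis
variances solve M ω² = rowsums(T) with M = (D−2)I + J; the strongest pair
with |ρ̂| above 0.1 is iteratively excluded from the system (M and the row
sums adjusted) and the system re-solved, up to 10 rounds — the reference
defaults. Negative solved variances are floored at 1e−10 with a warning.
Fractions come from Dirichlet(counts + 1) draws; the final r is the
element-wise **median** over 20 inner draws (median for robustness).
`n_inner=0` with `pseudocount=0` gives the deterministic, exactly
closure-invariant pipeline used in invariance tests.

Significance: "bootstrap" p-values in this literature are permutation
pseudo-p values — each null dataset permutes every taxon's counts
independently across samples (resampling samples *with* replacement would
preserve correlations and cannot form a null), the full pipeline is rerun,
and p = (1 + #{|r*| ≥ |r|})/(1 + n_null), two-sided. Networks keep an edge
when |r| > 0.5 (strict) **and** p < 0.05; isolated nodes are retained by
default so that "number of nodes" equals the taxon universe (a flag drops
them). Networks are built per (treatment, timepoint) stratum from that
stratum's ~16 samples; small-n instability is surfaced as a logged
warning, not hidden.

### Network stability

All spectral and clique computations use the unweighted 0/1 adjacency
(the natural-connectivity formula references adjacency eigenvalues; a
weighted |r| variant sits behind a flag). Natural connectivity is
evaluated by symmetric eigendecomposition with a log-sum-exp
stabilisation; an edgeless graph scores exactly 0. Characteristic path
length averages over **reachable** ordered pairs only, and local
clustering of degree < 2 nodes counts as 0 in the mean — both the common
network-analyzer conventions, stated here because thresholded
co-occurrence networks are usually disconnected. Degree centralization is
(N/(N−2))(max deg/(N−1) − density); heterogeneity is the coefficient of
variation of the degree sequence (population SD).

Robustness curves remove a fraction grid of nodes (default 0–0.8 in steps
of 0.05): randomly with 100 replicates (mean ± SD reported), or
deterministically in descending-degree order for sensitivity analysis.
The x-axis is a *fraction* of removed nodes.

MCC uses Bron–Kerbosch enumeration (`networkx.find_cliques`) with a hard
cap on the number of cliques — exceeding it raises a named error rather
than hanging — and competition ranking ("1, 2, 2, 4") so "rank/N" labels
are unambiguous. Singleton cliques are ignored, which makes isolated
nodes score 0 and reduces the score of a node with an edgeless
neighbourhood to its degree, as the reference definition requires.

### Differential genera

Per taxon the mixed model is `log10(rel. abundance + δ) ~ treatment × time`
with a random intercept per subject, fitted by REML; δ is half the taxon's
smallest nonzero relative abundance, a variance-stabilising choice that
keeps zero-heavy taxa in play. Fixed-effect blocks are tested with
type-III-style marginal Wald chi-square contrasts: because the design is
dummy-coded, the raw treatment coefficient describes the reference
timepoint only, so the treatment contrast averages its interaction terms
over timepoints (and the time contrast averages over arms). The
interaction block is tested as-is. statsmodels provides no
Satterthwaite/Kenward–Roger correction for MixedLM; with 192 observations
the chi-square reference is adequate, which the null-calibration test
verifies empirically. Screening uses raw p < 0.05 per effect ("affected by
both treatment and time"), mirroring how such tables are reported; BH-
adjusted columns are emitted alongside for transparency.

Two observations from the package's own simulations, both frozen into
tests: (i) the 5-df omnibus interaction test has ~0.64 power for a
+2 log2 effect confined to one timepoint at 16 subjects/arm (the localized
single-coefficient test reaches ~0.75) — localized effects dilute across
an omnibus block; (ii) compositional closure attenuates the true
log10-relative-abundance interaction coefficient below 2·log10 2 by a
taxon-dependent amount, so CI-coverage experiments compare against the
closure-adjusted truth computed by Monte Carlo from the generator's ground
truth, not against the raw planted constant.

The LEfSe screen is the two-class variant with no subclass tier (the
design has none): Kruskal–Wallis on relative abundances scaled to 10⁶ at
α = 0.05, then 30 bootstrap rounds subsampling ⅔ of each class without
replacement and fitting a one-feature linear discriminant. With one
feature the unit-norm discriminant axis is the feature itself, so the
effect size is the |class-mean difference| on the scaled abundances; the
LDA score is log10 of the mean effect (floored at 1), thresholded at 2.
Classes are iterated in order of smallest sample position so relabeling
flips the enriched class but preserves scores exactly.

Key genera = (treatment **and** time significant in the LMM) ∩ (LEfSe
passed at the chosen timepoint), filtered to overall mean relative
abundance > 0.1%; all tiers are reported, not only the final subset.

### Associations

Spearman matrices use average ranks, the t-approximation for p, and
pairwise-complete handling of missing outcomes; constant columns yield
missing values with a warning. Heatmap-style outputs carry raw-p stars
(*, **, *** at 0.05/0.01/0.001) for parity with how such figures are
annotated, with BH q-values alongside. The volcano filter computes fold
change on raw intensity means but tests on log intensities with Welch's t
(the common metabolomics convention), keeping features with BH q < 0.05
and |log2FC| > 1.

## Problem sizes used in validation

The recovery battery runs at the sizes its questions demand while staying
desk-scale: SparCC recovery at 50 taxa × 200 samples × depth 50,000 with
10 planted pairs, 20 inner draws and a 100-iteration permutation null;
PERMANOVA calibration over 500 null datasets at 199 permutations;
mixed-model coverage and null calibration over 200 simulated studies each;
LEfSe detection with 10 planted 8-fold genera among 100 and 20 null
replicate studies. The end-to-end dry run pushes the full default cohort
(192 samples × 150 genera) through every shell stage, with a 60-iteration
permutation null for the four per-stratum networks.

## Known limitations

- SparCC's sparsity assumption fails on densely correlated communities;
  the exhausted-exclusion case surfaces as `SingularSystemError`.
- Per-stratum networks from 16 samples are noisy by construction; the
  package reports them (as the study design does) but warns below 10.
- PERMANOVA's free permutations ignore repeated measures; use per-timepoint
  invocations for longitudinal data.
- The LEfSe variant omits the subclass/pairwise-Wilcoxon tier of the full
  published algorithm — correct for a plain two-class design, not for
  nested designs.
- No UniFrac or other phylogeny-aware metrics (no tree in scope), no
  compositional differential-abundance alternatives (ANCOM, ALDEx2), no
  visualisation.
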
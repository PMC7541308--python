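# Methods

This note documents the models and procedures `protnet` implements, the
defaults and why they are what they are, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Study design and data model

The pipeline targets a two-batch TMT design: 16 samples spanning two
genotypes (WT, KO) × two age groups (young, old) × 4 replicates, with one
TMT batch per age group.  The central container is an `AbundanceMatrix`:
log2 reporter-ion abundances with a boolean quantification mask.  Missing
cells live only in the mask (never as sentinel values), and all stages
consume log2-scale values as given — no re-logging, and no batch
normalisation by default (an optional per-sample median-centering flag
exists but is off, since how the original batches were referenced to the
global internal standard is not modelled here).

Because each batch holds a single age group, a protein detected in only one
batch is missing in exactly 50% of cells.  Those "half-missing" proteins
never enter QC, differential testing or network construction — they carry
no cross-batch covariance — and are annotated into the finished network
afterwards (see *Mapping half-missing proteins*).

## Sample-connectivity QC

Over the complete proteins, the inter-sample Pearson correlation matrix *C*
defines connectivity *k*ᵢ = Σ_{j≠i} *C*ᵢⱼ, standardized to *Z*ₖ.  Samples
with |*Z*ₖ| > `outlier_sd` (default 3) are flagged.  Flagging is a report,
not a removal; `--drop-outliers` removes flagged samples in a single pass
(no iterative re-check — with clean data none are flagged, so iteration
order is unconstrained and we keep the simplest rule).  Connectivity is
computed on the combined matrix; Pearson (not bicor) is used for
sample–sample correlation, following the sample-network convention.
Numerical guard: when connectivity is numerically constant across samples
(all samples affine transforms of one profile), *Z*ₖ is defined as 0 rather
than amplifying rounding noise.

## Differential abundance

Per complete protein, one-way ANOVA across the four design cells
(F = MSB/MSE, df (k−1, N−k)), followed by all six pairwise Tukey HSD tests

    q_ij = |m_i − m_j| / sqrt((MSE/2)(1/n_i + 1/n_j)),

with p-values from the studentized range distribution (k groups, N−k df).
Degenerate proteins (MSE = 0) get p = 0 when means differ (flagged) and
p = 1 when all values are equal.

The studentized range CDF is evaluated by numerical integration: the CDF of
the range of k standard normals is tabulated on a fine grid by 120-point
Gauss–Legendre quadrature and splined, then integrated over the scale
distribution √(χ²_ν/ν) with an 80-point rule.  This reproduces
`scipy.stats.studentized_range` to ~1e-8 while being ~400× faster per
batch, which is what makes per-protein, per-pair Tukey p-values cheap; the
scipy distribution and a 200,000-draw Monte-Carlo serve as independent
oracles in the tests.

Volcano classification: a protein is *increased* on a contrast when the
contrast p ≤ `p_threshold` (0.05, boundary inclusive) **and** its log2
ratio > `log2fc_threshold` = log2(1.25) ≈ 0.3219, i.e. a minimum 25% linear
fold change; *decreased* symmetric.  Which p drives the call is ambiguous
in the four-group ANOVA–Tukey framing; the default is the Tukey pairwise p
for the displayed contrast (KO vs WT within age), with the omnibus ANOVA p
reported alongside and selectable via `volcano_p="anova"`.  No
multiple-testing correction is applied to the volcano calls (the filter is
on raw p); a BH column is emitted for information.

## Co-expression network

Defaults reproduce the published analysis settings: unsigned network,
Pearson correlation for network construction (bicor is reserved for
module–trait and missing-protein correlation), soft-threshold power
β = 29, TOM with the *mean* denominator, average-linkage clustering of
1 − TOM, dynamic hybrid tree cut with deepSplit 4 and minimum module size
25, PAM stage on, eigenprotein merge cut height 0.07, reassignment
threshold p < 0.05.  β is taken as given; no scale-free-fit sweep is
implemented.  The network is computed in a single block — at a few thousand
proteins a full TOM is easily held in memory, so no blockwise pre-clustering
is applied.

**Eigenproteins.**  Per module, protein profiles are z-scored across
samples and the first right singular vector is the eigenprotein (unit-norm
scores), sign-oriented to correlate positively with the module-average
profile; `var_explained` is the first squared singular value over the
total.  kME is the Pearson correlation of a (standardized) protein profile
with an eigenprotein, with two-sided Student-t p-values
(t = r·√((n−2)/(1−r²))).

**Dynamic hybrid tree cut.**  The cut walks the dendrogram bottom-up
maintaining live branches.  A branch is a finished cluster when it (a) has
≥ `min_module_size` members, (b) its *core scatter* — the mean joining
height of its earliest `min_module_size` joiners — is below a threshold,
and (c) its core closed clearly below the height at which the branch merges
onwards (*gap*).  `deep_split` 0–4 maps to maximum normalized core scatter
{0.64, 0.73, 0.82, 0.91, 0.95} with minimum gap 0.75·(1 − scatter), the
published constant mapping for the hybrid method.  Three implementation
choices matter and are this package's own:

- *Height transform.*  At β = 29 the 1 − TOM dissimilarities compress
  against 1 and merge heights become numerically indistinguishable, so all
  cut criteria are evaluated on the monotone transform −log(1 − h), which
  decompresses the near-1 region without changing the tree.  Generic
  dissimilarities with heights above 1 are used as-is.
- *Normalization anchors.*  Scatter/gap thresholds are normalized between
  the 5th-percentile merge height and the larger of the median merge height
  and the 99%-range cut on the raw scale.  Noise merges concentrate in the
  upper half of the dendrogram, so the median keeps credible cores below
  them; when genuine clusters dominate the tree the raw-scale cut keeps the
  ceiling above their internal structure.
- *Branch growth.*  Branches grow by accretion (real dendrograms are
  caterpillar-shaped); a qualified branch keeps absorbing scattered
  stragglers, closes when it meets another qualified branch, a growing
  proto-cluster (a tight-core sibling of at least half the minimum size),
  or a larger unassigned pool, and is *trimmed* at closing time: members
  whose mean topological overlap with the branch core falls below 1/3 of
  the weakest core member's internal connectivity are released.  The same
  1/3 connectivity floor defines the PAM assignment radius for leftover
  objects.

**Merge, reassignment, membership sweep.**  Modules whose eigenproteins are
closer than `merge_cut_height` (1 − cor, average linkage) merge iteratively
until stable.  A single reassignment pass then moves any protein whose kME
to a foreign module exceeds its own-module kME with p < 0.05.  Finally an
iterative kME membership sweep (≤ 3 rounds) re-derives every protein's
membership from the module eigenproteins: a protein belongs to its
best-correlated module only if that kME is significant at the reassignment
threshold Bonferroni-corrected across the k candidate modules; otherwise it
is unassigned.  The sweep is the analogue of the reference tool's kME-based
cleanup and is where final membership is decided — the correlation scale is
much better powered than topological overlap at n = 16.  Setting
`reassign_threshold = 0` disables both the pass and the sweep, and together
with `merge_cut_height = 0` makes the pipeline return the raw dynamic-cut
labels.

Module labels are M1…Mk by decreasing size, 0/M0 = unassigned.  All steps
are deterministic: scipy's linkage is deterministic with lowest-index-first
tie-breaking, and every other stage is pure linear algebra.

## Module–trait correlation

Each eigenprotein is correlated with binary traits (genotype KO = 1, age
old = 1) by biweight midcorrelation with robust weighting disabled on the
binary side (a binary vector's median absolute deviation is degenerate), and
p-values from the Student-t transform.  Correlations are computed jointly
over all 16 samples and within each age stratum (genotype only), since age
and batch coincide and the joint age correlation cannot be separated from a
batch effect.  Significance stars follow the 0.05/0.01/0.001/0.0001
convention.

## Enrichment

Cell-type enrichment is the one-tailed hypergeometric overlap test
p = P(X ≥ r | N, R, n), computed via `scipy.stats.hypergeom`, with BH
correction across all module × set tests jointly (per-set families by
flag).  The default universe is the complete-protein network; an explicit
universe can be supplied, and set members outside the universe are dropped
with a logged count.  Ontology over-representation additionally reports the
Z-score

    Z = (r − nR/N) / sqrt(n (R/N)(1 − R/N)(1 − (n−1)/(N−1))),

the normal approximation with finite-population correction, with a
one-sided normal p that is labelled approximate (no permutation p is
implemented).  The approximation's ranking agrees with the exact tail
(Spearman ≥ 0.99) at universe sizes in the hundreds and above; at very
small N its ranking coarsens.  Enriched terms can be clustered by Cohen's
kappa of their membership indicators (average linkage on 1 − κ, cut at
κ = 0.3, representative = smallest p); term databases are user-supplied GMT
inputs, not bundled.

## Mapping half-missing proteins

Each half-missing protein is correlated (bicor) with every eigenprotein
restricted to the protein's quantified samples and assigned to the argmax,
carrying the correlation, n = 8, and a reduced-confidence flag; a
minimum-kME option refuses poor assignments instead.  A structural caveat:
age coincides with batch, so the age-driven component of an eigenprofile is
nearly constant within a single batch.  Half-missing members of age-driven
modules are therefore only weakly identifiable from 8 within-batch samples
— on synthetic data their mapping accuracy drops to roughly coin-flip
against correlated alternatives, while genotype-driven and trait-free
modules map at 80–95%.  This is a property of the design, not of the
estimator, and is why the reduced-confidence flag exists.

## Synthetic data generator

`simulate(SimConfig)` draws, per module m, a latent eigenprofile

    e_m = standardize(β_geno[m]·I(KO) + β_age[m]·I(old) + σ_e·N(0,1)),

and protein profiles xₚ = baselineₚ + loadingₚ·e_m + N(0, noise_sd²);
background proteins are baseline + noise.  Standardizing e_m makes the
within-module correlation depend only on loadings and noise:
E[r] ≈ 1/(1 + noise_sd²) at unit loadings.  Defaults: 5 modules × 40
proteins, 200 background, 40 half-missing (planted as module members,
cycled over modules, alternating retained batch), loadings N(1, 0.2²),
noise_sd 0.8 (realized mean within-module |r| ≈ 0.61), eigenprofile noise
σ_e = 0.25, baselines N(12, 1²) on the log2 scale.  Effects:
β_geno = (1.0, 0, 0.8, 0, 0), β_age = (0, 1.0, 0.8, 0, 0) — one clean
genotype module, one clean age module, one mixed, two null.  σ_e = 0.25 is
chosen so that a module planted with β_geno = 1.0 yields an expected
eigenprotein–genotype point-biserial correlation of ≈ 0.89
(r = (β/2)/√(β²/4 + σ_e²)), making trait recovery a sharp test; at σ_e = 1
the expected correlation would be ≈ 0.45 and module-level trait recovery
would be impossible by construction rather than informative.  Marker sets
(40 ids each) are drawn with configured overlap fractions into planted
modules (defaults: 0.8 into module 1, 0.4–0.5 elsewhere), remainder from
outside the module.

What the generator does **not** emulate: reporter-ion interference and
ratio compression, isotope impurity, peptide-to-protein roll-up,
batch-specific intensity shifts, non-Gaussian heavy-tailed noise, and
correlated background structure.  Passing recovery tests therefore shows
the estimators recover the model's own planted structure under realistic
noise levels — not that the pipeline is robust to every artefact of real
TMT data.

## Problem sizes and runtime

Default test and acceptance problem sizes were chosen so the whole suite
runs in seconds on one CPU while keeping every statistical check
well-powered: 440-protein × 16-sample simulations (ten seeds for recovery
medians), 2,000 null proteins for type-I calibration, 25 random 20-node
graphs per TOM denominator, exact-enumeration Fisher checks up to N = 60,
a 15-leaf dendrogram against the naive O(n³) linkage, and 200,000
Monte-Carlo draws for the studentized range (standard error ≈ 0.001).

## Known limitations

- Single-block network only; results on very large matrices may differ
  from a blockwise run of the reference tool.
- The hybrid tree cut follows the published criteria but is an independent
  implementation with its own normalization and trimming choices (above);
  it is validated by recovery experiments, not by output-identity with the
  reference implementation.
- The Z-score enrichment p is a normal approximation; no permutation
  testing.
- No moderated variance estimation in the differential stage (plain ANOVA
  by design).
- bicor falls back to Pearson weighting for vectors with zero median
  absolute deviation, with a log message.
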
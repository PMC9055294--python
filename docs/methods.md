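# Methods

`traitassembly` infers the processes assembling plant communities along a
successional chronosequence from the mismatch between observed functional
traits and trait patterns expected under random draws from the species
pool. This note documents the models, the conventions chosen where the
field's practice is not unique, the synthetic data the package is
validated on, and the limits of what those validations show.

## The inference logic

Communities assembled by **environmental filtering** contain species with
more similar trait values than a random pool sample (trait convergence);
communities structured by **competition / limiting similarity** contain
more dissimilar species (divergence); **dispersal limitation** produces
convergence in regenerative traits specifically; when observed and
expected patterns coincide, **stochastic (neutral) assembly** is the
parsimonious reading. Two trait classes are analysed separately:

* *Establishment traits* — individual-level leaf traits: leaf area LA
  (mm²), specific leaf area SLA (mm²/g), leaf dry matter content LDMC
  (dry/fresh mass fraction). Their joint spread is summarised as the
  volume of an n-dimensional hypervolume (the functional trait space,
  FTS) over standardized axes.
* *Regenerative traits* — species-level seed mass (g/1000 seeds),
  longevity class (1–4), flowering and fruiting period lengths (months),
  first month of flowering (0 = clonal, 1–12 = months, 13 = year-round).
  Mixed continuous/ordinal with missing entries, summarised as the mean
  pairwise Gower distance (MFD) within each plot.

## Null models and the effect size

For a stage with *n_s* leaf records, the FTS null draws *n_s* whole
(LA, SLA, LDMC) triplets from the pooled records of all stages — triplets
are never split, so the correlation structure among axes is preserved —
and rebuilds the hypervolume under one standardization model shared by
observed and simulated volumes (z-scores fitted on the pooled records;
population SD). Resampling is without replacement whenever the pool
allows, falling back to with-replacement with a log message. For a plot
of richness *S*, the MFD null draws *S* species without replacement from
the pooled species list; abundance plays no role in the null.

Each comparison is summarised by

    P  = (#{sim < obs} + ½ #{sim = obs}) / n_sims
    ES = 2 (P − 0.5)  ∈ [−1, 1]

with `n_sims` = 999 by default. The plain proportion (no +1 correction)
is used deliberately so ES can reach exactly ±1 at the boundary. Ties are
detected by exact floating-point equality; the statistics are
deterministic functions of the resample, so exact equality is the correct
tie notion. `|ES| ≥ 0.95` is labelled significant — equivalent to a
two-sided permutation test at α = 0.05 — and the threshold is
configurable. Convergent establishment traits are labelled
"environmental filtering", convergent regenerative traits "dispersal
limitation", divergence of either class "competition / limiting
similarity (or environmental heterogeneity)", and sub-threshold ES
"stochastic/neutral". MFD nulls run per plot; a stage's ES is the mean
over its plots (configurable).

A caution inherent to individual-resampling nulls: observed stage records
arrive in clusters of six individuals per species, while the null draws
individuals freely, so even neutrally assembled stages carry a mild
negative volume bias. The calibration studies therefore use record-level
neutral draws; stage-level ES values near −0.3 to −0.6 should not be
over-read as filtering (they sit well inside the neutral band).

## Hypervolumes

The occupied region of standardized trait space is delineated by a
one-class support-vector machine with radial kernel, which follows the
trait cloud's correlation structure rather than boxing axes
independently. Volume is estimated by rejection sampling in an
axis-aligned bounding box padded by 3 kernel bandwidths
(bandwidth = 1/√(2γ)); the estimate is (box volume) × (fraction of
uniform samples classified inside), with adaptive sample top-up when a
small boundary region is barely hit.

Defaults: ν = 0.01, γ = 1.0, 10⁴ Monte Carlo samples per estimate.
γ was calibrated on uniform-cube benchmarks with known volume: γ = 0.5
(a common convention) inflates a unit cube's volume by ~16–19% through
kernel smoothing, while γ = 1.0 recovers it within ~5% and gives the
offset-cube Jaccard 0.35 vs the exact 1/3. Null-model runs default to
2 × 10³ samples per volume: the permutation test compares volume *ranks*,
which are far less demanding than absolute volumes, and observed and
simulated volumes share identical settings so the Monte Carlo noise is
symmetric. Overlap statistics classify one common uniform sample over the
joint bounding box with both boundaries, making the Jaccard ratio
estimate unbiased and self-overlap exactly 1.

## Gower distances, MFD, FD and imputation

Gower distance: d(i,j) = Σ w_t |x_it − x_jt| / range_t / Σ w_t, ordinal
traits compared on their integer codes (the first-flowering month is
treated as linear 0–13 exactly as coded — no circular-month correction).
Ranges are computed on the pooled species set of all stages, because the
analysis compares stages and distances must be commensurable across them.
Missing cells use pairwise deletion with weight renormalization (Gower's
original proposal); a pair sharing no observed trait is an error. If
every trait has zero range the species are identical on the measured
traits and all distances are 0.

Per-trait functional diversity (FD) is the single-trait special case:
mean pairwise |Δx|/range within a plot, presence-weighted by default with
an abundance-weighted (p_i p_j) variant.

Missing regenerative cells are imputed before distance computation with
one recursive-partitioning regression tree per target trait (minimum leaf
size 5, deterministic seed), the remaining traits as predictors; trees
route missing predictor values through their learned splits. Strictly
positive continuous targets are fitted on the log scale (their errors are
multiplicative) and back-transformed; ordinal predictions are rounded to
the nearest valid class. Traits missing ≥ 50% are refused.

## CSR strategies

Each individual is placed on Grime's C-S-R simplex from its three leaf
traits: monotone transforms (√LA for size, ln SLA and logit LDMC for the
leaf-economics axis), z-scoring against a calibration reference, a linear
map to raw C/S/R components, negative components clipped to zero, and
renormalization to C+S+R = 100. The bundled calibration
(`calibrations/csr_global_synthetic.yml`) is **synthetic**: constructed
for this package from typical leaf-trait distributions so that large
leaves score competitive, tough conservative leaves stress-tolerant, and
cheap acquisitive leaves ruderal. It supports direction-level inference
only; any calibration file with the same layout can be substituted, and
absolute scores should only be compared within one calibration.

## Soil–strategy association

Per soil property, plots are compared by |log(x_i + c) − log(x_j + c)|
(c = 0, or the smallest positive value if zeros occur); community
strategy composition by Euclidean distance between plot-mean
(C, S, R)/100 triplets. The Mantel statistic is the Pearson correlation
of the lower triangles; its p-value comes from row/column permutations,
one-sided ("greater") with the identity permutation counted —
p = (r + 1)/(n_perm + 1) — or from exhaustive enumeration of all n!
permutations when requested. Note the deliberate asymmetry of
conventions: Mantel p can never be 0, while the null-model ES can reach
±1; both choices are standard in their respective literatures and are
recorded side by side in the run manifest. p-values across properties are
Benjamini–Hochberg adjusted by default (Holm/Bonferroni selectable), and
only properties with adjusted p < 0.05 proceed to beta regression — the
gate is an explicit, tested branch of the pipeline.

Beta regression models a strategy proportion y ∈ (0,1) with mean
logistic(β₀ + β₁x) and constant precision φ, fitted by maximum likelihood
(quasi-Newton from a least-squares-on-logit start, Nelder–Mead fallback;
non-convergence raises, never silently falls back). Boundary responses
are compressed by (y(n−1) + 0.5)/n and flagged. Wald standard errors and
p-values are reported.

## Diversity

Richness, Shannon H′ (natural log; base configurable) and Whittaker
turnover β_w = γ/ᾱ − 1 (0 for identical plots; the plain γ/ᾱ variant
available by flag — the ratio-minus-one form was chosen so "no turnover"
reads as 0). Stage-level group comparisons (Kruskal–Wallis and kin) are
left to standard statistical libraries.

## The synthetic chronosequence

The generator emulates a four-stage post-mining succession: 4 stages ×
3 plots, stage richness 12/13/17/19 from a 40-species pool, ~14.3% of
regenerative cells missing completely at random, a soil gradient with
available Cr/Cu declining along succession and moisture/ORP/TN peaking at
stage 3, and ~300 individual leaf records arising from the sampling rule
(six individuals per species per plot where abundance ≥ 5).

Species traits: establishment axes are correlated multivariate
log-/logit-normal (ρ = 0.5, SLA–LDMC negative); regenerative traits share
a latent life-history pace factor (heavier seeds, longer life spans,
longer and later reproduction covary), with the clonal code of the
first-flowering trait tied to the perennial-clonal longevity class — the
cross-trait structure that makes tree-based imputation meaningful.
Abundances are log-series (p = 0.95; many rare, few common — chosen so
roughly a third of occurrences reach the leaf-sampling threshold, matching
the observed record count); the true species-abundance distribution of
any real site is unknown and this stand-in is flagged in `truth.json`.

Assembly regimes per trait class and stage invert the inference rules:
`filtering` admits species by a Gaussian kernel on the focal trait
(default SLA) around a stage-drifting optimum (σ = 0.20/0.35/0.60 across
stages 1–3, neutral at stage 4); `limiting_similarity` greedily admits
species no closer than an exclusion radius in Gower space with a soft
farthest-first bias (per-stage radii 0.11/0.07 for the divergent stages,
sized to the pool's packing capacity — plain random sequential admission
cannot pack richness 19 from 40 species at any radius that still
over-disperses); `neutral` samples uniformly. Default regimes follow the
canonical succession narrative: establishment filtering relaxing to
neutrality, regenerative traits alternating convergent/divergent. Plot
occupancy rises with stage (0.60→0.85) so β_w falls as richness rises.

What the generator does **not** emulate: spatial structure and dispersal
kernels, within-stage dynamics, trait–environment feedbacks, phylogenetic
signal, non-random missingness, or measurement error in soil chemistry.
Passing the recovery tests therefore shows the statistics respond
correctly to the processes they are meant to detect under realistic
magnitudes — not that any particular field system will separate as
cleanly. In the default conditions the alternating regenerative signal is
qualitative (stage means roughly −0.4/+0.8/−0.9/+0.8): a 40-species pool
simply cannot be over-dispersed as extremely as the ±1 boundary.

## Problem sizes and numerics

Calibration and recovery studies run at n_sims = 199 with 1.5 × 10³
Monte Carlo samples per volume, 50–100 replicate runs per condition; the
default pipeline uses n_sims = 999. These sizes put the Monte Carlo error
of each reported rate well inside the tolerance it is judged against.
Degenerate inputs raise typed errors throughout: constant axes, coplanar
clouds, single-species plots, all-zero plots, constant covariates,
zero-variance distance triangles. Seeds fan out from one master seed via
`SeedSequence` spawn keys tagged by component name, so adding a pipeline
step never shifts another step's stream and runs are byte-reproducible.

## Known limitations

* The SVM boundary has a residual bias that depends on point density and
  kernel scale; absolute volumes carry ~5–15% systematic error even at
  large Monte Carlo effort. Rank-based comparisons (the null models) are
  insensitive to this; cross-study volume comparisons are not.
* The CSR calibration is synthetic (above); scores are comparable within
  a calibration, not across published analyses.
* MFD nulls ignore abundance by construction; an abundance-weighted
  observed MFD paired with a richness-only null would conflate two
  conventions and is not offered.
* With 12 plots, Mantel screening across ~20 soil properties has modest
  power after multiplicity adjustment; the gate errs toward false
  negatives.
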
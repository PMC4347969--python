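# Methods

`heatgrad` analyses experiments in which several plant genotypes (e.g.
maize inbred lines) are grown under a *gradient* of heat-stress levels —
a control regime and two or more elevated-temperature regimes — with
replicated phenotyping and RNA-seq at each genotype × level combination.
Instead of comparing stress levels pairwise, every model below treats the
gradient as a single metric dose, which reduces the multiple-testing
burden to one test per gene and lets effects be interpreted per unit of
stress intensity.

## Metric heat-level coding

Temperatures are mapped affinely onto [0, 1]:

    x_j = (T_j − T_min) / (T_max − T_min)

For the canonical 25/32/38 °C design this gives x = (0, 7/13, 1).  All
dose–response slopes below are per unit x, i.e. across the full gradient.

## Phenotype models

The phenotype layout is a randomized complete block design (RCBD) at each
heat level: `n` replications (blocks) per genotype, several traits.

* **Adjusted entry means (BLUEs).**  Per level and trait,
  `Y_ik = μ + I_i + R_k + e_ik` with genotype `I_i` fixed and replication
  `R_k` random, fitted by REML.  Cell-means coding returns the genotype
  BLUEs directly; on balanced complete data they equal arithmetic means
  (tested against that oracle).  Genotypes missing at a level are
  reported missing, never imputed.
* **Variance components and repeatability.**  The same model with
  genotype *random* yields σ²_G and σ²_e; entry-mean repeatability is

      H² = σ²_G / (σ²_G + σ²_e / n)

  Negative component estimates are truncated at zero (REML boundary).
  For unbalanced data `n` is the mean number of observations per
  genotype.
* **Combined model across levels.**
  `Y_ijk = μ + I_i + H_j + (IH)_ij + R_jk + e_ijk`, with genotype, level
  and interaction fixed (sum-to-zero coded) and replication-within-level
  random.  Fixed effects are tested by Wald F with containment
  denominator degrees of freedom (residual df for genotype and
  interaction, replication-stratum df for the heat level); on balanced
  data these reproduce the classical split-in-blocks ANOVA F statistics,
  which is how they are tested.

**REML engine.**  All mixed models here carry one or two crossed random
effects, so REML is implemented directly: the residual variance is
profiled analytically and the restricted likelihood is optimized over the
variance ratio(s) λ = σ²_u/σ²_e — a bounded 1-D search on log λ
(ratio ∈ [1e-8, 1e8], tolerance 1e-8) for a single random effect,
Nelder–Mead on the log-ratio vector for two.  Solves use the Woodbury
identity (cost O(n·q²)), so designs up to ~10⁵ observations with few
random-effect levels are cheap.  A single residual variance is assumed
across heat levels in the combined model; level-specific residuals are
out of scope.

## Multi-trait susceptibility: PCA and the HSI

The genotype × level table of adjusted means (rows = genotype–level
combinations, columns = traits) is centered and, by default, scaled to
unit variance — traits carry incommensurable units, so unscaled PCA
would be dominated by whichever trait has the largest numbers.  PC1 of
this matrix acts as an integrative plant-performance axis.  Its sign is
oriented so the mean score increases from the coolest to the hottest
level, making "high = stressed" deterministic rather than an arbitrary
eigenvector sign.

The **Heat Susceptibility Index** of genotype i is the OLS slope of its
PC1 scores over the metric-coded levels.  Genotypes are ranked by
descending HSI (rank 1 = most susceptible).  Two open choices are made
explicit and switchable:

* the per-observation quantity regressed is the PC1 *score* of each
  genotype–level row (loadings attach to traits; the HSI needs
  per-genotype, per-level values);
* the regressor defaults to the metric codes rather than °C
  (`axis="celsius"` switches), for consistency with the expression
  models.  The HSI's absolute scale depends on this choice and on the
  standardization, so HSI values are comparable within an analysis, not
  across differently configured ones.

## Read quality screening

A FASTQ read is excluded when strictly more than 30 % of its bases have
Phred quality ≤ 20 (the percentage bound is strict, the quality bound
inclusive — boundary reads with exactly 30 % low-quality bases are kept),
or when it contains a primer/adapter sequence as an exact forward-strand
substring.  Reads are dropped whole, never trimmed; adapter screening
can be disabled.  Phred+33 is assumed, with a Phred+64 flag.

## Count processing

* **CPM filter.**  A gene is kept iff it has ≥ 2 counts per million in
  ≥ 2 samples (both bounds inclusive), CPM being counts over effective
  library size × 10⁶.
* **TMM normalization.**  Trimmed mean of M-values with the conventional
  trims (30 % on log-ratios, 5 % on average log intensity),
  inverse-variance weights, the upper-quartile rule for picking the
  reference sample, and rescaling to geometric mean 1.  The
  implementation is tested both against an independently coded
  brute-force trimmed weighted mean and against edgeR's
  `calcNormFactors`, which it matches to ~1e-14.
* **Common dispersion / BCV.**  Counts are modelled NB with
  variance = μ + φμ²; the biological coefficient of variation is
  BCV = √φ.  A single common φ is estimated by maximizing the summed
  per-gene *Cox–Reid adjusted* profile likelihood: for each candidate φ
  the per-gene means are refitted under a one-parameter-per-experimental-
  cell design (offsets = log effective library size) and the penalty
  −½ log det(XᵀWX) is added per gene.  The adjustment matters: with two
  replicates per cell the unadjusted profile likelihood underestimates φ
  by roughly half, while the adjusted estimator recovers a simulated
  BCV of 0.26 to within ±0.01 and agrees with edgeR's common-dispersion
  estimate to ~1e-6.  φ is searched on a log scale over [1e-6, 10].
  Gene-wise/tagwise shrinkage is deliberately out of scope; one common φ
  is used everywhere downstream.
* **Sample PCA.**  PCA of log2(CPM + 1), genes centered, samples scored;
  optionally restricted to the most variable genes.

## Dose–response differential expression

Per gene, counts follow an NB log-linear GLM in the metric code x with
log effective library size as offset and the common φ fixed:

* **Overall response:** `log μ = intercept + β·x`, all genotypes treated
  as replications of one average genotype.
* **Per-genotype response:** one joint GLM per gene with
  genotype-specific slopes γ_i.  By default each genotype also gets its
  own intercept, since baseline expression differs markedly between
  inbred lines; a strict shared-intercept mode reproduces the literal
  one-intercept form.  Per-inbred-subset fitting is available implicitly
  (a single-genotype matrix reduces exactly to the overall fit, which is
  tested).

Fitting is iteratively reweighted least squares (tolerance 1e-8, ≤ 50
iterations), vectorized across genes since all genes share the design;
at φ = 0 it coincides with a Poisson GLM (tested against statsmodels to
1e-6).  Linear predictors are clipped at ±30, so completely separated
genes stay finite but are flagged non-converged and excluded from
calling; all-zero genes report β = 0, p = 1.

Slope significance is a likelihood-ratio χ² test (1 df) — LRT rather
than Wald for better small-sample behaviour — with Benjamini–Hochberg
FDR across genes (per genotype for the γ matrix).  Slopes are reported
in log2 units; a gene is called responsive at FDR < 0.05 and
|log2 FC| > 2, both strict, so a gene at exactly 2 is not called.  The
threshold applies to the slope expressed in log2 fold change across the
full gradient.

**Common responsive genes** are intersections of the per-genotype call
sets over configurable genotype groups (all, pool subsets,
tolerant/susceptible halves).

## Heat-tolerance genes

Per gene, the per-genotype slopes are regressed on the phenotypic HSI:

    γ_i = μ + h_i·δ + e_i

by OLS across genotypes; δ measures how much a gene's dose response
steepens per unit susceptibility.  Significance is the two-sided t test
with n − 2 df, deliberately **not** adjusted for multiple testing (with
only ~8 genotypes the power of this second-stage regression is low, as
in small association-mapping panels); a gene is called at p < 0.05 and
|δ| > 2, both strict.  Called genes are clustered on their γ vectors
(Euclidean distance, complete linkage, tree cut at k = 2) to separate
up-in-susceptible from up-in-tolerant patterns; cluster ids are
relabelled along the dendrogram leaf order so output is deterministic.

## Enrichment

Called gene sets (up and down separately) are tested per annotation term
with the upper-tail hypergeometric probability; the universe is all
genes surviving the CPM filter — the only defensible reference for
synthetic runs.  BH FDR across terms, enrichment fold (k/K)/(n/N), terms
with zero hits kept at p = 1 for a stable output schema.  No ontology
graph propagation.

## Synthetic data: what it emulates, what it does not

The generators reproduce the moment structure the analysis assumes, at
the canonical design scale (8 genotypes × 3 levels; 10 phenotype reps;
2 RNA samples per cell, optionally 47 after dropping one to exercise
unbalanced handling).

* **Phenotypes:** six traits with realistic mean profiles over
  25/32/38 °C (including a non-monotone growth-rate optimum at the mild
  level); each genotype scales the linear damage component by a planted
  susceptibility s_i ~ U(0.9, 1.9), mirroring a realistic index range.
  Noise is proportional to each trait's dynamic range (genotype 0.12,
  block 0.06, residual 0.22 of range), tuned so per-level repeatabilities
  land in the 0.6–0.95 band at n = 10.
* **Counts:** NB draws with mean L_s·q_g·2^(γ_ig·x_j) and common
  φ = BCV² (default 0.26).  Baseline abundances are log-normal
  (parameters configurable, optional floor by reflection).  Library
  sizes default to 0.5–2 × 10⁶ — a deliberate desk-scale stand-in for
  production depths, which changes absolute power but not the method's
  logic.  A configurable fraction of genes gets a common slope ±β
  (default 4) and a fraction gets γ_ig = μ_g + h_i·δ_g with planted
  ±δ (default 4).  The tolerance intercept μ_g defaults to −h̄·δ_g,
  centering the slope profile at zero so planted fold changes stay
  bounded regardless of the HSI scale.
* **FASTQ:** planted low-quality and adapter-bearing subsets with exact
  counts (round(f·n)); clean reads are verified adapter-free so planted
  membership is exactly recoverable.
* Each RNA sample is one NB draw; pooling of biological replicates
  before sequencing is *not* modelled, so any dispersion-reducing effect
  of pooling is absorbed into the configured BCV.  Read sequences have
  no base-composition realism and no gene models — they exist only to
  exercise the QC rule.

Consequently, passing tests demonstrate correct *inference under the
assumed model* (calibration, recovery, determinism), not robustness to
real-data pathologies such as outlier genes with gene-specific
dispersion, batch effects, or mappability artifacts.

In the end-to-end pipeline the count simulator plants tolerance slopes
against the HSI values *estimated* from the phenotype stage rather than
the raw susceptibilities: estimated HSIs are on an arbitrary PCA scale,
and planting against them keeps the planted δ and the |δ| > 2 calling
threshold on the same scale.  HSI estimation quality itself is validated
separately (Spearman vs planted susceptibility).

## Numerical choices and degenerate inputs

* Variance ratios bounded in [1e-8, 1e8]; components at the boundary
  reported as 0.  All-identical responses are flagged degenerate (NaN F,
  zero variances) with a warning, not an exception.
* IRLS ridge 1e-10 on XᵀWX; LRT statistics clipped at 0.
* BH ties resolved by stable sorting with gene-ID order.
* Zero-residual tolerance fits (exactly collinear γ) report p = 0, and
  the strict |δ| > 2 rule still applies.
* All simulators consume a `numpy` `default_rng` seed; the pipeline fans
  one master seed out to stages via `SeedSequence.spawn`, so a config
  plus seed fully determines every artifact.

## Problem sizes used in the shipped checks

Simulation-backed tests run at 1,000–5,000 genes × 47–48 samples,
100-seed phenotype replicates, and 200–500-run Monte-Carlo loops —
sizes chosen so the full suite completes in about a minute while keeping
Monte-Carlo bands (e.g. type-I error in [0.035, 0.065]) tight enough to
be informative.

## Known limitations

* One common dispersion; genes with atypical dispersion are mis-weighted
  (anti-conservative for high-dispersion genes).
* Containment df for Wald F is one convention among several for mixed
  models; with small level counts the heat-level test is approximate.
* The HSI's absolute scale is convention-dependent (see above).
* The second-stage tolerance regression treats γ̂_i as known; their
  estimation error inflates the residual rather than being propagated,
  which the type-I-error checks show is acceptable at this design size.
* Adapter screening is exact substring match on the forward strand only.
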
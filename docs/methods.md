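# Methods

## The problem

Beef eating quality is scored by consumer taste panels: each striploin sample
is eaten by 10 consumers who score tenderness, juiciness, flavour and overall
liking on a 0–100 scale. The two highest and two lowest scores are discarded
and the middle six averaged (the *clipped* score), and the MQ4 composite is
the fixed weighted sum 0.4·TENDER + 0.1·JUICY + 0.2·FLAVOR + 0.3·OVERALL.
The goal is to predict these phenotypes for new animals from SNP genotypes
plus simple covariates, in a cohort mixing *Bos indicus* and *Bos taurus*
breeds and their crosses — so breed composition, heterosis and
management-group structure all matter.

## Model

The training model (Model 1) is a whole-genome regression

    y = μ + cg + b_d·days_aged + b_w·carcass_weight
        + Σ_j c_j·PC_j + b_h·het + Z g + e,

where `cg` is a fixed contemporary-group effect, PC1–PC4 are the leading
principal components of the VanRaden/GCTA genomic relationship matrix
(breed-composition proxies; PC1 tracks indicus content), `het` is the
proportion of heterozygous loci (its slope estimates heterosis), `Z` is the
allele-dosage matrix and `g` the vector of SNP effects. A reduced model
(Model 5) omits the PC and heterosis terms so breed effects are absorbed
into `g`.

SNP effects follow the BayesR four-component mixture

    g_i ~ π₁ N(0, 0) + π₂ N(0, 10⁻⁴σg²) + π₃ N(0, 10⁻³σg²) + π₄ N(0, 10⁻²σg²),

sampled by Gibbs: fixed effects from their conditional normals (flat
priors), each SNP's component indicator from the marginal likelihood ratio
and then its effect from the conditional normal, π from a Dirichlet, and
σg², σe² from scaled-inverse-χ² conditionals. Default chain settings are
25,000 iterations, 5,000 burn-in, thinning by 10 (2,000 retained samples).
The per-SNP posterior inclusion probability (PIP) is the fraction of
retained samples in which the SNP occupies a nonzero component.

### Prediction strategies

Validation phenotypes are assembled from posterior-mean estimates; the
intercept and cg effects never enter a prediction (a new animal's management
group is unknown):

1. ŷ = Zĝ (Model 1) — breeding value only;
2. ŷ = Zĝ + all estimated covariate terms (days aged, carcass weight,
   PC1–4, heterosis);
3. ŷ = Zĝ + genotype-derivable terms only (PC1–4, heterosis);
4. ŷ = Zĝ from Model 5 — breed effects absorbed into the SNP effects.

Accuracy is the Pearson correlation between ŷ and the raw clipped phenotype
within each of five random folds (equal sizes ±1), averaged, with
SE = SD/√5. Strategies are compared by a paired t-test on fold-level
correlations (4 df); compact letters join strategies whose differences are
not significant at α = 0.05. The test is a documented stand-in: the original
analysis reports letters without naming its procedure.

## Key numerical and design choices

**Genotype coding.** Codes count copies of the PLINK .bim allele1
(A1 dosage). The sign of every reported SNP effect depends on this.

**Genotype scaling in the sampler.** Columns are centred and scaled to unit
variance inside `fit_bayesr` (better mixing; puts the γ factors on a
per-SNP-variance scale); posterior effect means are transformed back to the
per-allele scale, so predictions are plain dosage dot products.

**Heritability.** h² is computed per retained sample from the genic
variance: h² = var(Zg)/(var(Zg) + σe²). The variance-parameter form
σg²/(σg² + σe²) is available (`h2_from_genic=False`) but is calibrated only
when roughly 1/γ₄ = 100 SNPs occupy the largest component — the
hundreds-of-thousands-of-markers regime. At desk scale (m ≈ 2,000) σg² is
weakly identified and the parametric ratio overshoots badly (measured ≈ 0.64
for a true 0.30), while the genic form recovers the target.

**Mixture prior.** Default Dirichlet prior counts are (1, 0.01, 0.01, 0.01).
The 10⁻⁴σg² component is individually undetectable at desk scale
(z'z·v₂/σe² ≪ 1), so with flat counts the null-vs-component-2 allocation is
an almost neutral Pólya urn: on pure-noise data π₂ drifts to ≈ 0.3 and mean
PIP to ≈ 0.4. The sparse prior keeps π at the null corner unless the data
insist; a pure-noise run then gives mean PIP ≈ 0.02. With very dense marker
panels the aggregate likelihood pins π by itself and flat counts behave the
same. π starts at (0.5, 0.3, 0.15, 0.05); on weak-signal data the chain
takes ~4,000 iterations to drain to the corner, which is why short-chain
runs here use burn-ins of at least 500–3,000.

**Variance priors.** Scaled-inverse-χ² with ν = 4 for both variances, scales
splitting var(y) by an assumed h² of 0.5 — weakly informative; the data
dominate after a few hundred iterations.

**Sweep order and reproducibility.** SNPs are updated in genome order by
default (a flag enables random sweeps). All randomness flows from one numpy
Generator seeded by `config.seed`; the numba kernel consumes pre-drawn
uniforms/normals, so identical config + seed gives bit-identical chains.
The incrementally updated residual is checked against a from-scratch
recomputation every 1,000 iterations (tolerance 10⁻⁸ relative).

**QC.** Filters run in fixed order (missing rate > 0.1 strictly, then
MAF < 0.01, then exact HWE p < 10⁻⁸), each SNP attributed to the first
filter it fails. The HWE test is the exact conditional test (two-sided, sum
of configurations no more probable than observed), computed on all animals
pooled — a Wahlund caveat is recorded in the report since pooled breeds
show heterozygote deficits. Surviving SNPs are mean-imputed; reference-panel
imputation is out of scope.

**Validation PCs.** By default validation animals are projected onto the
training-set PCA (Nyström projection; no leakage). A joint all-animal PCA
mode mirrors the single-cohort setting in which structure is computed once
for everyone; cross-validation results here use the joint mode, matching
that setting, and the projection mode is the conservative default for true
out-of-sample use.

## The synthetic cohort generator

The generator emulates the cohort the analysis assumes, not any particular
dataset:

* **Breeds.** Two Balding–Nichols populations (ancestral frequencies uniform
  on [0.05, 0.95], differentiation FST, default 0.1) plus F1 crosses that
  draw one allele per breed. Default 400 + 400 + 200 animals, 2,000 SNPs.
* **Effects.** SNP effects from the BayesR mixture itself, default
  π = (0.95, 0.03, 0.015, 0.005). Effects are rescaled so var(Zg) takes
  exactly the target h² (default 0.30) share of a within-group phenotypic
  variance budget of 14² points²; the mixture's σg² therefore only sets
  relative spreads.
* **Fixed effects.** Contemporary groups (~26 animals each) are
  breed-blocked and carry N(0, 5²) effects; days aged is drawn once per
  group (integer 3–35) with within-group jitter of SD 0.5 days — aging time
  is effectively a cohort property, so the days-aged coefficient is
  identified only through that small jitter; carcass weight is
  N(261, 74²) kg truncated to [50.6, 576] with a 0.02 points/kg slope;
  heterosis adds 8 points per unit heterozygosity; an explicit breed-mean
  shift of 21 points (≈1.5 within-group phenotypic SD) per unit breed-A
  ancestry makes breed structure matter, as it does in a mixed
  indicus/taurus cohort. The baseline μ = 42 puts the realized cohort mean
  near 57 so the 0/100 score bounds rarely bind.
* **Panels.** Each trait's panel is latent value + i.i.d. N(0, 10²) consumer
  noise, truncated to [0, 100], clipped to the middle six. The clipped mean
  of 10 unit-normal draws has variance 0.1133 (Monte-Carlo constant), and
  the generator subtracts that panel contribution from the residual variance
  so the *clipped* phenotype realizes the target h². All four sensory traits
  share one latent animal value and differ only through panel noise — MQ4
  and trait-specific architectures are not modelled separately.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
exchangeable given frequencies, so "discovery" here means finding the causal
marker itself, not a proxy), pedigree/family structure, trait-specific
genetic correlations, imputation error, or scoring-protocol drift across
cohorts. Passing tests therefore demonstrate correctness of the machinery
and qualitative behaviour of the strategies under breed confounding — not
real-data accuracy levels.

**Why the strategy ordering emerges.** The breed shift is excluded from
strategy 1 (Model 1 fits PCs, and ŷ omits them), explicitly added back in
strategies 2–3, and absorbed into Zĝ by strategy 4 — so 1 trails the rest.
The days-aged coefficient, identified only through the 0.5-day within-group
jitter, has a large standard error; multiplied by the 3–35-day between-group
spread it injects noise into strategy 2's predictions while the true slope
(0.2 points/day) contributes little signal, so strategy 2 trails strategies
3/4 — the regime the cohort analysis reports, in which adding estimated
days-aged/carcass-weight terms did not improve accuracy. Because that
coefficient error has very few effective degrees of freedom per cohort, the
ordering is asserted on mean accuracies over five replicate cohorts.

## Problem sizes used by tests and the acceptance script

Chains are shortened where the quantity being measured stabilises early:
accuracy comparisons use 2,000-iteration chains (500 burn-in) — GEBV
posterior means stabilise quickly; heritability recovery uses 8,000
iterations (2,000 burn-in) over five seeded cohorts of 1,000 animals ×
2,000 SNPs; the enumeration-oracle check fixes the variances at truth and
retains 20,000 samples on an n = 50, m = 3 instance; the exact-HWE sweep
enumerates every allele-count configuration up to n = 200 (tests) / 120
(script). The full 25,000/5,000/10 setting is exercised for the sample
bookkeeping itself.

## Known limitations

* σg² from the conjugate update is retained for the component variances but
  should not be read as the genetic variance at desk scale (see above).
* The exact HWE test is O(allele count) per SNP; for very large cohorts a
  mid-p or asymptotic option would be cheaper.
* Contemporary-group effects are never part of ŷ; if a deployment had
  partial cg knowledge the strategies would need extending.
* MQ4 is computed from clipped trait scores by default; the consumer-level
  alternative (clip after weighting) is available via
  `panel_traits(..., mq4_at_consumer_level=True)` because the published
  description is ambiguous about the order; the two differ by ≲0.5 points
  on realistic panels.
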
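# Methods

## The model

`micropart` partitions the variance of a quantitative phenotype — the
motivating case is daily methane production of dairy cows — into a
host-polygenic component, a rumen-microbiome component and residual noise,
fitting all terms jointly:

    y | γ, u, β, σe² ~ N(Xγ + Zu + Mβ, I σe²)

* **X γ** — fixed covariates: intercept, herd dummies (reference level
  dropped), parity dummies, days in milk (DIM), and a Wilmink lactation
  term `exp(-k · DIM)`; flat priors on γ. Optionally a sequencing-instrument
  dummy.
* **Z u** — animal-level polygenic effect, `u ~ N(0, A σu²)` with A either
  the pedigree numerator relationship matrix (tabular method) or the
  SNP-based genomic relationship matrix (Yang et al. standardized-marker
  estimator, including its distinct own-relationship diagonal). Flat prior
  on σu².
* **M β** — the microbiome term. M is the animals × taxa matrix of
  transformed OTU abundances; each taxon effect β_i carries a K-component
  scale-mixture-of-normals prior in the BayesR tradition. A latent label
  z_i ∈ {1..K} assigns the taxon to a shrinkage class; class variances are
  locked at fixed ratios (1:10:100:1000 by default, strongest → mildest
  shrinkage) with one free scale; the class proportions π have a
  Dirichlet(125, 25, 5, 1) prior that concentrates mass on the
  strongest-shrinkage class, inducing a sparse model.

The quantities of interest are the explained-variance shares
`prop_u = σu² / T` and `prop_m = var(Mβ) / T` with
`T = σu² + var(Mβ) + σe²`. var(Mβ) is the sample variance (n−1 divisor) of
the fitted microbiome contribution, recomputed in every MCMC cycle so its
full posterior (mean and 95% highest-posterior-density interval) is
available. The denominator excludes fixed-effect variance; this is a
documented convention, switchable only by pre-correcting y.

### Component ordering

The mixture is parameterized so that component 1 has the smallest variance
and the most prior mass, and component K the largest variance and the
least — i.e. the ratio constraint reads
`σ²_K = 1000 σ²_1` for K = 4 with ratios (1, 10, 100, 1000). This is the
ordering the sparsity rationale of this model family requires: most taxa
negligible, a small prior fraction allowed large effects.

## The sampler

A single Markov chain mixes Gibbs and Metropolis–Hastings updates:

* γ, the polygenic effects and β are single-site Gibbs draws from their
  Normal full conditionals, with the residual vector maintained
  incrementally (numba kernels; the fitted microbiome and polygenic vectors
  are maintained the same way, so per-cycle var(Mβ) is O(n)).
* The polygenic term is reparameterized through a factor L with LL' = A
  (Cholesky, with an eigendecomposition square root as fallback for
  numerically semi-definite genomic matrices): u = L a with
  a ~ N(0, σu² I), so no solves against A occur inside the chain and
  u'A⁻¹u reduces to a'a.
* Labels z_i move to a neighbouring component (interior: ±1 with
  probability ½ each; boundaries propose their single neighbour), accepted
  by the prior-times-density ratio with the Hastings correction ½ / 2 at
  the boundaries.
* π is a conjugate Dirichlet draw, Dir(α + class counts).
* σe² and σu² are scaled-inverse-χ² draws under flat variance priors
  (`e'e / χ²_{n−2}`, `a'a / χ²_{n−2}`), floored at 1e-12.
* The constrained class variances move together: a log-normal random-walk
  proposal on the free scale, accepted by the β-likelihood ratio **times
  the Jacobian σ²′/σ²**. The Jacobian term is what the flat prior on the
  variance scale requires; omitting it (a flat prior on log σ²) makes the
  posterior improper at σ² → 0 and, empirically, lets the chain fall into
  a quasi-absorbing collapsed state (all β pinned near zero). The proposal
  SD is auto-tuned toward 20–50% acceptance during burn-in only, so the
  post-burn-in kernel is fixed and valid.

Initialization: γ at its OLS fit, polygenic effects at zero, β at its
ridge estimate `M'y_c / (m_i'm_i + 2n)`, all labels in class 1, π at the
prior mean, σe² = var(y)/2, σu² = var(y)/4, and the class-1 variance at the
mean squared ridge effect. The ridge start matters: starting β at exactly
zero lets the very first scale updates crash the mixture scale before β
can grow. The stationary distribution is unaffected; this is burn-in
engineering.

Default protocol: 100,000 iterations, 10,000 burn-in, every 20th
post-burn-in sample saved. The chain is bit-reproducible from its seed.
Divergence guard: any variance exceeding 1e12 aborts with diagnostics.

DIC is computed as D̄ + pD with D(θ) = −2 log N(y; fitted, Iσe²) per saved
sample and pD = D̄ − D at the posterior mean of the linear predictor and
σe². The 95% HPD interval is the shortest contiguous interval over sorted
samples containing ⌈0.95 n⌉ points.

## Preprocessing

* SNP QC order: individual call rate ≥ 0.99 → SNP call rate ≥ 0.98 → HWE
  p ≥ 1e-8 (exact conditional test when any HWE-expected genotype count is
  below 5, else 1-df χ²) → MAF ≥ 0.02. Surviving missing genotypes are
  imputed to the SNP mean (QC uses call rate; something must fill the rest).
* OTU prevalence filter: keep taxa present in ≥ 50% of animals (boundary
  inclusive).
* `log_std` transform: ln(count + 0.001), then per-taxon z-score
  (n−1 divisor). Optionally within instrument group.
* `clr` transform: per-animal centered log-ratio after replacing zeros by
  0.5 counts (additive replacement; configurable). CLR output is *not*
  column-standardized by default — the compositional geometry is kept —
  with a flag to standardize.
* Genus collapsing sums counts over OTUs sharing the genus label;
  OTUs unclassified at genus group by their deepest assigned rank.
* The Wilmink rate constant defaults to the classical k = 0.05 (the
  function is conventionally cited without its rate; k is exposed).

## Mixed-model scans

Heritability of a pre-corrected microbial trait (taxon abundance, PCoA
axis, Chao1, CLR-PCA axis) is REML under `y = 1μ + u + e`,
`u ~ N(0, G σg²)`: one eigendecomposition of G diagonalizes the problem and
the restricted likelihood is profiled down to a bounded 1-D search over
log₁₀ λ, λ = σg²/σe² ∈ [1e-6, 1e6]. h² = σg²/(σg²+σe²) is clipped to
[0, 1]; its SE comes from the numerically observed information by the delta
method; significance is a one-sided Wald test (variance ratios are
non-negative). Multiple testing across traits uses the Benjamini–Yekutieli
step-up adjustment (valid under arbitrary dependence).

The association scan fits `y = 1μ + s g + u + e` one SNP at a time by
generalized least squares with covariance σg²G + σe²I, the variance
components estimated once under the null and reused across SNPs
(EMMAX/P3D; exact per-SNP REML behind a flag). t = ĝ/SE is referred to
t(n−2) — the df convention ignores the polygenic term's effective
dimension, documented as this implementation's choice — and Bonferroni
adjustment multiplies p by the number of SNPs tested. Monomorphic SNPs are
skipped.

## Diversity traits

Bray–Curtis dissimilarity is computed on raw filtered counts (flag for
relative abundances); PCoA is classical scaling with negative eigenvalues
dropped and their mass logged (no Cailliez correction). Chao1 is the
bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)), defined on integer
counts. PCA on CLR-transformed data gives the Aitchison-geometry
ordination; its scores equal classical scaling of Euclidean distances of
the CLR matrix up to sign.

## Synthetic data

The generator emulates a ~750-cow methane study without claiming to be
one:

* **Genotypes/pedigree** — founders at Hardy–Weinberg proportions with
  MAF ~ U(0.05, 0.5); offspring by Mendelian gene-dropping through
  paternal half-sib families (50 sires at study scale; dams reused
  cyclically, so full sibs occur).
* **OTU counts** — per-taxon log-normal baseline abundances (ln mean 50,
  sd 1); heritable taxa get a latent
  `√h² · g + √(1−h²) · ε` log-abundance with g a unit-variance polygenic
  draw on the relationship structure; counts are negative-binomial
  (size 10) around the exponentiated latent, with structural zeros
  injected independently (rate 0.1 by default) and an additive per-taxon
  instrument offset (sd 0.3 on the log scale) for the second
  sequencing-instrument half.
* **Phenotype** — drawn exactly from the analysis model: σu² = h²·T;
  β from the K-component mixture with class variances in the configured
  ratios, scaled so E var(Mβ) = m·T (m the microbiability target);
  σe² the remainder; fixed effects with herd/parity effects ~ N(0, 0.25T),
  a DIM slope and a Wilmink coefficient of realistic sign. Realized shares
  (which fluctuate around the targets because var(Mβ) is dominated by a
  few large effects) are recorded in the TruthRecord shipped with every
  dataset.

What the generator does **not** emulate: phylogenetic correlation among
taxa, compositional closure at the count level, read-depth variation,
diet/season structure, genotype LD beyond family structure. Passing
recovery tests on these data therefore demonstrates internal correctness
of the estimators under the stated generative model, not field performance
on real rumen data.

Named scenarios: `study` (n=750, 5000 SNPs, 500 OTUs, shares
0.25/0.07), `tiny` (n=60, 200 SNPs, 40 OTUs — IO and smoke tests), `null`
(study scale, both shares 0). The null scenario deliberately uses the full
study scale: variance-share posteriors under flat priors are weakly
identified at small n (their posterior mean under pure noise is of the
order of their posterior spread), so a null-calibration check at n=300
would measure identification, not correctness.

## Problem sizes and tolerances in the test suite

The validation suite runs the coverage study at the full study scale
(20 replicates of n=750 / 5000 SNPs / 500 OTUs) with 10,000-iteration
chains (2,500 burn-in); the enumeration oracle uses a 150,000-iteration
chain on n=30/p=5/K=2; REML recovery uses 50 trait replicates at n=500 /
2000 SNPs; association calibration uses 10,000 null SNP tests at n=500.
These sizes keep the complete suite within minutes on one CPU while
leaving each check statistically sharp; chain lengths shorter than the
production default are adequate here because the validation quantities
(posterior means and 95% intervals of variance shares) stabilize well
before the tails do.

Known limitations:

* The mixture has no point-mass-at-zero component, so under pure-noise
  data the microbiome share does not collapse to exactly zero; its
  posterior mean is of order a few percent at study scale. The same holds
  for the polygenic share under flat σu² priors. Null-calibration
  assertions are therefore inherently near their thresholds.
* Single-site Gibbs plus neighbour-move label proposals mix slowly when
  taxa are strongly correlated; production analyses should use the full
  100k-iteration protocol and inspect the sidecar trace.
* The P3D approximation understates per-SNP uncertainty slightly when a
  SNP explains a non-trivial variance fraction; the exact per-SNP REML
  flag exists for follow-up of top hits.
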
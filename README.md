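# micropart

Joint Bayesian partitioning of quantitative-trait variance into
host-genetic and microbiome components, with REML heritability scans of
microbial abundances and single-SNP mixed-model association.

## The problem

How much of the variation in a cow's methane output is her own genetics,
and how much is her rumen microbiome? Fitting the two one at a time
confounds them — heritable microbes carry genetic signal, and microbial
abundances are noisy, high-dimensional and zero-inflated. `micropart`
implements a joint Bayesian model for animal scientists and microbiome
researchers who want both answers from one fit:

    y | γ, u, β, σe² ~ N(Xγ + Zu + Mβ, I σe²)

with fixed herd/parity/lactation covariates (Xγ), a polygenic effect
u ~ N(0, A σu²) on a pedigree or genomic relationship matrix, and one
effect per microbial taxon (Mβ) under a BayesR-style K-component
scale-mixture prior: each β_i belongs to a latent shrinkage class
z_i ~ cat(π), class variances are locked at 1:10:100:1000 ratios, and
π ~ Dirichlet(125, 25, 5, 1) keeps most taxa in the strongest-shrinkage
class. A single MCMC chain (Gibbs + Metropolis–Hastings) yields posterior
means and 95% HPD intervals for the explained-variance shares
σu²/T and var(Mβ)/T, per-taxon variance contributions, and DIC for
comparing mixture sizes.

Around the core model the package provides the full pipeline: SNP QC
(call rate, exact/χ² HWE, MAF), OTU prevalence filtering, log-standardize
and centered-log-ratio transforms, genus collapsing, pedigree-A and Yang
genomic relationship matrices, eigendecomposition REML with
Benjamini–Yekutieli FDR for microbial-trait heritability scans,
EMMAX/P3D single-SNP association, Bray–Curtis PCoA / Chao1 / CLR-PCA
diversity traits, and a synthetic-data generator that emulates a 750-cow
study with recorded ground truth.

## Worked example

```python
import numpy as np
from micropart import (
    BayesianVariancePartition, grm_yang, log_standardize,
    otu_prevalence_filter, build_fixed_design, make_scenario,
)
from micropart import io

paths = make_scenario("tiny", seed=7, outdir="scratch/tiny")
t = io.load_tables(
    phenotype_path=paths["phenotype"], genotype_path=paths["genotypes"],
    otu_path=paths["otu"], taxonomy_path=paths["taxonomy"],
)
G = grm_yang(t["genotypes"].loc[:, t["genotypes"].std(0) > 0])
M = log_standardize(otu_prevalence_filter(t["otu"]))
X = build_fixed_design(t["phenotype"])

model = BayesianVariancePartition(
    chain_length=20_000, burn_in=5_000, thin=15, random_state=1,
).fit(M, t["phenotype"]["methane"].values, X=X, relationship=G)
print(model.summary().to_string(index=False))
```

prints (exact output of this snippet):

```
          quantity  posterior_mean  hpd_low  hpd_high
prop_host_genetics        0.202727 0.000063  0.473374
   prop_microbiome        0.111402 0.000127  0.300494
             var_u        0.302230 0.000126  0.816001
             var_m        0.162533 0.000217  0.496744
          sigma_e2        0.957890 0.315683  1.494168
               dic      185.994660      NaN       NaN
```

Reading: on this 60-cow synthetic herd (generated with true shares 0.25
and 0.07) the model attributes a posterior-mean 20% of phenotypic variance
to host genetics and 11% to the microbiome, with wide 95% HPD intervals —
at n=60 the shares are only weakly identified, which is exactly what the
intervals say. `model.taxon_variance_` gives each taxon's posterior mean
variance contribution; `model.trace_` holds the per-1000-cycle convergence
trace.

The same pipeline is scriptable from the shell:

```bash
micropart simulate tiny --seed 7 --outdir scratch/tiny
micropart bayes --phenotype scratch/tiny/phenotype.tsv \
    --genotypes scratch/tiny/genotypes.tsv \
    --otu scratch/tiny/otu_counts.tsv --taxonomy scratch/tiny/otu_taxonomy.tsv \
    --iters 20000 --burnin 5000 --seed 1 --out scratch/summary.tsv
micropart h2scan ... ; micropart gwas ... ; micropart diversity ...
```

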
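# cm3 — covariate-modulated mixture modeling for GWAS replication

`cm3` estimates, for every SNP in a GWAS meta-analysis, the probability
that its association will replicate in an independent sample — and uses
per-SNP auxiliary information to do it better than the p-value alone.

## Who this is for

GWAS analysts working with summary statistics from a meta-analysis of
multiple independent sub-studies (the package was designed around
psychiatric-genetics consortium data: tens of sub-studies, millions of
SNPs) who want to rank loci for follow-up by predicted replication
probability rather than nominal significance, with winner's-curse
shrinkage built in.

## The model

The z-score of SNP *i* in a study of effective sample size *n* is

    z_i = √n · δ_i + ε_i,    ε_i ~ N(0, σ₀²),

with the standardized effect δ_i drawn from a scale mixture of two
zero-mean Gaussians: with probability π₀ = 1 − π₁ the effect is *small*,
δ ~ N(0, H_i σ₁²); with probability π₁ it is *large*, δ ~ N(0, H_i (σ₁²
+ σ₂²)), where H_i = 2k(1−k) is the SNP's heterozygosity. σ₁² = 0
recovers the classical point-null two-groups model; σ₁² > 0 lets the
"null" component carry very small replicating effects (apparent
inflation).

From the marginal mixture f(z) = π₀ f₀(z) + π₁ f₁(z) the package
computes the local false discovery rate fdr(z) = π₀ f₀(z)/f(z), the
posterior mean effect E[√n δ | z] = z·[A·fdr(z) + B·tdr(z)] (equal to
the Tweedie form z + σ₀² (log f)′(z)), and the finite-sample predicted
replication probability — the chance that a replication sample of
effective size n_r yields a same-sign z-score beyond z_α.

**Covariate modulation.** SNPs are not exchangeable: LD-weighted genomic
annotation scores, total LD, heterozygosity and pleiotropy with a
secondary trait (squared z of e.g. bipolar disorder) all predict
replication. A logistic regression of the thresholded association
indicator (p ≤ 10⁻³) on these covariates gives each SNP a *relative
enrichment score*; SNPs are stratified into K score bins and the
mixture is fitted separately per stratum.

**Fitting.** The sub-studies are randomly partitioned (500-style
iterations; 20–50 in the bundled studies) into discovery/replication
halves at several discovery fractions; nonparametric binned curves of
the mean and second moment of the replication z given the discovery z
are accumulated, and (π₁, σ₀², σ₁², σ₂²) are estimated per stratum by
minimizing the count-weighted squared distance between model-implied
and empirical curves (quadratic estimating equations).

## Worked example

```python
import numpy as np
from cm3 import MixtureParams
from cm3 import simulate as sim, pipeline as pl

params = MixtureParams(pi1=0.05, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=2e-3)
data = sim.simulate_enriched_dataset(
    m=50_000, J=10, params=params,
    effect_map={"H": 0.8, "tld": 0.7, "bip_z2": 0.5, "exon": 0.6}, seed=7,
)
fit = pl.fit_cm3(data.panel, data.covariates, K=6, bin_mode="quantile",
                 iterations=10, fractions=(0.3, 0.5), seed=8)
pred = pl.predictions_frame(fit, data.panel,
                            n=data.panel.n_total, n_r=data.panel.n_total)
comp = pl.evaluate_yield(data.panel, fit, eval_iterations=10, seed=9)
print(f"SNPs with predicted replication >= 0.9: "
      f"{(pred['pred_repl'] >= 0.9).sum()}")
print(f"yield at replication rate 0.5: "
      f"{comp.yield_pred:.0f} (pred-repl ranking) vs "
      f"{comp.yield_p:.0f} (p ranking)")
```

Output:

```
SNPs with predicted replication >= 0.9: 1502
yield at replication rate 0.5: 3699 (pred-repl ranking) vs 3518 (p ranking)
```

The first number counts SNPs whose fitted per-stratum mixture predicts
at least a 90% chance of a same-sign significant z in an equally sized
replication sample. The second line is the point of the method: ranking
by predicted replication probability admits ~5% more SNPs than p-value
ranking before the cumulative observed replication rate (measured on
held-out split halves) drops below 0.5.

There is also a CLI (`cm3 simulate | enrich | resample | fit | run |
rank`) for file-based workflows; `cm3 run --config cfg.yaml --out dir`
executes the whole pipeline from a YAML configuration.

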
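# Methods

This note documents the statistical model, the estimation procedure,
the synthetic-data generators, and the numerical and design choices
behind `cm3`.

## Model

Per-SNP association z-scores are modeled as z = √n·δ + ε with ε ~
N(0, σ₀²) and n the study's effective sample size (for case-control
designs, 4/(1/cases + 1/controls)). The standardized effect δ follows a
zero-mean scale mixture of two Gaussians whose variances scale with the
SNP's heterozygosity H = 2k(1−k):

- small component (prior π₀ = 1 − π₁): δ ~ N(0, H σ₁²)
- large component (prior π₁):          δ ~ N(0, H (σ₁² + σ₂²))

σ₁² = 0 gives the familiar point-null two-groups model; a positive σ₁²
lets the bulk of SNPs carry tiny but real (and hence weakly
replicating) effects, the model's account of apparent genomic
inflation. σ₀² is *fitted*, not fixed at 1, for the same reason.

Marginally z | component k is N(0, σ₀² + n H σ\*²) with σ\*² = σ₁² or
σ₁² + σ₂². All posterior quantities follow in closed form:

- local fdr(z) = π₀ f₀(z)/f(z); tdr = 1 − fdr.
- posterior mean E[√n δ | z] = z·[A·fdr + B·tdr], A = nHσ₁²/(σ₀²+nHσ₁²),
  B = nH(σ₁²+σ₂²)/(σ₀²+nH(σ₁²+σ₂²)); identical to the Tweedie form
  z + σ₀²·(log f)′(z), which the tests verify by central differences.
- replication law: given the component and the discovery z_d, the
  replication z_r (effective size n_r) is Gaussian with mean c_k·z_d
  and variance v_k, where c_k = √(n n_r)·H σ\*²/(σ₀²+nHσ\*²) and
  v_k = σ₀² + n_r H σ\*² − n n_r (H σ\*²)²/(σ₀²+nHσ\*²). These follow
  from the joint bivariate Gaussian of (z_d, z_r) sharing δ; a
  Monte-Carlo oracle in the acceptance tests is the arbiter of this
  derivation. Component membership is shared between discovery and
  replication (no switching), so the conditional replication moments
  weight the two component laws by fdr/tdr.
- predicted replication probability: the same-sign tail
  P(sign(z_r)=sign(z_d), |z_r| ≥ z_α | z_d) = Σ_k w_k ·
  Φ((c_k|z_d| − z_α)/√v_k), with w = (fdr, tdr) and z_α = 1.959964 by
  default (two-sided 0.05 with the same-sign convention). The
  opposite-sign tail is deliberately excluded.

All densities are computed in log space; fdr uses the posterior-odds
logistic form, so extreme |z| never produces 0/0.

## Enrichment scores and strata

The binary outcome Y = 1{p ≤ p_thresh} (default p_thresh = 10⁻³,
inclusive) is regressed on the per-SNP covariates — eight LD-weighted
annotation scores, total LD, heterozygosity, and the squared z of a
secondary pleiotropic trait — by maximum-likelihood logistic
regression (statsmodels). Covariates are standardized at fit time, so
scores are invariant to affine rescaling. The fitted probability is the
SNP's relative enrichment score; scores are binned into K strata
(default equal-width over the observed score range, last bin
right-closed; quantile binning available because equal-width can leave
extreme bins thin). K defaults to 10 for panels of ≥ 10⁵ SNPs and 6
below that, matching the regimes where strata remain well populated.
Whether "equally spaced" bins should span [0,1] or the observed range
was an open choice; the observed range is the default.

Before fitting, the training set should have the extended MHC
(chr6:25652429–33368333, inclusive at both ends) removed and be
LD-pruned at r² < 0.8 keeping the smallest p per block; this is the
caller's responsibility (the pipeline does it when given an LD panel)
and is recorded in the model's provenance string.

Group importance is measured by the change in Nagelkerke's R² (or AUC,
or adjusted R² of a linear regression of unthresholded z²) between the
full model and the model refitted without the group, with a
likelihood-ratio p-value per group.

## Resampling estimator

The J sub-studies are repeatedly randomly partitioned into a discovery
subset (fractions 0.2/0.3/0.4/0.5 of J by default) and its complement.
Each half is meta-analyzed with sample-size weights, z_meta = Σ√n_j
z_j/√Σn_j, the inverse-variance weighting of standardized effects.
Discovery z-scores are binned into 1,001 equal-width bins (default
range [−15, 15]; −log₁₀ p range [0, 12] for rate curves); per-bin
counts, means, and second moments of the replication z accumulate
across iterations. The final curve pools all SNP-iteration pairs,
which is identical to the count-weighted across-iteration average (a
tested invariant). Each iteration is unbiased for the conditional
replication moments; averaging only removes partition noise.

The empirical replication rate is the per-bin fraction with
replication p < 0.05 — sign-free by default, with a sign-consistent
flag (the model's predicted probability is sign-consistent; under the
null the sign-free rate is ~0.05 and the sign-consistent rate ~0.025).

Per-iteration random LD pruning at r² < 0.8 is available (a fresh
seeded visiting order each iteration) and is recommended when the
panel has LD; it is off in the quick synthetic studies, whose SNPs are
simulated independent. A count-weighted cubic regression spline
(default 20 interior knots at count-weighted quantiles of the bin
midpoints) smooths curves for presentation; smoothed values are stored
alongside raw values and the raw values are what estimation consumes.
Iteration seeds spawn deterministically from one master seed, so
results are independent of any parallel scheduling.

## Parameter estimation (quadratic estimating equations)

Per stratum, the loss is the count-weighted squared difference between
the model-implied and empirical conditional replication curves, summed
over fractions and bins, with the mean-curve and second-moment-curve
terms weighted 1:λ (λ = 1 by default; setting λ = 0 fits means only
and demonstrably degrades σ₀² recovery). Weights are normalized within
each fraction, so the loss is invariant to rescaling all counts.

The model curve at a bin midpoint averages the replication moments over
the stratum's empirical H distribution (a deterministic quantile
subsample, 16 points during fitting, 256 in the final lookup). By
default each H is weighted by the marginal density f(z; n, H) — the
posterior weight of H given the observed discovery z — rather than
uniformly; plain averaging is available as an option. This is the
coherent average and measurably improves calibration when H is
heterogeneous.

Optimization is L-BFGS-B over (log₁₀ π₁, σ₀², σ₁², σ₂²) with bounds
π₁ ∈ [10⁻⁶, 0.5], σ₀² ∈ [0.5, 2], σ₁², σ₂² ∈ [0, 100/(n·median H)]
(the upper bound places the large component far beyond any observable
z), seeded Latin-hypercube multi-starts (8 by default), at most 2,000
function evaluations per restart. π₁ and σ₂² trade off along a ridge:
boundary solutions and non-convergence are flagged in the result, and
per-stratum failures are isolated.

## Prediction

A fine lookup grid (z ∈ [−15, 15], step 0.01) of fdr, posterior mean,
replication moments and replication probability is built per stratum
at a stated (n, n_r, z_α) design; per-SNP predictions interpolate
linearly in z on the SNP's stratum grid (z outside the grid is clamped
and flagged). The lookup is per-stratum — there is no interpolation
across the enrichment score. SNPs are ranked by predicted replication
probability (ties broken by smaller p, then SNP id); confident SNPs
(pred ≥ 0.8/0.9) are LD-clumped into independent loci (greedy prune at
r² < 0.1 keeping the best lead, then merging survivors within 250 kbp
on a chromosome).

## LD operators

r² is the squared Pearson correlation of genotype dosage vectors from
a reference panel (VCF or in-memory arrays; a PLINK-binary reader is
out of scope). Pairs beyond the window (default 1 Mbp) or involving a
monomorphic SNP count as 0; values within 10⁻¹² of 1 are snapped to
exactly 1 so the inclusive annotation-score bound of 1.0 behaves as
stated. Annotation scores sum r² between a tag and panel SNPs in each
positional category; total LD sums over all panel SNPs in the window
*including the self-term* (so TLD ≥ 1; configurable, as the convention
is not universal). Membership uses the inclusive bound score ≥ 1.0;
tags below 1 on all categories are intergenic. Pruning is greedy —
best-criterion-first or seeded-random visiting order — with
deterministic (chrom, pos, id) tie-breaks; the surviving set never
contains a pair at or above the threshold, checked exhaustively against
brute-force double loops in the tests.

## Synthetic data

The generators produce exactly the structure the model assumes: that
is their job, and it bounds what the tests show. Covariates are drawn
marginally realistic (sparse nonnegative annotation scores, TLD ≥ 1,
H from MAF ~ U(0.05, 0.5), secondary-trait z² ~ χ²₁); the covariates
act on the mixture weight only, through a logit shift equal to a
linear combination of standardized covariates — the minimal mechanism
consistent with per-stratum fits (component variances are not
modulated). Sub-study z-panels use log-uniform effective sizes
(default 1,000–4,000 per study) and independent noise across studies
(no sample overlap). The block-LD genotype generator produces
equicorrelated blocks via ancestor-copying haplotypes (copy
probability r²^(1/4) gives pairwise genotype r² ≈ the target).

What the generators do *not* emulate: LD between the association
statistics themselves (z-panels are independent across SNPs unless a
genotype panel is wired in), population structure, allele-frequency–
dependent architectures beyond the H scaling, case-control liability
scales, and study-level heterogeneity of true effects. Passing tests
therefore validate the estimator under its own assumptions, not
robustness to their violation.

### Study conditions used by the bundled studies

- Stratified replication study: m = 2×10⁵ SNPs, J = 10 studies,
  π₁ = 0.05, σ₀² = 1, σ₁² = 0, σ₂² = 2×10⁻³ (large-component
  non-centrality n H̄ σ₂² ≈ 8–9 at the split-half size — strong but
  realistic consortium-scale signal), logit-shift weights
  (H, TLD, BIP z², exon) = (0.8, 0.7, 0.5, 0.6), six quantile strata,
  20 resampling iterations.
- Recovery study: m = 2×10⁵, J = 20, π₁ = 0.01, σ₁² = 0, σ₂² set so
  the split-half n H̄ σ₂² = 9; fractions (0.2, 0.3, 0.4, 0.5), 16
  iterations per fraction, 4 restarts.
- Yield study: m = 2–5×10⁴ per seed, J = 10, six strata, fractions
  (0.3, 0.5).

These sizes were chosen as the smallest at which the quantities of
interest are estimated with comfortable margins; quantile strata are
used in the synthetic studies because equal-width bins on a skewed
score distribution leave extreme strata too thin at these m.

## Statistical test conventions

Per-bin "within 3 SE" checks repeated over hundreds of bins are
multiple comparisons: under the null ~0.3% of bins exceed 3 SE by
chance. Tests that sweep bins therefore require ≥ 99% of occupied bins
within 3 SE plus a pooled statistic within 3 pooled SE (and, for the
Monte-Carlo oracle, every comparison within 5 SE). Single-quantity
checks use plain 3-SE bands.

## Known limitations

- The logistic enrichment fit uses the full SNP set once; with many
  trait-specific covariates this can overfit. An odd/even-chromosome
  split or out-of-sample mode (fit on half the studies, evaluate on
  the rest) is the guard.
- π₁ and σ₂² are only jointly identified through curve shape; fits at
  low signal-to-noise hit bounds, which is reported, not hidden.
- The replication law conditions on shared component membership;
  mixtures of three or more Gaussians (heavier tails) are not
  implemented.
- Input dialects: two-sided p↔z only (sign carried separately);
  positions 1-based; no dosage input, no liftover, no VCF-encoded
  association output.
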
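# Methods

## The estimand

For a pair of preadjusted quantitative traits measured on the same n
individuals, the local genetic covariance of an LD window *w* is the
covariance over individuals between the two window-limited genetic scores,
Cov(X_w β₁, X_w β₂), where X_w holds the (mean-imputed, centered) dosages of
the window's member SNPs and β_k the SNP effects on trait k. V₁ and V₂ are
the corresponding variances. These quantities absorb local LD: correlated
SNPs with opposing effects can yield a small score variance even when
individual effects are large, which is exactly what a per-region measure of
shared genetic signal should do.

## Segment-wise bivariate spike-and-slab regression

Fitting all genome-wide SNPs jointly is unnecessary for local estimands and
computationally hostile at biobank scale, so the genome is cut into segments:
non-overlapping cores of `core_size` = 1,000 consecutive SNPs per chromosome
(the last core takes the remainder), each padded with `flank_size` = 250
buffer SNPs per side. Flanks let the regression condition on LD partners just
outside the core; they never seed windows, and each flank lies inside a
neighbouring core, so every SNP's effect is estimated exactly once as a core
member.

Within a segment, Y = 1μ' + Xβ + E with iid bivariate Gaussian errors,
Var(ε_i) = R. Effects follow a spike-and-slab: per SNP j and trait k,
β_jk = d_jk·b_jk with a latent bivariate slab effect b_j ~ N₂(0, Σ),
indicators d_jk ~ Bern(π_k) (a SNP may be active for one trait only), an
Inverse-Wishart prior on R and Σ, and a Beta prior on each π_k. The slab is
kept fully latent — when d_jk = 0 the component b_jk is refreshed from its
conditional prior — so the Σ update stays a conjugate Inverse-Wishart.

The Gibbs sweep updates, in order: μ | rest (flat prior, bivariate Gaussian);
for each SNP, trait-within-SNP, the pair (d_jk, b_jk) with the indicator
drawn from the collapsed Bernoulli (slab integrated out) and the effect from
its Gaussian conditional, using O(n) residual updating; Σ | {b_j} (IW);
R | residuals (IW); π_k | indicator counts (Beta). The kernel is
numba-compiled with hand-rolled 2×2 linear algebra and a Bartlett-based
Inverse-Wishart draw; covariance draws are jittered to positive-definite on
numerical failure, and the indicator probability is computed from log-odds in
a stable form. A fit is bit-reproducible given (data, config, seed).

Chain defaults follow the standard protocol for this model family: 5,000
iterations, burn-in 250, thinning 10, retaining ⌊(5000−250)/10⌋ = 475 draws.

### Default priors

The prior hyperparameters are conventions, overridable in `MTModelConfig`
and recorded in run metadata:

- R: IW(df = 5, scale chosen so the prior **mode** S/(df+3) equals half of
  each trait's sample variance) — agnostic between signal and noise.
- Σ: IW(df = 5, scale so the implied genomic variance, prior mean
  inclusion × Σ_j Var(x_j) × slab variance, covers the other half).
- π_k: Beta(0.1, 9.9) — prior mean 1%, worth 10 pseudo-observations, weak
  enough for the data to dominate.
- Initialisation: μ at the trait means, indicators all zero, R at the sample
  covariance of Y, Σ at its prior mean, π at its prior mean. Burn-in handles
  the rest.

### Sampler validation

Three independent routes check the sampler rather than trusting it:
(i) with the spike disabled (π ≡ 1) and R, Σ fixed, the model is a bivariate
Bayesian ridge whose posterior mean has a closed form (a 2m×2m normal-
equations solve) — the chain agrees within Monte-Carlo error; (ii) a
successive-conditional ("getting it right") run on an 8×4 instance — draw a
state from the prior, simulate data, apply one Gibbs sweep, resimulate,
repeat — leaves the prior invariant, so chain moments of π, diag(Σ), diag(R)
must match analytic prior moments (this check pins μ at zero because the
intercept's flat prior makes the joint otherwise improper); (iii) the
kernel's hand-rolled Inverse-Wishart is cross-checked against scipy's in the
prior-sampling utility.

## LD windows

Each core SNP seeds a window. Walking outward one SNP at a time in each
direction, a candidate passes when |Pearson r(seed, candidate)| ≥ 0.1 on the
imputed dosages; a single failing SNP followed by a passing one is included
(allowance for brief LD loss or minor mapping error); two consecutive
failures terminate the direction with both failures excluded. The walk may
enter the segment's flanks but never leaves the segment. Absolute correlation
is used because the sign of r flips with the arbitrary choice of counted
allele while window membership should not. Exact-duplicate member sets
(common inside tight LD blocks) are merged, keeping the first seed in map
order; both raw and deduplicated counts are logged. Membership depends only
on correlations **with the seed**, so windows are contiguous index runs and
raising the threshold can only shrink them.

## Window posteriors, significance, loci

Per retained draw, (V₁, V₂, Cov) are computed as quadratic forms
β'S_wβ with S_w the n−1-denominator sample covariance of member dosages —
algebraically identical to forming the score vectors explicitly, which the
tests use as the independent route. Summaries are the posterior mean, SD and
the equal-tailed empirical-quantile 95% CR (numpy's linear interpolation);
highest-density intervals would be a defensible alternative but equal-tailed
matches common reporting practice for these models. A window is significant
when its covariance CR excludes zero; no multiple-testing adjustment is
applied (windows are overlapping and strongly dependent; the report carries
the window count so users can post-filter). Significant windows are merged
into loci by transitive closure of "shares ≥ 1 member SNP" (union-find);
each locus reports the member window with the largest |posterior mean Cov|
and its sign as the locus direction. Reports multiply estimates and CRs by
1e4 for readability and record the factor in the header.

## Pipeline determinism

Each segment's chain seed is blake2b(global_seed, chromosome, core_start)
mod 2³¹, so serial and segment-parallel runs agree and adding a chromosome
never perturbs another segment's draws. A manifest records counts at every
stage (SNPs kept, segments, raw/dedup/significant windows, loci) together
with the fully materialised configuration. Re-running only the window stage
from persisted posterior files reproduces the windows report byte for byte.
Validation re-fits the model on a second cohort but scores the *frozen*
discovery window member sets; a window replicates when it is significant
again with the same covariance sign.

## The simulator

`simulate_genotypes` builds block-LD panels: block lengths uniform on
`block_lengths` (default 10–30 SNPs), and within a block each of two
haplotypes is a latent Gaussian AR(1) series (default autocorrelation 0.7)
thresholded at the SNP's MAF-matched normal quantile (MAF uniform on
0.05–0.5); dosages are haplotype sums. Dichotomisation attenuates the
realised dosage correlation below the latent 0.7, giving adjacent-SNP r of
roughly 0.3–0.6 — typical of dense-array data — and ~0 across blocks.
Positions sit on a uniform 3-kb grid.

`simulate_traits` plants effect pairs drawn from N₂(0, Σ_loc) on chosen SNPs
of designated causal blocks, adds residuals from N₂(0, R_true) (default unit
variances, correlation 0.25, mirroring a moderately correlated trait pair),
and forms Y = Xβ + E on centered X with column-centered E, so Y − E ≡ Xβ
exactly and the recorded truth never disagrees with the data. The default
study conditions used by the acceptance checks are n = 1,000 individuals and
p = 600 SNPs per replicate — one full segment — with the chain at its
5,000/250/10 defaults; the planted pleiotropic block uses
Σ_loc = [[0.02, 0.015], [0.015, 0.02]] over 10 causal SNPs, i.e. a local
genetic covariance of ≈ 0.05, about 17% of the total cross-trait covariance
and ~6% local heritability per trait — a strong single locus by field
standards.

What the simulator does **not** emulate: realistic demography or
recombination maps, MAF-dependent architecture, imputation error, relatedness
or population structure. Passing tests therefore demonstrate algorithmic
correctness and behaviour under idealised block LD, not robustness to the
confounders of real cohorts.

## Behaviour of the CR significance rule (measured, not assumed)

Two properties of the Bayesian machinery are worth stating plainly, as the
test suite measures them honestly:

- **Under the null** (no true effects anywhere) the posterior places almost
  all indicator mass at zero, covariance draws are mostly exactly 0, and the
  95% CR virtually never excludes zero: the measured exclusion rate is ≈ 0,
  far *below* the 5% a frequentist test would spend. The CR rule is strongly
  conservative under sparsity priors — a feature for discovery credibility,
  but it means the CR is not a 5%-level test.
- **Near the detectability edge**, shrinkage cuts the other way: when a
  planted signal's per-SNP z-scores sit around 2–4 (as under the default
  planted block at n = 1,000), the spike absorbs one trait's effects in a
  substantial fraction of replicates, the covariance posterior concentrates
  at 0, and the CR misses the nonzero truth — frequentist coverage of the
  credible region is well below nominal there. Coverage is good when the
  signal is decisively detectable (see `examples/01`, where a stronger block
  is recovered with the correct sign). Users should read the CRs as
  model-based posterior statements under a sparsity prior, not as calibrated
  confidence intervals for weak signals.

## Numerical and degenerate-input choices

Missing dosages are mean-imputed per SNP before modelling (keeps X complete
for the sampler); dosages are centered but not variance-standardised, so
effects stay on the per-allele scale and Var(X_w β) is unaffected by
centering. Monomorphic columns survive as all-zero columns (they contribute
nothing to any window variance and correlate with nothing). Zero-variance
columns define correlation 0 in the window walk. Sample (co)variances use
the n−1 denominator throughout. Duplicated trait columns, singular initial
covariance estimates and other degenerate 2×2 matrices are nudged by 1e-10
jitter rather than failing mid-chain.

## Limitations

Two traits only (the model generalises; the implementation commits to the
bivariate case). No relatedness handling, no BGEN dosages, no gene
annotation or eQTL colocalisation of the resulting loci, no multiple-testing
control. Locus condensation uses SNP sharing only; loci that are distinct
here may still tag the same causal gene through long-range LD.
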
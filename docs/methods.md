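# Methods

## The problem

mRNA-Seq measures expression as read counts over genomic segments.  Reads are
short, so a read falling in an exon shared by several splice variants
(isoforms) of a gene does not identify which isoform produced it.  `isobayes`
estimates isoform-level expression from segment-level counts by treating the
isoform expressions as latent variables tied to the observed segments through
a known exon–isoform membership matrix, and quantifies the uncertainty of
every estimate with a full posterior distribution.

## Pseudo-exon partitioning

Isoforms rarely share exons wholly.  For each gene we cut the union of all
isoform exons at every exon boundary of every isoform; the maximal resulting
segments that lie wholly inside or wholly outside each isoform are the
*pseudo-exons*.  Adjacent segments with identical isoform membership and
contiguous coordinates are merged, giving the minimal partition (merging loses
no information and reduces collinearity of the design; the choice is recorded
here because either convention is defensible).  The binary design matrix
`X (m × s)` has `X[i,k] = 1` iff segment `i` belongs to isoform `k`.
Coordinates are 0-based half-open internally; GFF3/GTF input (1-based
inclusive) is converted on read and restored on write.  Strand is recorded
but ignored: the counts being modeled are strand-agnostic.

Genes in which two isoforms have identical design columns are unidentifiable
at the likelihood level; they are flagged and sampled anyway (label switching
is reported, isoforms are never silently merged).

## Normalization

Three normalizers, all monotone within a sample:

* **RPKM**: `n / (ℓ_kb × N_millions)` with `N` the per-sample total mapped
  reads — the standard length- and depth-scaled measure.
* **Global**: each sample scaled by `(reference total)/(its total)`; reference
  is the across-sample mean total by default, or a named sample.  Column
  totals agree to 1e-9 relative after scaling.
* **Percentile (10–90)**: each sample is divided by the ratio of its trimmed
  mean (values strictly between its own nearest-rank 10th and 90th
  percentiles, zeros included) to the across-sample mean of those trimmed
  means.  Totals are *not* re-equalized afterwards.  The trimmed mean of the
  percentile body was chosen over a single quantile (e.g. the upper quartile)
  because it uses the whole body the method is meant to match; this is a
  genuinely open design point and is configurable through `lo_pct`/`hi_pct`.

The percentile method exists for the heavy-tailed-condition problem: when one
condition inflates a small fraction of regions enormously (a heat-shock-like
response), equalizing totals drags that condition's entire distribution body
down.  Matching the 10–90 body instead leaves the extreme tail as biology.
The package's `decile_discrepancy` summary (max cross-sample relative spread
of the decile values) quantifies the contrast.

All percentiles everywhere in the package are nearest-rank (the value at rank
`ceil(p/100·n)`), which is reproducible and estimator-free.

## The hierarchical model

For gene `g` with `m` segments, `s` isoforms, normalized segment expression
`y_l` in sample `l`:

    Y_l | I_l, β_l, τ_l ~ N_m(X β*_l, τ_l⁻¹ I_m)  truncated below at 0,
    β*_kl = I_kl · β_kl
    β_kl  ~ N(μ0_k, 1/τ0_k) truncated below at 0
    I_kl  ~ Bernoulli(p)
    τ_l   ~ Gamma(α1, α2)         — segment noise precision, per gene × sample
    τ0_k  ~ Gamma(α1⁰, α2⁰)       — isoform precision, pooled across samples

This is a Kuo–Mallick spike-and-slab: the indicator multiplies an
always-present coefficient, so "expressed at all" and "expressed how much"
are separate parameters.  `1/τ0_k` measures how variable isoform `k` is
across conditions and drives the variability classification.

Defaults: `α1 = α2 = α1⁰ = α2⁰ = 0.01` (diffuse), `p = 0.5` (uninformative
presence).  `μ0` defaults to the gene's pooled 10–90% trimmed mean of `y` —
a data-scale anchor constant across isoforms; inference is insensitive to
reasonable alternatives, and a scalar or per-isoform value can be supplied.

### Sampling

Metropolis-within-Gibbs, exact in every update:

* `I_kl` — exact Bernoulli full conditional: odds are prior odds times the
  truncated-normal likelihood ratio at the current `β_kl` (rows outside the
  isoform cancel).
* `β_kl` — slice sampling (stepping-out + shrinkage) on `[0, ∞)` when
  `I_kl = 1`; refreshed from its prior when `I_kl = 0` (the Kuo–Mallick
  decoupling, which keeps the indicator conditional well-defined).
* `τ_l`, `τ0_k` — independence Metropolis–Hastings with the conjugate Gamma
  proposal computed as if the likelihood were untruncated; the accept step
  corrects for the truncation normalizers `Π_i Φ(μ_i√τ)`.  Since means are
  non-negative each factor lies in [½, 1], so acceptance is high.

Defaults: 2 chains, 8000 retained iterations after 2000 burn-in, thin 1.
Initialization: `β` from the prior truncated at the data maximum, `I = 1`,
`τ` at method-of-moments from the residuals, jittered per chain so chains
start from random points.  Each gene's seed is derived from the base seed and
a hash of the gene id, so results are invariant to gene processing order and
fully reproducible from one integer.  With `prior_only=True` the likelihood
is switched off and the sampler targets the joint prior (used to validate
that `τ` draws reproduce the Gamma prior's mean and variance).

Correctness is validated two ways: a brute-force quadrature oracle
(`grid_indicator_posterior`) that enumerates indicator configurations and
integrates the likelihood against the priors on a parameter grid agrees with
the MCMC indicator posterior to total variation < 0.01 on tiny genes; and
prior-only runs recover the Gamma prior moments.

### Diagnostics

Per parameter: posterior mean/SD, Monte-Carlo standard error, effective
sample size and split-R̂ (via ArviZ).  Parameters whose MCSE exceeds 5% of
the posterior SD are flagged.  Single-chain fits omit R̂ with a warning.

## Posterior decision rules

* **Presence**: posterior mean of `I_kl`.
* **High/low expression**: an isoform×sample is *low* when the 95th
  percentile of its expression PPI falls below the 10th percentile of all
  posterior-mean expressions, *high* when its 5th PPI percentile exceeds the
  90th percentile of the means — i.e. with 95% posterior probability it sits
  in the bottom or top decile of expressions.
* **Bayesian t**: per draw, `t = (β*_l1 − β*_l2)/√(1/(m τ_l1) + 1/(m τ_l2))`.
  The exact functional form of this contrast was an open design point; the
  implemented form is a difference over the root-sum of the two samples'
  noise variances averaged over the gene's `m` segments, which is
  antisymmetric, scale-invariant, and makes the critical value depend on the
  exon count.  Three decision rules: R1, the 95% symmetric PPI of `t`
  excludes zero; R2, the PPI lies wholly in the upper or lower decile of all
  isoforms' mean `t` values (rank-based, usable even for single-segment
  isoforms); R3, |posterior mean t| exceeds the two-sided 5% Student-t
  critical value with `2(m−1)` degrees of freedom (two samples of `m` segment
  observations), defined only for `m ≥ 2`.
* **Indicator differential**: declared differential when presence probability
  is ≥ conf in one sample and ≤ 1−conf in the other (default 0.95),
  regardless of amount — the rule that sidesteps the classical t-statistic's
  collapse when one sample has zero counts.
* **Variability**: isoforms are classed by the posterior mean of `1/τ0_k`
  (a variance; `use='precision'` switches to `τ0` itself) against the
  nearest-rank 35th/65th/90th percentiles with strict inequalities: low /
  mid / moderate / high.  A Gamma distribution is fitted to the variability
  values by maximum likelihood with a QQ table and the fraction of isoforms
  beyond the fitted upper tail (configurable, default 5%).

No multiple-testing correction is applied anywhere: R2 is itself a rank-based
selection and the other rules are posterior probability statements.  Users
comparing many isoforms at fixed frequentist error rates should apply their
own FDR control downstream.

## Classical baselines

Two-sample count tests under the Poisson framework, with normalizing
constants `C`: exact binomial (`n1 | n1+n2 ~ Bin(n1+n2, C1/(C1+C2))`),
Audic–Claverie (`n2 | n1 ~ NB(n1+1, C1/(C1+C2))`), and the chi-square
goodness-of-fit with expected counts `m_i = C_i(n1+n2)/(C1+C2)`.
Two-sidedness doubles the smaller tail, capped at 1.  All return a no-call on
`(0, 0)`.  Note the Audic–Claverie construction conditions on the first
sample's count; swapping samples switches the conditioning variable, so exact
numeric symmetry holds only up to discreteness (verdicts agree; the p-values
differ by `O(pmf)`).

GLMs: Poisson-log with `log E[n] = log d + λ_{a(i)}` in condition-mean
parameterization (per-sample closed form `log(n/d)` when conditions are
unreplicated), and a Gaussian family (ordinary least squares) for normalized
continuous expression on the segment×isoform design.  The length-bias
demonstration is the closed form `T(L) = (λ1−λ2)/√(λ1+λ2) · √L`: an `L`-fold
longer gene inflates |t| by exactly `√L` with no change in expression ratio.

## Synthetic data

The generator emulates the study design the model targets: ~50 genes by
default, 84% single-isoform and the rest carrying 2–4 isoforms built by exon
skipping (isoform 1 always keeps the full chain, skip patterns are distinct,
so designs are identifiable by construction); exon counts 1–10 (shifted
Poisson, mean 3.5); log-normal exon lengths clipped to 50–2000 b; six samples
with unequal library sizes; presence Bernoulli(0.5); isoform expression
TruncNormal(5, 1) against segment noise SD 1 — a five-sigma effect chosen so
presence is recoverable but not trivial; Poisson counts with rates
proportional to expression × segment length × library size (reproducing
length bias); and one heavy-tailed sample whose top 1% of rates is multiplied
by 100 (the heat-shock-like condition).

What the generator does **not** emulate: positional/3′ coverage bias,
GC/base-composition bias, reads spanning splice junctions, multi-gene
mapping, or an elevated zero fraction in the heavy-tailed condition.  Passing
recovery tests therefore show correctness of the inference under the model's
own assumptions, not robustness to these real-data artifacts.

## Known properties and limitations

* On well-specified synthetic data, 95% posterior intervals for present
  isoforms' expression cover the truth at ~90–95% and the presence AUC
  exceeds 0.95.  The posterior mean of `β* = I·β` is systematically shrunk
  toward zero whenever presence is not fully resolved (it mixes the spike);
  with small segment counts and a free per-gene×sample noise variance the
  shrinkage reaches 10–20% relative.  When a point estimate of expression
  *given presence* is wanted, average the `β*` draws over `I = 1` draws only.
* Single-segment genes carry very weak evidence about the noise precision, so
  their presence probabilities stay moderate even for clear signals — the
  indicator rule compensates at the decision level.
* The quadrature oracle is exact only up to grid resolution and is restricted
  to tiny genes (`s ≤ 3`, one sample); it is a validation device, not an
  inference path.

## Problem sizes used in validation

The test-suite and acceptance-script runs use: 50 genes × 6 samples with
2 chains × 2500 retained draws (burn-in 800) for recovery; 50k retained draws
for the oracle comparison; 2000 simulated null genes for p-value uniformity;
500 genes for the length-bias law; and a 12-gene pipeline run twice for
byte-level determinism.  These sizes give Monte-Carlo error comfortably below
the asserted tolerances while keeping a full run in minutes on one core;
defaults for real analyses are larger (8000 draws, burn-in 2000).
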
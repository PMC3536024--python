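# isobayes

Bayesian hierarchical estimation of **isoform-level expression** from
exon-level mRNA-Seq read counts.

Short sequencing reads rarely identify which splice variant of a gene they
came from: most exons are shared between isoforms.  Given a known splicing
structure, `isobayes` partitions each gene's exons into *pseudo-exons*
(maximal segments wholly inside or outside every isoform), links the observed
segment expression to latent isoform expressions through the binary
segment×isoform design matrix, and fits, per gene, the spike-and-slab
hierarchy

```
y_il  = Σ_k I_kl · β_kl · X_ik + ε_il            (sample l, segment i)

Y_l | I_l, β_l, τ_l ~ N_m(X β*_l, τ_l⁻¹ I)  truncated below at 0
β_kl ~ N(μ0, 1/τ0_k) ≥ 0      I_kl ~ Bernoulli(p)
τ_l  ~ Gamma(α1, α2)          τ0_k ~ Gamma(α1⁰, α2⁰)
```

by Metropolis-within-Gibbs MCMC.  The latent indicator `I_kl` ("is isoform k
expressed in sample l at all?") and the expression amount `β_kl` are separate
parameters, which yields presence/absence calls for free, regularizes the
deconvolution, and gives a differential-expression rule that survives zero
counts in one condition — exactly where classical t-statistics collapse.
The posterior supports: presence probabilities, high/low expression calls,
a Bayesian t contrast with three decision rules, an indicator-based
differential rule, cross-condition variability classes from `1/τ0`, and
gene-level totals.  Classical baselines (exact binomial, Audic–Claverie,
chi-square, Poisson-log/Gaussian GLMs, the √L length-bias law) are included
for comparison, along with RPKM / global / 10–90-percentile normalization and
a fully synthetic data generator, so everything runs with no downloads.

Audience: statisticians and computational biologists analyzing multi-condition
RNA-Seq with known transcript annotations who want uncertainty-aware
isoform-level estimates rather than gene-level counts.

## Worked example

```python
import isobayes as ib
import isobayes.io as iio

cfg = ib.SimulationConfig(n_genes=20, seed=42)        # synthetic study, 6 samples
genes, parts = ib.simulate_annotation(cfg)
truth, expr  = ib.simulate_expression(parts, cfg)

gene_data = iio.gene_data_from(parts, expr)
fits = ib.fit_genes(gene_data, ib.Hyperparameters(),
                    ib.MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=7))

summary = ib.isoform_summaries(fits)
print(summary[summary.gene_id == "G0003"].round(3))
```

prints (isoform `G0003.1` of a two-isoform gene):

```
gene_id isoform_id sample_id  presence_prob  expr_mean  expr_sd  ppi_5  ppi_95
  G0003    G0003.1        S1          0.970      5.085    1.069  3.899   5.959
  G0003    G0003.1        S2          0.852      4.933    2.430  0.000   7.973
  G0003    G0003.1        S3          0.103      0.302    1.018  0.000   2.862
  G0003    G0003.1        S4          0.721      3.393    2.316  0.000   6.266
  G0003    G0003.1        S5          0.026      0.041    0.356  0.000   0.000
  G0003    G0003.1        S6          0.921      4.628    1.564  0.000   6.143
```

`presence_prob` is the posterior probability that the isoform is expressed in
that sample; the generating truth had it present in S1, S2, S4 and S6
(true expressions 5.24, 7.58, 4.48, 3.71) and absent in S3 and S5 — the
posterior tracks it.  `expr_mean`/`ppi_*` summarize the posterior of
`β* = I·β`; where this isoform shares segments with its sibling the intervals
widen and part of the signal is honestly attributed to either isoform rather
than silently assigned.  Downstream calls:

```python
labels = ib.call_high_low(summary)                   # high / low / none per isoform×sample
calls  = ib.differential_calls(fits, ("S2", "S1"))   # three t-based rules
ib.indicator_differential(fits["G0003"], "G0003.1", ("S5", "S1"))  # -> "down"
```

The same pipeline runs from the shell:

```bash
isobayes simulate  --out bundle --seed 4
isobayes partition --annotation bundle/annotation.gff3 --out parts.tsv
isobayes normalize --counts bundle/counts.tsv --method percentile --out expr.tsv
isobayes fit       --partitions parts.tsv --expression expr.tsv --seed 9 --out fit/
isobayes call      --fits fit/ --control S1 --out calls/
```

All outputs are TSVs with provenance headers; reruns with the same seed are
byte-identical.

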
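"""Synthetic annotations, expression truths and count matrices.

The generator emulates the statistical structure the hierarchical model
assumes, at the scale of the motivating dataset: a minority of multi-isoform
genes (84% of genes are single-isoform), six samples (five treatment-like
conditions plus a control), Bernoulli isoform presence, truncated-normal
expression, Poisson read counts with length-proportional rates and unequal
library sizes, and one heavy-tailed sample in which a small fraction of
segments is extremely amplified (the heat-shock-like condition: more zeros
elsewhere cannot be emulated without breaking the count link, but the
inflated top tail — the feature that breaks global normalization — is).

Everything is driven by a single integer seed; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .gene_models import GeneModel, PseudoExonPartition, build_pseudo_exons
from .normalization import CountMatrix, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_annotation",
    "simulate_expression",
    "simulate_counts",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults: 50 genes, 84% single-isoform and the rest carrying 2-4
    isoforms; exon counts 1-10 (shifted Poisson); log-normal exon lengths
    clipped to 50-2000 bases; six samples with the last one heavy-tailed;
    presence prior 0.5; isoform expression TruncNormal(5, 1) against noise
    SD 1 (a five-sigma effect: recoverable, not trivial); unequal library
    size factors.
    """

    n_genes: int = 50
    isoform_probs: dict = field(
        default_factory=lambda: {1: 0.84, 2: 0.08, 3: 0.05, 4: 0.03}
    )
    exon_count_mean: float = 3.5  # 1 + Poisson(mean - 1), capped at 10
    exon_length_log_mean: float = 5.3  # ~200 b median
    exon_length_log_sd: float = 0.7
    exon_length_min: int = 50
    exon_length_max: int = 2000
    n_samples: int = 6
    heavy_tail_sample: int = 5  # index of the heavy-tailed condition
    heavy_tail_factor: float = 100.0
    heavy_tail_top_frac: float = 0.01
    p_true: float = 0.5
    beta_mu: float = 5.0
    beta_sigma: float = 1.0
    tau_true: float = 1.0  # segment-noise precision (SD = 1)
    library_sizes: tuple = (1.0, 0.85, 1.2, 0.9, 1.1, 1.05)
    depth: float = 200.0  # expected reads per kb per unit expression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("sizes must be >= 1")
        if not 0 <= self.p_true <= 1:
            raise ValueError("p_true must be in [0, 1]")
        if abs(sum(self.isoform_probs.values()) - 1.0) > 1e-9:
            raise ValueError("isoform_probs must sum to 1")
        if len(self.library_sizes) < self.n_samples:
            raise ValueError("need a library size per sample")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class TruthTable:
    """Ground truth for every latent quantity of the hierarchical model."""

    presence: pd.DataFrame  # gene_id, isoform_id, sample_id, I_true, beta_true, beta_star_true
    noise: pd.DataFrame  # gene_id, sample_id, tau_true
    isoform_precision: pd.DataFrame  # gene_id, isoform_id, tau0_true


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _truncnorm(rng: np.random.Generator, mu, sigma, size) -> np.ndarray:
    """Elementwise N(mu, sigma^2) truncated below at zero via inverse CDF."""
    from scipy.special import ndtr, ndtri

    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    lo = ndtr(-mu / sigma)
    u = lo + rng.random(size) * (1.0 - lo)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return np.maximum(0.0, mu + sigma * ndtri(u))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[PseudoExonPartition]]:
    """Random gene models with exon-skipping isoform structures.

    Isoform 1 always carries the full exon chain (so the exon union is
    covered); further isoforms skip random proper subsets of exons, distinct
    from each other, which guarantees no duplicate design columns
    (identifiable by construction).
    """
    rng = _rng(config, 0)
    iso_counts = np.array(sorted(config.isoform_probs))
    iso_p = np.array([config.isoform_probs[int(c)] for c in iso_counts])
    genes: list[GeneModel] = []
    cursor = 1000
    for g in range(config.n_genes):
        n_iso = int(rng.choice(iso_counts, p=iso_p))
        n_exons = 1 + int(rng.poisson(config.exon_count_mean - 1))
        n_exons = min(max(n_exons, 1), 10)
        if n_iso > 1:
            # need enough exons for distinct skipping patterns
            n_exons = max(n_exons, int(np.ceil(np.log2(n_iso))) + 1, 2)
        lengths = np.clip(
            rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd, n_exons),
            config.exon_length_min,
            config.exon_length_max,
        ).astype(int)
        introns = rng.integers(60, 300, n_exons)
        exons = []
        pos = cursor
        for ln, intron in zip(lengths, introns):
            exons.append((pos, pos + int(ln)))
            pos += int(ln) + int(intron)
        cursor = pos + int(rng.integers(500, 1500))

        gene_id = f"G{g + 1:04d}"
        subsets: list[tuple[int, ...]] = [tuple(range(n_exons))]
        attempts = 0
        while len(subsets) < n_iso and attempts < 200:
            attempts += 1
            keep = tuple(i for i in range(n_exons) if rng.random() < 0.7)
            if len(keep) == 0 or keep in subsets:
                continue
            subsets.append(keep)
        isoforms = [
            (f"{gene_id}.{j + 1}", [exons[i] for i in keep])
            for j, keep in enumerate(subsets)
        ]
        genes.append(GeneModel(gene_id=gene_id, chrom="chrS", strand="+", isoforms=isoforms))
    partitions = [build_pseudo_exons(g) for g in genes]
    return genes, partitions


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        start = min(s for _, exons in gene.isoforms for s, _ in exons) + 1
        end = max(e for _, exons in gene.isoforms for _, e in exons)
        strand = gene.strand if gene.strand in ("+", "-") else "."
        lines.append(
            f"{gene.chrom}\tisobayes\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene.gene_id}"
        )
        for iso_id, exons in gene.isoforms:
            istart = exons[0][0] + 1
            iend = exons[-1][1]
            lines.append(
                f"{gene.chrom}\tisobayes\tmRNA\t{istart}\t{iend}\t.\t{strand}\t.\t"
                f"ID={iso_id};Parent={gene.gene_id}"
            )
            for j, (s, e) in enumerate(exons):
                lines.append(
                    f"{gene.chrom}\tisobayes\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={iso_id}.exon{j + 1};Parent={iso_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression and counts
# ---------------------------------------------------------------------------


def simulate_expression(
    partitions: list[PseudoExonPartition], config: SimulationConfig
) -> tuple[TruthTable, ExpressionMatrix]:
    """Draw latent truths and the model-scale expression matrix.

    Generative direction of the hierarchy: I ~ Bernoulli(p_true), beta ~
    TruncNormal(beta_mu, beta_sigma^2) >= 0, and per segment
    y ~ TruncNormal(X beta*, 1/tau_true) >= 0 elementwise.
    """
    rng = _rng(config, 1)
    sample_ids = config.sample_ids
    L = config.n_samples
    noise_sd = 1.0 / np.sqrt(config.tau_true) if np.isfinite(config.tau_true) else 0.0
    tau0_true = 1.0 / config.beta_sigma**2

    pres_rows, noise_rows, prec_rows = [], [], []
    y_blocks = []
    index_tuples = []
    for part in partitions:
        s = len(part.isoform_ids)
        m = part.n_segments
        I = (rng.random((s, L)) < config.p_true).astype(int)
        beta = _truncnorm(rng, config.beta_mu, config.beta_sigma, (s, L))
        bstar = I * beta
        mu = part.design.astype(float) @ bstar  # (m, L)
        if noise_sd > 0:
            y = _truncnorm(rng, mu, noise_sd, (m, L))
        else:
            y = mu.copy()
        y_blocks.append(y)
        index_tuples.extend((part.gene_id, i) for i in range(m))
        for k, iso in enumerate(part.isoform_ids):
            prec_rows.append((part.gene_id, iso, tau0_true))
            for l, sid in enumerate(sample_ids):
                pres_rows.append(
                    (part.gene_id, iso, sid, int(I[k, l]), float(beta[k, l]), float(bstar[k, l]))
                )
        for sid in sample_ids:
            noise_rows.append((part.gene_id, sid, config.tau_true))

    index = pd.MultiIndex.from_tuples(index_tuples, names=["gene_id", "segment_index"])
    values = pd.DataFrame(np.vstack(y_blocks), index=index, columns=sample_ids)
    lengths = pd.Series(
        np.concatenate([p.lengths for p in partitions]), index=index, name="length"
    )
    truth = TruthTable(
        presence=pd.DataFrame(
            pres_rows,
            columns=["gene_id", "isoform_id", "sample_id", "I_true", "beta_true", "beta_star_true"],
        ),
        noise=pd.DataFrame(noise_rows, columns=["gene_id", "sample_id", "tau_true"]),
        isoform_precision=pd.DataFrame(
            prec_rows, columns=["gene_id", "isoform_id", "tau0_true"]
        ),
    )
    expr = ExpressionMatrix(
        values=values, lengths=lengths, provenance={"method": "synthetic-truth"}
    )
    return truth, expr


def simulate_counts(
    partitions: list[PseudoExonPartition],
    truth_expr: ExpressionMatrix,
    config: SimulationConfig,
) -> CountMatrix:
    """Poisson read counts from the true segment expression.

    Rates are expression x segment length (kb) x library size x depth —
    length-proportional, reproducing the documented length bias.  In the
    heavy-tailed sample the top ``heavy_tail_top_frac`` of positive rates is
    multiplied by ``heavy_tail_factor``.
    """
    rng = _rng(config, 2)
    lib = np.asarray(config.library_sizes[: config.n_samples], dtype=float)
    vals = truth_expr.values.to_numpy(dtype=float)
    lengths_kb = truth_expr.lengths.to_numpy(dtype=float) / 1000.0
    rates = vals * lengths_kb[:, None] * lib[None, :] * config.depth
    h = config.heavy_tail_sample
    if h is not None and 0 <= h < config.n_samples and config.heavy_tail_factor != 1.0:
        col = rates[:, h]
        pos = col[col > 0]
        if pos.size:
            cutoff = np.quantile(pos, 1.0 - config.heavy_tail_top_frac)
            col[col >= max(cutoff, np.min(pos))] *= config.heavy_tail_factor
            # guard: at least the single largest rate is amplified
            rates[:, h] = col
    counts = rng.poisson(rates)
    frame = pd.DataFrame(
        counts, index=truth_expr.values.index, columns=truth_expr.values.columns
    )
    return CountMatrix(counts=frame, lengths=truth_expr.lengths)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(outdir: str, config: SimulationConfig | None = None) -> dict:
    """Generate and write the full bundle: GFF3, counts TSV, truth TSVs,
    config JSON and a checksum manifest.  Returns the manifest dict."""
    from . import io as iio

    config = config or SimulationConfig()
    os.makedirs(outdir, exist_ok=True)
    genes, partitions = simulate_annotation(config)
    truth, expr = simulate_expression(partitions, config)
    counts = simulate_counts(partitions, expr, config)

    paths = {
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "truth_expression": os.path.join(outdir, "truth_expression.tsv"),
        "truth_presence": os.path.join(outdir, "truth_presence.tsv"),
        "truth_noise": os.path.join(outdir, "truth_noise.tsv"),
        "truth_isoform_precision": os.path.join(outdir, "truth_isoform_precision.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    write_gff3(genes, paths["annotation"])
    iio.write_counts_table(counts, paths["counts"])
    iio.write_expression_table(expr, paths["truth_expression"])
    truth.presence.to_csv(paths["truth_presence"], sep="\t", index=False)
    truth.noise.to_csv(paths["truth_noise"], sep="\t", index=False)
    truth.isoform_precision.to_csv(paths["truth_isoform_precision"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "seed": config.seed,
        "files": {name: {"path": os.path.basename(p), "sha256": _sha256(p)} for name, p in paths.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
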
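"""Count-matrix normalization: RPKM, global (total-count) and percentile scaling.

Global normalization equalizes per-sample totals, which lets a handful of very
highly expressed regions in one sample depress that sample's whole
distribution.  Percentile normalization instead matches the 10th-90th
percentile body of the per-sample distributions and deliberately leaves the
extreme tails untouched, so a condition whose biology genuinely inflates a few
regions (the heavy-tailed, heat-shock-like case) is not artificially scaled
down.  Totals are *not* re-equalized after percentile adjustment.

All percentiles here are nearest-rank, shared with :mod:`isobayes.gene_models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import nearest_rank_percentile

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "rpkm",
    "global_normalize",
    "percentile_normalize",
    "percentile_profile",
    "decile_discrepancy",
    "counts_to_expression",
]


@dataclass
class CountMatrix:
    """Per-pseudo-exon read counts.

    ``counts``: DataFrame indexed by ``(gene_id, segment_index)`` with one
    integer column per sample.  ``lengths``: per-segment length in bases,
    same index.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every segment needs a positive length")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Normalized per-pseudo-exon expression values with provenance."""

    values: pd.DataFrame
    lengths: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        factors = self.provenance.get("factors")
        if factors is not None and any(f <= 0 for f in factors.values()):
            raise ValueError("scale factors must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def method(self) -> str | None:
        return self.provenance.get("method")


def _check_totals(counts: CountMatrix) -> pd.Series:
    totals = counts.totals().astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total mapped reads: {list(zero.index)}")
    return totals


def rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of region per million mapped reads.

    ``RPKM_il = n_il / (l_i * N_l) * 1e9`` with ``N_l`` the sample's total
    mapped reads.
    """
    totals = _check_totals(counts)
    vals = counts.counts.div(counts.lengths, axis=0).div(totals, axis=1) * 1e9
    return ExpressionMatrix(
        values=vals,
        lengths=counts.lengths,
        provenance={"method": "rpkm", "factors": {s: float(t) for s, t in totals.items()}},
    )


def global_normalize(
    counts: CountMatrix | ExpressionMatrix, reference: str = "mean-total"
) -> ExpressionMatrix:
    """Scale each sample by (reference total) / (its total).

    ``reference`` is ``"mean-total"`` (across-sample mean of the totals) or a
    sample id.  After scaling, all column totals equal the reference total.
    """
    if isinstance(counts, CountMatrix):
        frame, lengths = counts.counts.astype(float), counts.lengths
    else:
        frame, lengths = counts.values, counts.lengths
    totals = frame.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total: {list(zero.index)}")
    if reference == "mean-total":
        ref_total = float(totals.mean())
    elif reference in frame.columns:
        ref_total = float(totals[reference])
    else:
        raise ValueError(f"unknown reference {reference!r}")
    factors = ref_total / totals
    vals = frame.mul(factors, axis=1)
    return ExpressionMatrix(
        values=vals,
        lengths=lengths,
        provenance={
            "method": "global",
            "reference": reference,
            "factors": {s: float(f) for s, f in factors.items()},
        },
    )


def _trimmed_mean(col: np.ndarray, lo_pct: float, hi_pct: float) -> float:
    """Mean of the values strictly between the sample's lo/hi nearest-rank
    percentiles; falls back to the inclusive body when the strict one is empty
    (near-constant samples)."""
    lo = nearest_rank_percentile(col, lo_pct)
    hi = nearest_rank_percentile(col, hi_pct)
    body = col[(col > lo) & (col < hi)]
    if body.size == 0:
        body = col[(col >= lo) & (col <= hi)]
    if body.size == 0:  # cannot happen, but keep total order
        body = col
    return float(body.mean())


def percentile_normalize(
    values: ExpressionMatrix, lo_pct: float = 10, hi_pct: float = 90
) -> ExpressionMatrix:
    """Match the 10th-90th percentile body across samples.

    Each sample's scale factor is its trimmed mean (values strictly inside its
    own lo/hi percentiles, zeros included when computing the percentiles)
    relative to the across-sample mean of those trimmed means; the sample is
    divided by its factor.  Totals are left alone afterwards: an extreme upper
    tail in one condition is treated as biology, not as an artifact.
    """
    if lo_pct >= hi_pct:
        raise ValueError(f"lo_pct {lo_pct} must be < hi_pct {hi_pct}")
    if values.method not in (None, "global"):
        log.warning(
            "percentile_normalize expects globally normalized input, got %r", values.method
        )
    frame = values.values
    tmeans = {}
    for s in frame.columns:
        col = frame[s].to_numpy(dtype=float)
        if not (col > 0).any():
            raise ValueError(f"sample {s!r} is all zero")
        tmeans[s] = _trimmed_mean(col, lo_pct, hi_pct)
    ref = float(np.mean(list(tmeans.values())))
    factors = {s: tm / ref for s, tm in tmeans.items()}
    vals = frame.div(pd.Series(factors), axis=1)
    return ExpressionMatrix(
        values=vals,
        lengths=values.lengths,
        provenance={
            "method": "percentile",
            "lo_pct": lo_pct,
            "hi_pct": hi_pct,
            "factors": factors,
        },
    )


def percentile_profile(
    values: pd.DataFrame | ExpressionMatrix, include_top: bool = False
) -> dict:
    """Per-sample decile table plus within-decile mean expression.

    Returns ``{"deciles": DataFrame, "decile_means": DataFrame}``; rows are the
    deciles 10..90 (the top decile boundary is omitted unless ``include_top``,
    since a handful of extreme regions dominate it), columns are samples.
    ``decile_means`` holds the mean expression within each rank decile bin.
    """
    frame = values.values if isinstance(values, ExpressionMatrix) else values
    if frame.shape[1] < 1:
        raise ValueError("need at least one sample column")
    pcts = list(range(10, 100, 10)) + ([100] if include_top else [])
    deciles = pd.DataFrame(
        {
            s: [nearest_rank_percentile(frame[s].to_numpy(), p) for p in pcts]
            for s in frame.columns
        },
        index=pd.Index(pcts, name="percentile"),
    )
    dec_means = {}
    for s in frame.columns:
        col = np.sort(frame[s].to_numpy(dtype=float))
        n = col.size
        bounds = [int(np.ceil(j / 10.0 * n)) for j in range(11)]
        means = []
        for j in range(10):
            chunk = col[bounds[j] : bounds[j + 1]]
            means.append(float(chunk.mean()) if chunk.size else np.nan)
        dec_means[s] = means
    decile_means = pd.DataFrame(
        dec_means, index=pd.Index(range(1, 11), name="decile_bin")
    )
    if not include_top:
        decile_means = decile_means.iloc[:9]
    return {"deciles": deciles, "decile_means": decile_means}


def decile_discrepancy(values: pd.DataFrame | ExpressionMatrix) -> float:
    """Max over deciles 10..90 of the cross-sample relative spread
    ``(max - min) / mean`` of the decile values; the scalar summary of how far
    the samples' distribution bodies disagree."""
    deciles = percentile_profile(values)["deciles"]
    spread = []
    for _, row in deciles.iterrows():
        mu = row.mean()
        if mu > 0:
            spread.append((row.max() - row.min()) / mu)
    return float(max(spread)) if spread else 0.0


def counts_to_expression(
    counts: CountMatrix, method: str = "global", reference: str = "mean-total"
) -> ExpressionMatrix:
    """Counts -> model-ready expression: normalize, then divide by segment
    length in kb, giving RPKM-like continuous values the hierarchical model
    consumes as ``y``."""
    if method == "rpkm":
        norm = rpkm(counts)
        return norm
    norm = global_normalize(counts, reference=reference)
    if method == "percentile":
        norm = percentile_normalize(norm)
    elif method != "global":
        raise ValueError(f"unknown normalization method {method!r}")
    vals = norm.values.div(counts.lengths / 1000.0, axis=0)
    prov = dict(norm.provenance)
    prov["per_kb"] = True
    return ExpressionMatrix(values=vals, lengths=counts.lengths, provenance=prov)
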
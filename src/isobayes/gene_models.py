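"""Gene annotation models and pseudo-exon partitioning.

Isoforms of a gene share exons, often only partially.  To obtain observation
units that are wholly inside or wholly outside every isoform, exons are cut at
every exon boundary of every isoform of the gene; the resulting maximal disjoint
segments are the *pseudo-exons*.  Each gene then carries a binary design matrix
``X`` of shape ``(m, s)`` (segments x isoforms) with ``X[i, k] = 1`` iff segment
``i`` belongs to isoform ``k``; this matrix links observed segment-level
expression to latent isoform-level expression.

Coordinates are 0-based half-open internally; GFF3/GTF input (1-based,
inclusive) is converted on read and converted back by the writers.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PseudoExonPartition",
    "LengthClassTable",
    "AnnotationFormatError",
    "read_gene_models",
    "build_pseudo_exons",
    "classify_segment_lengths",
    "nearest_rank_percentile",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with its known isoform exon structures.

    ``isoforms`` maps isoform id -> list of exon intervals ``(start, end)``
    in 0-based half-open genomic coordinates, sorted and non-overlapping
    within each isoform.
    """

    gene_id: str
    chrom: str
    strand: str  # '+', '-' or 'unknown'
    isoforms: list[tuple[str, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id}: no isoforms")
        seen: set[str] = set()
        cleaned = []
        for iso_id, exons in self.isoforms:
            if iso_id in seen:
                raise ValueError(f"gene {self.gene_id}: duplicate isoform id {iso_id!r}")
            seen.add(iso_id)
            if not exons:
                raise ValueError(f"gene {self.gene_id}: isoform {iso_id!r} has no exons")
            for s, e in exons:
                if e <= s:
                    raise AnnotationFormatError(
                        f"gene {self.gene_id}, isoform {iso_id}: exon end {e} <= start {s}"
                    )
            exons = _merge_intervals(sorted(exons))
            cleaned.append((iso_id, exons))
        self.isoforms = cleaned
        if self.strand not in ("+", "-"):
            self.strand = "unknown"

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)

    @property
    def isoform_ids(self) -> list[str]:
        return [iso_id for iso_id, _ in self.isoforms]


@dataclass
class PseudoExonPartition:
    """Disjoint pseudo-exon segments of a gene plus the segment x isoform design matrix."""

    gene_id: str
    chrom: str
    segments: list[tuple[int, int]]  # 0-based half-open, genomic ascending
    design: np.ndarray  # (m, s) binary
    isoform_ids: list[str]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=np.int8)
        m, s = self.design.shape
        if m != len(self.segments) or s != len(self.isoform_ids):
            raise ValueError(f"gene {self.gene_id}: design shape mismatch")
        if m < 1:
            raise ValueError(f"gene {self.gene_id}: empty partition")
        if (self.design.sum(axis=1) < 1).any():
            raise ValueError(f"gene {self.gene_id}: segment with no isoform membership")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.segments], dtype=np.int64)

    def duplicate_design_columns(self) -> list[tuple[str, str]]:
        """Pairs of isoform ids whose design columns are identical (unidentifiable)."""
        pairs = []
        for a in range(self.design.shape[1]):
            for b in range(a + 1, self.design.shape[1]):
                if np.array_equal(self.design[:, a], self.design[:, b]):
                    pairs.append((self.isoform_ids[a], self.isoform_ids[b]))
        return pairs


@dataclass
class LengthClassTable:
    """Short/medium/long labels for pseudo-exon segments.

    Thresholds are the nearest-rank 5th and 95th percentiles of the segment
    length distribution over the whole dataset.  A segment that would qualify
    as both short and long (degenerate length distribution) is labelled medium.
    """

    labels: "pd.DataFrame"  # gene_id, segment_index, length, label
    short_threshold: float
    long_threshold: float
    isoform_fractions: "pd.DataFrame" = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Percentiles (nearest-rank, shared with normalization)
# ---------------------------------------------------------------------------


def nearest_rank_percentile(values, p: float) -> float:
    """Nearest-rank percentile: the value at rank ``ceil(p/100 * n)`` (1-based)."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("percentile of empty collection")
    rank = max(1, math.ceil(p / 100.0 * n))
    return float(arr[min(rank, n) - 1])


# ---------------------------------------------------------------------------
# Annotation reading
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_models(annotation_file: str, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a GFF3 or GTF annotation.

    ``format`` is ``"gff3"`` or ``"gtf"``; if omitted it is inferred from the
    file extension.  Exon features must carry transcript and gene identifiers
    (``Parent``/``ID`` chains for GFF3, ``gene_id``/``transcript_id``
    attributes for GTF).  Transcripts without exon records are dropped with a
    warning.
    """
    import gffutils

    if format is None:
        ext = os.path.splitext(annotation_file)[1].lower().lstrip(".")
        format = "gtf" if ext == "gtf" else "gff3"
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format {format!r}")

    with open(annotation_file) as fh:
        n_records = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise AnnotationFormatError(
                    f"{annotation_file}:{lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            n_records += 1
    if n_records == 0:
        raise AnnotationFormatError(f"{annotation_file}: no feature records")

    infer = format == "gtf"
    try:
        db = gffutils.create_db(
            annotation_file,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=not infer,
            disable_infer_transcripts=not infer,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationFormatError(
            f"cannot parse {annotation_file} as {format}: {exc}"
        ) from exc

    transcript_types = ("mRNA", "transcript")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        isoforms: list[tuple[str, list[tuple[int, int]]]] = []
        for tx in db.children(gene, featuretype=transcript_types, order_by="start"):
            exons = []
            for exon in db.children(tx, featuretype="exon", order_by="start"):
                if exon.end < exon.start:
                    raise AnnotationFormatError(
                        f"{annotation_file}: exon with end < start in transcript {tx.id}"
                    )
                exons.append((exon.start - 1, exon.end))  # to 0-based half-open
            if not exons:
                log.warning("transcript %s of gene %s has no exons; dropped", tx.id, gene.id)
                continue
            isoforms.append((tx.id, exons))
        if not isoforms:
            log.warning("gene %s has no transcripts with exons; dropped", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in ("+", "-") else "unknown",
                isoforms=isoforms,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Pseudo-exon partitioning
# ---------------------------------------------------------------------------


def build_pseudo_exons(gene: GeneModel) -> PseudoExonPartition:
    """Cut the union of a gene's exons at every isoform exon boundary.

    The atomic intervals between consecutive boundaries that fall inside the
    exon union become candidate segments; adjacent (genomically contiguous)
    candidates with identical isoform membership are merged, yielding the
    minimal partition.  Membership is by whole containment: a segment belongs
    to isoform ``k`` iff it lies wholly inside one of ``k``'s exons.
    """
    exon_sets = [exons for _, exons in gene.isoforms]
    bounds = sorted({b for exons in exon_sets for iv in exons for b in iv})
    atoms: list[tuple[list[int], tuple[bool, ...]]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        membership = tuple(
            any(s <= a and b <= e for s, e in exons) for exons in exon_sets
        )
        if not any(membership):
            continue  # intron / inter-exon gap
        if atoms and atoms[-1][1] == membership and atoms[-1][0][1] == a:
            atoms[-1][0][1] = b  # merge contiguous same-membership run
        else:
            atoms.append(([a, b], membership))
    segments = [(a, b) for (a, b), _ in atoms]
    design = np.array([mem for _, mem in atoms], dtype=np.int8)
    part = PseudoExonPartition(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        segments=segments,
        design=design,
        isoform_ids=gene.isoform_ids,
    )
    dups = part.duplicate_design_columns()
    if dups:
        log.warning(
            "gene %s: isoform pairs with identical design columns (unidentifiable): %s",
            gene.gene_id,
            dups,
        )
    return part


def classify_segment_lengths(partitions: list[PseudoExonPartition]) -> LengthClassTable:
    """Label segments short/medium/long by the 5th/95th length percentiles.

    ``short``: length <= 5th percentile; ``long``: length >= 95th percentile;
    segments qualifying as both (degenerate distributions) are ``medium``.
    Also reports, per isoform, the fraction of its member segments that are
    short and long.
    """
    import pandas as pd

    if not partitions:
        raise ValueError("classify_segment_lengths: empty partition list")
    rows = []
    for part in partitions:
        for idx, ((s, e), length) in enumerate(zip(part.segments, part.lengths)):
            rows.append((part.gene_id, idx, int(length)))
    table = pd.DataFrame(rows, columns=["gene_id", "segment_index", "length"])
    lo = nearest_rank_percentile(table["length"], 5)
    hi = nearest_rank_percentile(table["length"], 95)
    is_short = table["length"] <= lo
    is_long = table["length"] >= hi
    label = np.where(is_short & is_long, "medium", np.where(is_short, "short", np.where(is_long, "long", "medium")))
    table["label"] = label

    frac_rows = []
    lab_by_key = {(g, i): l for g, i, l in zip(table["gene_id"], table["segment_index"], table["label"])}
    for part in partitions:
        for k, iso_id in enumerate(part.isoform_ids):
            member = np.flatnonzero(part.design[:, k])
            labs = [lab_by_key[(part.gene_id, int(i))] for i in member]
            n = len(labs)
            frac_rows.append(
                (
                    part.gene_id,
                    iso_id,
                    n,
                    sum(l == "short" for l in labs) / n,
                    sum(l == "long" for l in labs) / n,
                )
            )
    fractions = pd.DataFrame(
        frac_rows, columns=["gene_id", "isoform_id", "n_segments", "frac_short", "frac_long"]
    )
    return LengthClassTable(
        labels=table,
        short_threshold=lo,
        long_threshold=hi,
        isoform_fractions=fractions,
    )
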
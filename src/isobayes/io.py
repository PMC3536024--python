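"""Tabular readers/writers and run configuration.

All outputs are TSV with ``#``-prefixed provenance headers (method, seed,
factors, upstream checksums) so every file can be re-derived; floats are
written with 6 significant digits; files are written atomically
(temp-and-rename) so failed runs leave no partial outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import PseudoExonPartition
from .hierarchical_model import GeneData, PosteriorSamples
from .normalization import CountMatrix, ExpressionMatrix

__all__ = [
    "RunConfig",
    "load_config",
    "read_counts_table",
    "write_counts_table",
    "read_expression_table",
    "write_expression_table",
    "write_partitions",
    "read_partitions",
    "write_table",
    "gene_data_from",
    "save_fits",
    "load_fits",
]

_FLOAT_FMT = "%.6g"

_CONFIG_SCHEMA = {
    "normalization": {"method", "reference", "lo_pct", "hi_pct"},
    "hyperparameters": {"alpha1", "alpha2", "alpha1_0", "alpha2_0", "mu0", "p"},
    "mcmc": {"chains", "iterations", "burn_in", "thin", "seed"},
    "calls": {"control", "conf", "level", "decile", "tail_prob", "use"},
    "seed": None,
    "log_level": None,
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected up front."""

    normalization: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    calls: dict = field(default_factory=dict)
    seed: int | None = None
    log_level: str = "INFO"


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = json.load(fh)
    for key, val in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"config: unknown key {key!r}")
        allowed = _CONFIG_SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise ValueError(f"config: {key!r} must be an object")
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(f"config: unknown keys in {key!r}: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Atomic writes with provenance headers
# ---------------------------------------------------------------------------


def file_fingerprint(path: str) -> dict:
    """Content-based provenance reference for an upstream file: basename plus
    sha256 (absolute paths would break run-to-run reproducibility checks)."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return {"file": os.path.basename(path), "sha256": h.hexdigest()}


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _format_frame(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Write a TSV with ``# key: value`` provenance header lines."""
    header = ""
    if meta:
        header = "".join(f"# {k}: {json.dumps(v, sort_keys=True, default=str)}\n" for k, v in meta.items())
    _atomic_write(path, header + _format_frame(df))


def _read_meta(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ": " in body:
                k, v = body.split(": ", 1)
                try:
                    meta[k] = json.loads(v)
                except json.JSONDecodeError:
                    meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# Count / expression matrices
# ---------------------------------------------------------------------------

_ID_COLS = ["gene_id", "segment_index", "length"]


def read_counts_table(path: str) -> CountMatrix:
    """Read a counts TSV (gene_id, segment_index, length, one column per
    sample) into a validated :class:`CountMatrix`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ID_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in _ID_COLS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    dup = df.duplicated(subset=["gene_id", "segment_index"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}: duplicate (gene_id, segment_index) at row {row}")
    neg = (df[sample_cols] < 0).any(axis=1)
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise ValueError(f"{path}: negative count at row {row}")
    idx = pd.MultiIndex.from_frame(df[["gene_id", "segment_index"]])
    counts = df[sample_cols].astype(np.int64)
    counts.index = idx
    lengths = pd.Series(df["length"].to_numpy(), index=idx, name="length")
    return CountMatrix(counts=counts, lengths=lengths)


def write_counts_table(counts: CountMatrix, path: str, meta: dict | None = None) -> None:
    df = counts.counts.reset_index()
    df.insert(2, "length", counts.lengths.to_numpy())
    write_table(df, path, meta)


def read_expression_table(path: str) -> ExpressionMatrix:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_cols = [c for c in df.columns if c not in _ID_COLS]
    idx = pd.MultiIndex.from_frame(df[["gene_id", "segment_index"]])
    values = df[sample_cols].astype(float)
    values.index = idx
    lengths = None
    if "length" in df.columns:
        lengths = pd.Series(df["length"].to_numpy(), index=idx, name="length")
    return ExpressionMatrix(values=values, lengths=lengths, provenance=meta.get("provenance", {}))


def write_expression_table(expr: ExpressionMatrix, path: str, meta: dict | None = None) -> None:
    df = expr.values.reset_index()
    if expr.lengths is not None:
        df.insert(2, "length", expr.lengths.to_numpy())
    all_meta = {"provenance": expr.provenance}
    if meta:
        all_meta.update(meta)
    write_table(df, path, all_meta)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


def write_partitions(partitions: list[PseudoExonPartition], path: str, meta: dict | None = None) -> None:
    """Partition TSV (1-based inclusive coordinates on output) plus a
    design-matrix sidecar in coordinate-triplet text at ``<path>.design.mtx``."""
    rows = []
    triplets = ["%%coordinate gene_id segment_index isoform_id value"]
    for part in partitions:
        for i, (s, e) in enumerate(part.segments):
            members = [
                iso for k, iso in enumerate(part.isoform_ids) if part.design[i, k]
            ]
            rows.append(
                {
                    "gene_id": part.gene_id,
                    "segment_index": i,
                    "chrom": part.chrom,
                    "start": s + 1,
                    "end": e,
                    "length": e - s,
                    "isoform_memberships": ",".join(members),
                }
            )
            for iso in members:
                triplets.append(f"{part.gene_id}\t{i}\t{iso}\t1")
    write_table(pd.DataFrame(rows), path, meta)
    _atomic_write(path + ".design.mtx", "\n".join(triplets) + "\n")


def read_partitions(path: str) -> list[PseudoExonPartition]:
    df = pd.read_csv(path, sep="\t", comment="#")
    parts = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("segment_index")
        memberships = [str(ms).split(",") for ms in grp["isoform_memberships"]]
        # column order is not stored in the TSV; use sorted ids for determinism
        iso_ids = sorted({iso for members in memberships for iso in members})
        design = np.zeros((len(grp), len(iso_ids)), dtype=np.int8)
        for i, members in enumerate(memberships):
            for iso in members:
                design[i, iso_ids.index(iso)] = 1
        parts.append(
            PseudoExonPartition(
                gene_id=str(gene_id),
                chrom=str(grp["chrom"].iloc[0]),
                segments=[(int(s) - 1, int(e)) for s, e in zip(grp["start"], grp["end"])],
                design=design,
                isoform_ids=iso_ids,
            )
        )
    return parts


# ---------------------------------------------------------------------------
# Gene data assembly and fit archives
# ---------------------------------------------------------------------------


def gene_data_from(
    partitions: list[PseudoExonPartition], expr: ExpressionMatrix
) -> list[GeneData]:
    """Join partitions with the expression matrix into per-gene model inputs."""
    out = []
    genes_in_expr = set(expr.values.index.get_level_values(0))
    for part in partitions:
        if part.gene_id not in genes_in_expr:
            raise ValueError(f"gene {part.gene_id}: present in partitions but not in expression matrix")
        block = expr.values.loc[part.gene_id].sort_index()
        if len(block) != part.n_segments:
            raise ValueError(
                f"gene {part.gene_id}: {len(block)} expression rows vs "
                f"{part.n_segments} partition segments"
            )
        out.append(
            GeneData(partition=part, y=block.to_numpy(dtype=float), sample_ids=list(block.columns))
        )
    return out


def save_fits(fits: dict[str, PosteriorSamples], directory: str) -> None:
    """Archive posterior draws, one compressed .npz per gene plus an index."""
    os.makedirs(directory, exist_ok=True)
    index = []
    for gene_id in sorted(fits):
        s = fits[gene_id]
        fname = f"{gene_id}.npz"
        np.savez_compressed(
            os.path.join(directory, fname),
            beta=s.beta,
            indicator=s.indicator,
            tau=s.tau,
            tau0=s.tau0,
            meta=np.frombuffer(
                json.dumps(
                    {
                        "gene_id": s.gene_id,
                        "isoform_ids": s.isoform_ids,
                        "sample_ids": s.sample_ids,
                        "n_segments": s.n_segments,
                        "burn_in": s.burn_in,
                        "thin": s.thin,
                        "seed": s.seed,
                        "warnings": s.warnings,
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        )
        index.append(fname)
    with open(os.path.join(directory, "index.json"), "w") as fh:
        json.dump({"genes": index}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_fits(directory: str) -> dict[str, PosteriorSamples]:
    with open(os.path.join(directory, "index.json")) as fh:
        index = json.load(fh)
    fits = {}
    for fname in index["genes"]:
        with np.load(os.path.join(directory, fname)) as npz:
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
            fits[meta["gene_id"]] = PosteriorSamples(
                gene_id=meta["gene_id"],
                isoform_ids=meta["isoform_ids"],
                sample_ids=meta["sample_ids"],
                n_segments=meta["n_segments"],
                beta=npz["beta"],
                indicator=npz["indicator"],
                tau=npz["tau"],
                tau0=npz["tau0"],
                burn_in=meta["burn_in"],
                thin=meta["thin"],
                seed=meta["seed"],
                warnings=meta["warnings"],
            )
    return fits
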
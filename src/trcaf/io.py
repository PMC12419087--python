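"""Readers and writers for the pipeline's plain-text formats.

Conventions: TSV for all tables (gene names with commas exist), Matrix Market
plus features/barcodes for count matrices (10x orientation: genes x cells on
disk, cells x genes in memory), GMT for gene sets, BED (0-based half-open)
for peaks.  Gzipped inputs are accepted wherever the plain format is.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .scrna import GeneSet

__all__ = [
    "MatrixFormatError",
    "DimensionMismatchError",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_expression",
    "write_expression",
    "write_bed",
    "read_bed",
    "write_tss",
    "read_tss",
]


class MatrixFormatError(ValueError):
    """Malformed Matrix Market content."""


class DimensionMismatchError(ValueError):
    """Features/barcodes line counts do not match the matrix dimensions."""


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_lines(path: Path) -> list[str]:
    with _open_text(Path(path)) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_cell_matrix(
    mtx_path,
    features_path,
    barcodes_path,
    meta_path=None,
) -> ad.AnnData:
    """Read a 10x-convention triple (matrix genes x cells) into AnnData.

    ``meta_path`` optionally points to a TSV of per-cell metadata indexed by
    barcode.  Plain and gzipped files are treated identically.
    """
    try:
        with _open_text(Path(mtx_path)) as fh:
            mat = scipy.io.mmread(fh)
    except ValueError as err:
        raise MatrixFormatError(f"malformed MTX header in {mtx_path}: {err}") from err
    features = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = _read_lines(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise DimensionMismatchError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(features)}, {len(barcodes)})"
        )
    adata = ad.AnnData(
        X=mat.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        missing = [b for b in barcodes if b not in meta.index]
        if missing:
            raise DimensionMismatchError(
                f"{len(missing)} barcodes missing from metadata"
            )
        meta = meta.loc[barcodes]
        for col in meta.columns:
            adata.obs[col] = meta[col].to_numpy()
    return adata


def write_cell_matrix(m: ad.AnnData, out_dir, meta_cols: Sequence[str] | None = None):
    """Write an AnnData as matrix.mtx + features.tsv + barcodes.tsv
    (+ cell_meta.tsv when metadata columns exist); lossless for counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(m.X)
    scipy.io.mmwrite(out / "matrix.mtx", X.T.tocoo())
    (out / "features.tsv").write_text("\n".join(m.var_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(m.obs_names) + "\n")
    cols = list(meta_cols) if meta_cols is not None else list(m.obs.columns)
    if cols:
        m.obs[cols].to_csv(out / "cell_meta.tsv", sep="\t")
    return out


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (name, description, genes...); duplicates within a set
    are dropped with a warning."""
    sets = []
    for ln, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValueError(f"{path}:{ln}: GMT line has no genes")
        name, genes = parts[0], [g for g in parts[2:] if g.strip()]
        if len(set(genes)) != len(genes):
            warnings.warn(f"duplicate genes in set {name!r}; keeping first")
        sets.append(GeneSet.from_iterable(name, genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "trcaf") -> None:
    """Empty sets cannot be represented in GMT and are skipped with a warning."""
    lines = []
    for s in sets:
        if len(s.genes) == 0:
            warnings.warn(f"skipping empty gene set {s.name!r} in GMT output")
            continue
        lines.append("\t".join([s.name, description, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV: sample_id, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return df


def write_clinical(samples, time, event, path) -> None:
    pd.DataFrame(
        {"sample_id": samples, "time": time, "event": event}
    ).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def write_bed(peaks: pd.DataFrame, path) -> None:
    """Peaks BED: chrom, start, end, peak_id (0-based half-open, bit-exact)."""
    peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id"],
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[["peak_id", "chrom", "start", "end"]]


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[["gene_id", "chrom", "tss_pos", "strand"]].to_csv(path, sep="\t", index=False)


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["tss_pos"] = df["tss_pos"].astype(int)
    return df
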
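"""Reading/writing 10x-style matrices, QC filtering and normalization.

Supports both the v2 (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``)
and v3 (``matrix.mtx.gz`` + ``features.tsv.gz`` + ``barcodes.tsv.gz``)
triplet dialects, plus a plain TSV matrix (first column barcodes, header
genes).  10x stores genes as rows; orientation is corrected against the
name-list lengths so the returned matrix is always cells x genes.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from scgem.datamodel import CountMatrix, ProportionMatrix

logger = logging.getLogger(__name__)

__all__ = ["QcParams", "read_10x", "write_10x", "read_counts_tsv",
           "qc_filter", "normalize_proportions", "FormatError"]


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass(frozen=True)
class QcParams:
    """Cell-level quality-control thresholds.

    A cell is *removed* when it has fewer than ``min_genes`` detected
    genes, more than ``max_genes`` detected genes, or a mitochondrial
    UMI fraction above ``max_mito_frac`` (all three conditions strict,
    so the kept interval is closed).  Mitochondrial genes are matched by
    a case-insensitive name prefix.
    """

    min_genes: int = 200
    max_genes: int = 2500
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")


def _find_one(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / (stem + suffix)
            if candidate.exists():
                return candidate
    raise FormatError(f"none of {stems} (.gz or plain) found in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    return [ln.split("\t")[column] if "\t" in ln else ln for ln in lines]


def _dedupe(names: list[str], kind: str) -> list[str]:
    """Disambiguate duplicates by appending .1, .2, ... (deterministic)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    if len(out) != len(names) or len(set(out)) != len(out):
        raise FormatError(f"could not disambiguate duplicate {kind} names")
    if any(seen.values()):
        logger.warning("deduplicated %d duplicate %s names",
                       sum(1 for v in seen.values() if v), kind)
    return out


def read_10x(path: str | Path) -> CountMatrix:
    """Read a 10x MatrixMarket triplet directory (or the .mtx file itself).

    The features file may use either v2 ``genes.tsv`` or v3
    ``features.tsv.gz`` naming; the gene *symbol* column (second column,
    falling back to the first) is used as the gene name.  Orientation is
    inferred from the barcode/feature list lengths; a genes x cells
    matrix is transposed so rows are cells.
    """
    path = Path(path)
    if path.is_file():
        directory, mtx_path = path.parent, path
    else:
        directory = path
        mtx_path = _find_one(directory, ["matrix.mtx"])
    features_path = _find_one(directory, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_one(directory, ["barcodes.tsv"])

    # gene symbol is the 2nd column in both 10x dialects when present
    first_row = _read_tsv_column(features_path, 0)
    try:
        genes = _read_tsv_column(features_path, 1)
    except IndexError:
        genes = first_row
    if len(genes) != len(first_row) or any(g == "" for g in genes):
        genes = first_row
    barcodes = _read_tsv_column(barcodes_path, 0)

    mat = scipy.io.mmread(str(mtx_path))
    mat = sp.csr_matrix(mat)
    n_rows, n_cols = mat.shape
    if (n_rows, n_cols) == (len(genes), len(barcodes)):
        mat = mat.T.tocsr()  # 10x convention: genes x cells
    elif (n_rows, n_cols) == (len(barcodes), len(genes)):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(genes)} genes x {len(barcodes)} barcodes nor its transpose")
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("matrix contains non-integer values")
    mat.data = np.round(mat.data)
    return CountMatrix(counts=mat,
                       gene_names=_dedupe(genes, "gene"),
                       barcodes=_dedupe(barcodes, "barcode"))


def write_10x(cm: CountMatrix, directory: str | Path) -> None:
    """Write a plain (uncompressed) v2-style triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # stored genes x cells, the 10x convention
    scipy.io.mmwrite(str(directory / "matrix.mtx"),
                     sp.coo_matrix(cm.counts.T), field="integer")
    with open(directory / "genes.tsv", "w") as fh:
        for g in cm.gene_names:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(cm.barcodes) + "\n")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a dense TSV count matrix: first column barcodes, header genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=sp.csr_matrix(df.to_numpy()),
                       gene_names=_dedupe([str(c) for c in df.columns], "gene"),
                       barcodes=_dedupe([str(i) for i in df.index], "barcode"))


def qc_filter(cm: CountMatrix, params: QcParams = QcParams()) -> CountMatrix:
    """Drop cells failing the detected-gene and mitochondrial-fraction rules.

    Keeps exactly the cells with detected-gene count in
    ``[min_genes, max_genes]`` and mitochondrial UMI fraction at most
    ``max_mito_frac``.  Idempotent; may return zero cells.
    """
    detected = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(cm.counts.sum(axis=1)).ravel().astype(float)
    prefix = params.mito_prefix.upper()
    mito_mask = np.array([g.upper().startswith(prefix) for g in cm.gene_names])
    if mito_mask.any():
        mito_counts = np.asarray(cm.counts[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = ((detected >= params.min_genes)
            & (detected <= params.max_genes)
            & (mito_frac <= params.max_mito_frac))
    return cm.subset_cells(np.flatnonzero(keep))


def normalize_proportions(cm: CountMatrix) -> ProportionMatrix:
    """Normalize each cell's UMI counts to relative gene proportions.

    All-zero cells stay all-zero and are flagged in ``zero_cells``.
    """
    counts = np.asarray(cm.counts.todense(), dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    props = np.divide(counts, np.where(zero, 1.0, totals)[:, None])
    return ProportionMatrix(props=props, gene_names=cm.gene_names,
                            barcodes=cm.barcodes, zero_cells=zero)
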
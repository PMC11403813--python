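"""Readers and writers for count matrices (dense TSV/CSV and MatrixMarket
triplets), annotation CSVs, and run artifacts."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import AlignmentError, FormatError, ValidationError
from .preprocess import CellAnnotation, CountMatrix

__all__ = [
    "read_dense_matrix",
    "write_dense_matrix",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_annotation",
    "write_annotation",
    "read_expression_input",
    "write_json",
    "read_json",
]

log = logging.getLogger("ccnet")

FOREIGN_EXTENSIONS = {".rds", ".h5seurat"}


def read_dense_matrix(path: str | Path) -> CountMatrix:
    """Dense genes x cells table; TSV unless the extension is .csv."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    genes = [str(g) for g in df.index]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: duplicate gene names")
    return CountMatrix(df.to_numpy(dtype=np.float64), genes, [str(c) for c in df.columns])


def write_dense_matrix(X: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(X.values, index=X.gene_names, columns=X.cell_barcodes)
    df.to_csv(path, sep=sep)


def read_mtx_dir(directory: str | Path) -> CountMatrix:
    """MatrixMarket triplet: matrix.mtx + genes.tsv + barcodes.tsv."""
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    genes_p = directory / "genes.tsv"
    barcodes_p = directory / "barcodes.tsv"
    for p in (mtx, genes_p, barcodes_p):
        if not p.exists():
            raise FormatError(f"missing {p.name} in {directory}")
    M = spio.mmread(mtx)
    genes = genes_p.read_text(encoding="utf-8").split()
    barcodes = barcodes_p.read_text(encoding="utf-8").split()
    values = np.asarray(M.todense() if sparse.issparse(M) else M, dtype=np.float64)
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{genes_p}: duplicate gene names")
    return CountMatrix(values, genes, barcodes)


def write_mtx_dir(X: CountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(X.values))
    (directory / "genes.tsv").write_text("\n".join(X.gene_names) + "\n", encoding="utf-8")
    (directory / "barcodes.tsv").write_text(
        "\n".join(X.cell_barcodes) + "\n", encoding="utf-8"
    )


def read_annotation(path: str | Path) -> CellAnnotation:
    """CSV with header ``barcode,cell_type``."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("barcode", "cell_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return CellAnnotation.from_pairs(
        [(str(b), str(t)) for b, t in zip(df["barcode"], df["cell_type"])]
    )


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("barcode,cell_type\n")
        for bc, ct in ann.mapping.items():
            fh.write(f"{bc},{ct}\n")


def read_expression_input(
    matrix_path: str | Path, annotation_path: str | Path
) -> tuple[CountMatrix, CellAnnotation, int]:
    """Load a matrix (dense table or MTX directory) aligned to its annotation.

    Cells absent from the annotation are dropped (count returned); zero
    barcode overlap is an alignment error.  Foreign serializations (.rds,
    .h5seurat) are rejected with conversion guidance.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix.lower() in FOREIGN_EXTENSIONS:
        raise FormatError(
            f"{matrix_path.suffix} is an unsupported foreign serialization; "
            "export your object to a dense TSV/CSV or an MTX triplet "
            "(matrix.mtx + genes.tsv + barcodes.tsv) and retry"
        )
    if matrix_path.is_dir():
        X = read_mtx_dir(matrix_path)
    else:
        X = read_dense_matrix(matrix_path)
    ann = read_annotation(annotation_path)
    keep = [b in ann.mapping for b in X.cell_barcodes]
    n_dropped = int(len(keep) - sum(keep))
    if sum(keep) == 0:
        raise AlignmentError(
            "no overlap between matrix barcodes and annotation barcodes"
        )
    if n_dropped:
        log.info("dropping %d cell(s) without annotation", n_dropped)
        X = X.subset(cell_mask=np.asarray(keep))
    ann = ann.subset(X.cell_barcodes)
    return X, ann, n_dropped


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
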
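"""Count-matrix preprocessing: library-size normalization, log transform,
gene/cell filtering, and per-cell-type summaries.

The processing order follows normalize -> ln(1+x) -> filter; size factors
are anchored to the mean library size so total counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AnnotationError, PreprocessingError, StageError, ValidationError

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CellAnnotation",
    "TypeSummary",
    "FilterResult",
    "normalize_library_size",
    "log_transform",
    "filter_genes_cells",
    "summarize_by_type",
]


def _check_labels(values: np.ndarray, gene_names, cell_barcodes) -> None:
    if values.ndim != 2:
        raise ValidationError("matrix must be 2-D (genes x cells)")
    if values.shape != (len(gene_names), len(cell_barcodes)):
        raise ValidationError(
            f"shape {values.shape} does not match {len(gene_names)} genes "
            f"x {len(cell_barcodes)} cells"
        )
    if len(set(gene_names)) != len(gene_names):
        raise ValidationError("gene names must be unique")
    if len(set(cell_barcodes)) != len(cell_barcodes):
        raise ValidationError("cell barcodes must be unique")


@dataclass
class CountMatrix:
    """Raw genes x cells counts with axis labels."""

    values: np.ndarray
    gene_names: list[str]
    cell_barcodes: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        self.cell_barcodes = list(self.cell_barcodes)
        _check_labels(self.values, self.gene_names, self.cell_barcodes)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("counts must be finite")
        if np.any(self.values < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.values[np.ix_(gm, cm)],
            [g for g, k in zip(self.gene_names, gm) if k],
            [b for b, k in zip(self.cell_barcodes, cm) if k],
        )


@dataclass
class NormalizedMatrix:
    """Normalized (or log-transformed) genes x cells matrix."""

    values: np.ndarray
    gene_names: list[str]
    cell_barcodes: list[str]
    stage: str = "normalized"

    def __post_init__(self):
        if self.stage not in ("normalized", "log"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_labels(self.values, self.gene_names, self.cell_barcodes)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if self.stage == "log" and np.any(self.values < 0):
            raise ValidationError("log-stage values must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "NormalizedMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return NormalizedMatrix(
            self.values[np.ix_(gm, cm)],
            [g for g, k in zip(self.gene_names, gm) if k],
            [b for b, k in zip(self.cell_barcodes, cm) if k],
            stage=self.stage,
        )


@dataclass
class CellAnnotation:
    """Barcode -> cell-type labels; type order is first appearance."""

    mapping: dict[str, str]
    cell_types: list[str] = field(init=False)

    def __post_init__(self):
        seen: dict[str, None] = {}
        for t in self.mapping.values():
            seen.setdefault(t, None)
        self.cell_types = list(seen)
        if not self.cell_types:
            raise ValidationError("annotation has no cells")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "CellAnnotation":
        mapping: dict[str, str] = {}
        for bc, ct in pairs:
            if bc in mapping:
                raise ValidationError(f"duplicate barcode in annotation: {bc}")
            mapping[bc] = ct
        return cls(mapping)

    def labels_for(self, barcodes: Sequence[str]) -> list[str]:
        missing = [b for b in barcodes if b not in self.mapping]
        if missing:
            raise AnnotationError(
                f"{len(missing)} barcode(s) missing from annotation: "
                + ", ".join(missing[:10])
            )
        return [self.mapping[b] for b in barcodes]

    def subset(self, barcodes: Sequence[str]) -> "CellAnnotation":
        return CellAnnotation({b: self.mapping[b] for b in barcodes})


@dataclass
class TypeSummary:
    """Per-cell-type mean log expression and non-zero expression fraction."""

    cell_types: list[str]
    gene_names: list[str]
    mean_expr: np.ndarray      # (types, genes)
    expr_fraction: np.ndarray  # (types, genes)
    cells_per_type: np.ndarray  # (types,)

    def __post_init__(self):
        if np.any(self.expr_fraction < 0) or np.any(self.expr_fraction > 1):
            raise ValidationError("expr_fraction must lie in [0, 1]")

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def type_index(self, cell_type: str) -> int:
        try:
            return self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(cell_type) from None


@dataclass
class FilterResult:
    matrix: CountMatrix
    n_genes_dropped: int
    n_cells_dropped: int
    gene_mask: np.ndarray
    cell_mask: np.ndarray


def normalize_library_size(X: CountMatrix) -> NormalizedMatrix:
    """Divide each cell by its size factor lb_j / mean(lb).

    Conserves total counts; preserves within-cell proportions.
    """
    lb = X.values.sum(axis=0)
    zero = lb == 0
    if np.any(zero):
        bad = [b for b, z in zip(X.cell_barcodes, zero) if z]
        raise PreprocessingError(
            "cells with zero library size: " + ", ".join(bad[:10])
        )
    sf = lb / lb.mean()
    return NormalizedMatrix(
        X.values / sf[np.newaxis, :], X.gene_names, X.cell_barcodes, stage="normalized"
    )


def log_transform(Xn: NormalizedMatrix) -> NormalizedMatrix:
    """Elementwise ln(1 + x); only valid once, on a normalized-stage matrix."""
    if Xn.stage != "normalized":
        raise StageError(f"log_transform expects stage 'normalized', got {Xn.stage!r}")
    return NormalizedMatrix(
        np.log1p(Xn.values), Xn.gene_names, Xn.cell_barcodes, stage="log"
    )


def filter_genes_cells(
    X: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
) -> FilterResult:
    """Single pass: drop sparse genes, then sparse cells.

    A gene is kept if it has non-zero counts in >= min_cells_per_gene cells;
    a cell (evaluated on the gene-filtered matrix) if it expresses
    >= min_genes_per_cell genes.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be >= 0")
    nz = X.values > 0
    gene_mask = nz.sum(axis=1) >= min_cells_per_gene
    cell_mask = nz[gene_mask, :].sum(axis=0) >= min_genes_per_cell
    if not gene_mask.any() or not cell_mask.any():
        raise PreprocessingError(
            "filtering removed every gene or cell; relax min_cells_per_gene / "
            "min_genes_per_cell"
        )
    return FilterResult(
        matrix=X.subset(gene_mask, cell_mask),
        n_genes_dropped=int((~gene_mask).sum()),
        n_cells_dropped=int((~cell_mask).sum()),
        gene_mask=gene_mask,
        cell_mask=cell_mask,
    )


def summarize_by_type(Xlog: NormalizedMatrix, ann: CellAnnotation) -> TypeSummary:
    """Per-type mean of log values and fraction of expressing cells.

    ``expr_fraction`` counts cells with value > 0, which is equivalent on
    raw and log1p scales.
    """
    if Xlog.stage != "log":
        raise StageError("summarize_by_type expects a log-stage matrix")
    labels = ann.labels_for(Xlog.cell_barcodes)
    types = [t for t in ann.cell_types if t in set(labels)]
    codes = np.array([types.index(t) for t in labels])
    T, G = len(types), Xlog.n_genes
    counts = np.bincount(codes, minlength=T).astype(np.float64)
    onehot = np.zeros((T, Xlog.n_cells))
    onehot[codes, np.arange(Xlog.n_cells)] = 1.0
    mean_expr = (onehot @ Xlog.values.T) / counts[:, None]
    expr_fraction = (onehot @ (Xlog.values > 0).T.astype(np.float64)) / counts[:, None]
    return TypeSummary(
        cell_types=types,
        gene_names=list(Xlog.gene_names),
        mean_expr=mean_expr,
        expr_fraction=expr_fraction,
        cells_per_type=counts.astype(np.int64),
    )
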
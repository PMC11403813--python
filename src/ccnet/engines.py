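"""Three ligand-receptor scoring engines with a shared permutation-null
framework.

Each engine maps a per-type expression summary and an L-R database to a
(sender, receiver, pair) score array:

* ``cellchat_like``    — product of ligand and receptor expression, complex
  subunits combined by geometric mean;
* ``cellphonedb_like`` — arithmetic mean of ligand and receptor expression,
  complex subunits combined by minimum;
* ``celltalker_like``  — same product score, but an entry is only tested
  when every subunit is expressed in at least ``min_fraction`` of the
  sender/receiver cells.

P-values come from shuffling cell-type labels over cells (group sizes
preserved) and recomputing the score; the same shuffles are reused for all
engines run under one seed so their p-values are commensurable.  The
add-one rule p = (1 + #{perm >= obs}) / (1 + n_perm) keeps p strictly
positive, as required by downstream log-based combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, GeneLookupError
from .lrdb import GeneComplex, LRDatabase
from .preprocess import CellAnnotation, NormalizedMatrix, TypeSummary, summarize_by_type

__all__ = [
    "METHOD_TAGS",
    "MethodResult",
    "complex_expression",
    "score_cellchat_like",
    "score_cellphonedb_like",
    "score_celltalker_like",
    "permutation_pvalues",
    "run_engine",
    "run_all_engines",
]

METHOD_TAGS = ("cellchat_like", "cellphonedb_like", "celltalker_like")


@dataclass
class MethodResult:
    """One engine's scores, permutation p-values, and tested mask."""

    method: str
    scores: np.ndarray   # (types, types, pairs)
    pvalues: np.ndarray  # (types, types, pairs); NaN where untested
    tested: np.ndarray   # bool, same shape
    n_perm: int
    seed: int
    cell_types: list[str]
    pair_ids: list[str]

    def __post_init__(self):
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")
        shape = (len(self.cell_types), len(self.cell_types), len(self.pair_ids))
        for arr in (self.scores, self.pvalues, self.tested):
            if arr.shape != shape:
                raise AlignmentError(f"array shape {arr.shape} != {shape}")


def _subunit_indices(db: LRDatabase, summary: TypeSummary):
    """Per pair: (ligand subunit column indices, receptor subunit indices)."""
    gene_pos = {g: i for i, g in enumerate(summary.gene_names)}
    lig, rec = [], []
    for pair in db:
        try:
            lig.append(np.array([gene_pos[g] for g in pair.ligand.subunits]))
            rec.append(np.array([gene_pos[g] for g in pair.receptor.subunits]))
        except KeyError as e:
            raise GeneLookupError(
                f"pair {pair.pair_id}: gene {e.args[0]} not in summary"
            ) from None
    return lig, rec


def _complex_values(mean_expr: np.ndarray, idx_list, mode: str) -> np.ndarray:
    """(types, pairs) matrix of complex-level expression."""
    T = mean_expr.shape[0]
    out = np.empty((T, len(idx_list)))
    for p, idx in enumerate(idx_list):
        sub = mean_expr[:, idx]
        if mode == "geometric":
            out[:, p] = np.prod(sub, axis=1) ** (1.0 / len(idx))
        elif mode == "minimum":
            out[:, p] = sub.min(axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def complex_expression(
    summary: TypeSummary, cx: GeneComplex, cell_type: str, mode: str
) -> float:
    """Complex-level mean expression of ``cx`` in ``cell_type``.

    ``geometric`` takes the geometric mean over subunits, ``minimum`` the
    minimum; both reduce to the subunit's own mean for single genes.
    """
    try:
        t = summary.type_index(cell_type)
    except KeyError:
        raise GeneLookupError(f"cell type {cell_type!r} not in summary") from None
    vals = []
    for g in cx.subunits:
        try:
            vals.append(summary.mean_expr[t, summary.gene_index(g)])
        except KeyError:
            raise GeneLookupError(
                f"gene {g!r} not in summary (cell type {cell_type!r})"
            ) from None
    vals = np.asarray(vals)
    if mode == "geometric":
        return float(np.prod(vals) ** (1.0 / len(vals)))
    if mode == "minimum":
        return float(vals.min())
    raise ValueError(f"unknown mode {mode!r}")


def _scores_product_geometric(mean_expr, lig_idx, rec_idx):
    lig = _complex_values(mean_expr, lig_idx, "geometric")
    rec = _complex_values(mean_expr, rec_idx, "geometric")
    return lig[:, None, :] * rec[None, :, :]


def _scores_mean_minimum(mean_expr, lig_idx, rec_idx):
    lig = _complex_values(mean_expr, lig_idx, "minimum")
    rec = _complex_values(mean_expr, rec_idx, "minimum")
    return 0.5 * (lig[:, None, :] + rec[None, :, :])


def score_cellchat_like(summary: TypeSummary, db: LRDatabase) -> np.ndarray:
    """score[s, r, p] = geomean(ligand subunits in s) * geomean(receptor in r)."""
    lig_idx, rec_idx = _subunit_indices(db, summary)
    return _scores_product_geometric(summary.mean_expr, lig_idx, rec_idx)


def score_cellphonedb_like(summary: TypeSummary, db: LRDatabase) -> np.ndarray:
    """score[s, r, p] = 1/2 (min ligand subunit in s + min receptor subunit in r)."""
    lig_idx, rec_idx = _subunit_indices(db, summary)
    return _scores_mean_minimum(summary.mean_expr, lig_idx, rec_idx)


def score_celltalker_like(
    summary: TypeSummary, db: LRDatabase, min_fraction: float = 0.1
):
    """Product score plus a tested mask from expression-fraction thresholds."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    lig_idx, rec_idx = _subunit_indices(db, summary)
    scores = _scores_product_geometric(summary.mean_expr, lig_idx, rec_idx)
    T = summary.mean_expr.shape[0]
    lig_ok = np.empty((T, len(lig_idx)), bool)
    rec_ok = np.empty((T, len(rec_idx)), bool)
    for p, idx in enumerate(lig_idx):
        lig_ok[:, p] = (summary.expr_fraction[:, idx] >= min_fraction).all(axis=1)
    for p, idx in enumerate(rec_idx):
        rec_ok[:, p] = (summary.expr_fraction[:, idx] >= min_fraction).all(axis=1)
    tested = lig_ok[:, None, :] & rec_ok[None, :, :]
    return scores, tested


def _onehot_weights(labels: list[str], cell_types: list[str]) -> np.ndarray:
    codes = np.array([cell_types.index(t) for t in labels])
    T, C = len(cell_types), len(labels)
    counts = np.bincount(codes, minlength=T).astype(np.float64)
    W = np.zeros((T, C))
    W[codes, np.arange(C)] = 1.0
    return W / counts[:, None]


def _observed(summary, db, method, min_fraction):
    lig_idx, rec_idx = _subunit_indices(db, summary)
    if method == "cellchat_like":
        scores = _scores_product_geometric(summary.mean_expr, lig_idx, rec_idx)
        tested = np.ones_like(scores, dtype=bool)
    elif method == "cellphonedb_like":
        scores = _scores_mean_minimum(summary.mean_expr, lig_idx, rec_idx)
        tested = np.ones_like(scores, dtype=bool)
    elif method == "celltalker_like":
        scores, tested = score_celltalker_like(summary, db, min_fraction)
    else:
        raise ValueError(f"unknown method tag {method!r}")
    return scores, tested, lig_idx, rec_idx


def run_all_engines(
    Xlog: NormalizedMatrix,
    ann: CellAnnotation,
    db: LRDatabase,
    n_perm: int = 100,
    seed: int = 0,
    min_fraction: float = 0.1,
    methods: tuple[str, ...] = METHOD_TAGS,
) -> list[MethodResult]:
    """Run the requested engines over one shared permutation stream.

    The label shuffles are drawn once from ``seed`` and reused for every
    engine, so a single engine run and a joint run see identical nulls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for m in methods:
        if m not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {m!r}")
    summary = summarize_by_type(Xlog, ann)
    obs = {m: _observed(summary, db, m, min_fraction) for m in methods}
    lig_idx, rec_idx = _subunit_indices(db, summary)

    W = _onehot_weights(ann.labels_for(Xlog.cell_barcodes), summary.cell_types)
    X = Xlog.values  # (genes, cells)
    rng = np.random.default_rng(seed)
    ge = {m: np.zeros_like(obs[m][0]) for m in methods}
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        mean_perm = W[:, perm] @ X.T
        for m in methods:
            if m in ("cellchat_like", "celltalker_like"):
                sp = _scores_product_geometric(mean_perm, lig_idx, rec_idx)
            else:
                sp = _scores_mean_minimum(mean_perm, lig_idx, rec_idx)
            ge[m] += sp >= obs[m][0]

    out = []
    for m in methods:
        scores, tested = obs[m][0], obs[m][1]
        pvals = (1.0 + ge[m]) / (1.0 + n_perm)
        pvals = np.where(tested, pvals, np.nan)
        out.append(
            MethodResult(
                method=m,
                scores=scores,
                pvalues=pvals,
                tested=tested,
                n_perm=n_perm,
                seed=seed,
                cell_types=list(summary.cell_types),
                pair_ids=db.pair_ids,
            )
        )
    return out


def run_engine(
    method: str,
    Xlog: NormalizedMatrix,
    ann: CellAnnotation,
    db: LRDatabase,
    n_perm: int = 100,
    seed: int = 0,
    min_fraction: float = 0.1,
) -> MethodResult:
    """Single-engine facade over :func:`run_all_engines`."""
    return run_all_engines(
        Xlog, ann, db, n_perm=n_perm, seed=seed, min_fraction=min_fraction,
        methods=(method,),
    )[0]


def permutation_pvalues(
    Xlog: NormalizedMatrix,
    ann: CellAnnotation,
    db: LRDatabase,
    method: str,
    n_perm: int,
    seed: int,
    min_fraction: float = 0.1,
) -> np.ndarray:
    """P-value array for one engine (NaN at untested entries)."""
    return run_engine(
        method, Xlog, ann, db, n_perm=n_perm, seed=seed, min_fraction=min_fraction
    ).pvalues
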
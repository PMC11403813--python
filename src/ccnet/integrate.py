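"""Fuse per-engine results: Fisher's combined probability over the engines
that tested each entry, a per-pair-normalized combined score, significance
filtering, and the flat result table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError
from .engines import MethodResult

__all__ = [
    "IntegratedResult",
    "fisher_combine",
    "combine_pvalue_matrix",
    "combine_score_matrix",
    "integrate",
    "significance_filter",
    "build_result_table",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "method",
    "task_id",
    "ligand",
    "receptor",
    "lr_pair",
    "communication_score",
    "p_value",
    "sender",
    "receiver",
]


@dataclass
class IntegratedResult:
    cell_types: list[str]
    pair_ids: list[str]
    combined_p: np.ndarray      # (T, T, P); NaN where never tested
    combined_score: np.ndarray  # (T, T, P) in [0, 1]
    shared_num: np.ndarray      # int, number of engines testing each entry
    significant: np.ndarray     # bool
    alpha: float
    weights: tuple[float, ...]
    adjusted_p: np.ndarray | None = field(default=None)

    @property
    def shape(self):
        return self.combined_p.shape


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: chi2_{2k} upper tail of -2 sum(ln p_i).

    For k = 1 this is the identity (returns the input p).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, df=2 * p.size))


def _check_axes(results: Sequence[MethodResult]) -> None:
    if not results:
        raise ValueError("need at least one MethodResult")
    ref = results[0]
    for r in results[1:]:
        if r.cell_types != ref.cell_types or r.pair_ids != ref.pair_ids:
            raise AlignmentError("MethodResults have mismatched axes")


def combine_pvalue_matrix(results: Sequence[MethodResult]):
    """Per entry, Fisher-combine the p-values of the engines that tested it.

    Returns (combined_p, shared_num); entries tested by no engine carry
    NaN and shared_num 0.
    """
    _check_axes(results)
    P = np.stack([r.pvalues for r in results])  # (K, T, T, pairs)
    tested = np.stack([r.tested for r in results])
    shared_num = tested.sum(axis=0).astype(np.int64)
    logs = np.where(tested, np.log(np.where(tested, P, 1.0)), 0.0)
    stat = -2.0 * logs.sum(axis=0)
    combined = np.full(stat.shape, np.nan)
    for k in range(1, len(results) + 1):
        mask = shared_num == k
        if mask.any():
            combined[mask] = stats.chi2.sf(stat[mask], df=2 * k)
    return combined, shared_num


def combine_score_matrix(
    results: Sequence[MethodResult],
    weights: Sequence[float] | None = None,
    global_normalize: bool = False,
) -> np.ndarray:
    """Weighted sum of per-engine scores, normalized to sum to 1 per pair.

    Engine scores live on different scales, so each is first rescaled by
    its own maximum over tested entries.  The weighted sum (over testing
    engines only) is then divided, per L-R pair, by its total over all
    (sender, receiver) entries — or by the global total with
    ``global_normalize``.  Pairs whose total is zero come back all-zero
    with a warning.
    """
    _check_axes(results)
    if weights is None:
        weights = [1.0] * len(results)
    w = np.asarray(list(weights), dtype=np.float64)
    if w.size != len(results):
        raise ValueError("one weight per engine required")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be >= 0 and not all zero")

    num = np.zeros_like(results[0].scores, dtype=np.float64)
    for wi, r in zip(w, results):
        mx = r.scores[r.tested].max() if r.tested.any() else 0.0
        if mx > 0:
            num += wi * np.where(r.tested, r.scores / mx, 0.0)
    if global_normalize:
        total = num.sum()
        if total == 0:
            warnings.warn("all combined scores are zero")
            return num
        return num / total
    out = np.zeros_like(num)
    totals = num.sum(axis=(0, 1))  # per pair
    zero_pairs = totals == 0
    if zero_pairs.any():
        warnings.warn(
            f"{int(zero_pairs.sum())} pair(s) have all-zero scores; left at 0"
        )
    nz = ~zero_pairs
    out[:, :, nz] = num[:, :, nz] / totals[nz]
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def integrate(
    results: Sequence[MethodResult],
    weights: Sequence[float] | None = None,
    alpha: float = 0.05,
    global_normalize: bool = False,
    bh_correct: bool = False,
) -> IntegratedResult:
    """Full integration: combined p, combined score, significance mask."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    combined_p, shared_num = combine_pvalue_matrix(results)
    combined_score = combine_score_matrix(results, weights, global_normalize)
    tested = shared_num >= 1
    adjusted = None
    crit = combined_p
    if bh_correct:
        adjusted = np.full(combined_p.shape, np.nan)
        if tested.any():
            adjusted[tested] = _bh_adjust(combined_p[tested])
        crit = adjusted
    with np.errstate(invalid="ignore"):
        significant = tested & (crit < alpha)
    if weights is None:
        weights = [1.0] * len(results)
    return IntegratedResult(
        cell_types=list(results[0].cell_types),
        pair_ids=list(results[0].pair_ids),
        combined_p=combined_p,
        combined_score=combined_score,
        shared_num=shared_num,
        significant=significant,
        alpha=alpha,
        weights=tuple(float(x) for x in weights),
        adjusted_p=adjusted,
    )


def significance_filter(integrated: IntegratedResult, alpha: float | None = None):
    """Significant mask plus deterministically ranked entry indices.

    Ranking: combined_p ascending, combined_score descending, then
    pair_id / sender / receiver lexicographic.
    """
    alpha = integrated.alpha if alpha is None else alpha
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        mask = (integrated.shared_num >= 1) & (integrated.combined_p < alpha)
    entries = list(zip(*np.nonzero(mask)))
    entries.sort(
        key=lambda e: (
            integrated.combined_p[e],
            -integrated.combined_score[e],
            integrated.pair_ids[e[2]],
            integrated.cell_types[e[0]],
            integrated.cell_types[e[1]],
        )
    )
    return mask, entries


def build_result_table(
    integrated: IntegratedResult,
    results: Sequence[MethodResult],
    task_id: str = "run",
    top_n: int | None = None,
) -> pd.DataFrame:
    """Flat table: one row per (significant entry x testing method) plus a
    ``combined`` row per entry; entries ranked as in significance_filter.
    """
    _, entries = significance_filter(integrated)
    if top_n is not None:
        entries = entries[:top_n]
    pair_name = {}
    if results:
        for p_idx, pair_id in enumerate(integrated.pair_ids):
            lig, _, rec = pair_id.partition("_")
            pair_name[p_idx] = (lig, rec)
    rows = []
    for s, r, p in entries:
        lig, rec = pair_name.get(p, ("", ""))
        sender = integrated.cell_types[s]
        receiver = integrated.cell_types[r]
        pair_id = integrated.pair_ids[p]
        for res in results:
            if res.tested[s, r, p]:
                rows.append(
                    (res.method, task_id, lig, rec, pair_id,
                     float(res.scores[s, r, p]), float(res.pvalues[s, r, p]),
                     sender, receiver)
                )
        rows.append(
            ("combined", task_id, lig, rec, pair_id,
             float(integrated.combined_score[s, r, p]),
             float(integrated.combined_p[s, r, p]),
             sender, receiver)
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
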
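"""Cell-type communication graph and its topology analytics: PageRank,
largest clique, modularity clustering, and cross-method agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import AlignmentError, ConvergenceError
from .engines import MethodResult
from .integrate import IntegratedResult

__all__ = [
    "CellTypeNetwork",
    "AgreementReport",
    "build_network",
    "pagerank_scores",
    "largest_clique",
    "cluster_network",
    "network_pcc",
    "compare_methods",
]


@dataclass
class CellTypeNetwork:
    """Directed weighted graph over cell types.

    ``weight_count[s, r]`` counts significant L-R pairs sent from type s to
    type r; ``weight_score[s, r]`` sums their communication scores.
    """

    cell_types: list[str]
    weight_count: np.ndarray  # (T, T) int
    weight_score: np.ndarray  # (T, T) float
    cells_per_type: dict[str, int] = field(default_factory=dict)
    mode: str = "combined"

    def __post_init__(self):
        T = len(self.cell_types)
        if self.weight_count.shape != (T, T) or self.weight_score.shape != (T, T):
            raise AlignmentError("weight matrices must be (T, T)")
        if np.any(self.weight_count < 0) or np.any(self.weight_score < 0):
            raise ValueError("edge weights must be >= 0")

    @property
    def n_nodes(self) -> int:
        return len(self.cell_types)

    def edges(self):
        """Yield (sender, receiver, count, score) for non-empty edges."""
        for s, sender in enumerate(self.cell_types):
            for r, receiver in enumerate(self.cell_types):
                if self.weight_count[s, r] > 0 or self.weight_score[s, r] > 0:
                    yield sender, receiver, int(self.weight_count[s, r]), float(
                        self.weight_score[s, r]
                    )


def build_network(
    result: IntegratedResult | MethodResult,
    alpha: float | None = None,
    cells_per_type: Mapping[str, int] | None = None,
) -> CellTypeNetwork:
    """Aggregate significant (sender, receiver, pair) entries into a graph.

    An integrated result uses its own significance mask and combined
    scores; a single-engine result uses tested & p < alpha with its raw
    scores.
    """
    if isinstance(result, IntegratedResult):
        alpha = result.alpha if alpha is None else alpha
        with np.errstate(invalid="ignore"):
            sig = (result.shared_num >= 1) & (result.combined_p < alpha)
        scores = result.combined_score
        mode = "combined"
    else:
        if alpha is None:
            alpha = 0.05
        with np.errstate(invalid="ignore"):
            sig = result.tested & (result.pvalues < alpha)
        scores = result.scores
        mode = result.method
    return CellTypeNetwork(
        cell_types=list(result.cell_types),
        weight_count=sig.sum(axis=2).astype(np.int64),
        weight_score=np.where(sig, scores, 0.0).sum(axis=2),
        cells_per_type=dict(cells_per_type or {}),
        mode=mode,
    )


def pagerank_scores(
    net: CellTypeNetwork,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 500,
    weight: str = "score",
) -> dict[str, float]:
    """Power iteration on the weight-normalized transition matrix.

    Dangling nodes (no outgoing weight) redistribute uniformly; uniform
    teleportation with probability 1 - damping.  Converged when the L1
    change drops below ``tol``.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("network has no nodes")
    A = net.weight_score if weight == "score" else net.weight_count.astype(np.float64)
    out = A.sum(axis=1)
    dangling = out == 0
    P = np.zeros_like(A, dtype=np.float64)
    nz = ~dangling
    P[nz] = A[nz] / out[nz, None]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v_new = damping * (P.T @ v + v[dangling].sum() / n) + (1 - damping) / n
        delta = np.abs(v_new - v).sum()
        v = v_new
        if delta < tol:
            v = v / v.sum()
            return {t: float(x) for t, x in zip(net.cell_types, v)}
    raise ConvergenceError(
        f"PageRank did not converge in {max_iter} iterations", residual=float(delta)
    )


def _undirected_presence(net: CellTypeNetwork, rule: str) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.cell_types)
    T = net.n_nodes
    for i in range(T):
        for j in range(i + 1, T):
            fwd = net.weight_count[i, j] > 0
            bwd = net.weight_count[j, i] > 0
            keep = (fwd and bwd) if rule == "both" else (fwd or bwd)
            if keep:
                G.add_edge(net.cell_types[i], net.cell_types[j])
    return G


def largest_clique(net: CellTypeNetwork, presence_rule: str = "both") -> set[str]:
    """Exact maximum clique of the presence graph (small cell-type graphs).

    ``presence_rule='both'`` draws an undirected edge only when significant
    pairs run in both directions; ``'any'`` when either direction has one.
    Ties break toward the lexicographically smallest sorted node list.
    """
    if presence_rule not in ("both", "any"):
        raise ValueError("presence_rule must be 'both' or 'any'")
    G = _undirected_presence(net, presence_rule)
    if G.number_of_nodes() == 0:
        return set()
    best: tuple[int, list[str]] | None = None
    for clique in nx.find_cliques(G):
        cand = (len(clique), sorted(clique))
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0] and cand[1] < best[1]
        ):
            best = cand
    return set(best[1])


def cluster_network(net: CellTypeNetwork) -> list[list[str]]:
    """Greedy modularity communities on the symmetrized score graph.

    Deterministic under node-label order; singletons allowed.  Clusters
    come back sorted internally and by their first member.
    """
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    W = net.weight_score + net.weight_score.T
    G = nx.Graph()
    G.add_nodes_from(net.cell_types)
    T = net.n_nodes
    for i in range(T):
        for j in range(i + 1, T):
            if W[i, j] > 0:
                G.add_edge(net.cell_types[i], net.cell_types[j], weight=float(W[i, j]))
    if G.number_of_edges() == 0:
        return sorted([[t] for t in net.cell_types])
    comms = nx.community.greedy_modularity_communities(G, weight="weight")
    return sorted([sorted(c) for c in comms])


def network_pcc(netA: CellTypeNetwork, netB: CellTypeNetwork, on: str = "scores") -> float:
    """Pearson r of the flattened off-diagonal weight matrices.

    NaN when either flattening is constant (correlation undefined).
    """
    if netA.cell_types != netB.cell_types:
        raise AlignmentError("networks must share an identical node list")
    mask = ~np.eye(netA.n_nodes, dtype=bool)
    if on == "scores":
        a, b = netA.weight_score[mask], netB.weight_score[mask]
    elif on == "counts":
        a = netA.weight_count[mask].astype(float)
        b = netB.weight_count[mask].astype(float)
    else:
        raise ValueError("on must be 'scores' or 'counts'")
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class AgreementReport:
    methods: list[str]
    datasets: list[str]
    pcc: dict[str, np.ndarray]  # dataset -> (M, M) symmetric, unit diagonal
    wilcoxon: dict[str, dict]   # reference method -> test summary

    def pcc_series(self, method_a: str, method_b: str) -> np.ndarray:
        ia, ib = self.methods.index(method_a), self.methods.index(method_b)
        return np.array([self.pcc[d][ia, ib] for d in self.datasets])


def _exact_signed_rank_greater(diff: np.ndarray) -> float:
    """Exact one-sided signed-rank p over all 2^n sign assignments.

    Counted by dynamic programming over the subset-sum distribution of the
    (tie-averaged, doubled-to-integer) ranks — exact even with ties.
    """
    d = diff[diff != 0]
    n = d.size
    ranks2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)
    w_obs2 = int(np.rint(ranks2[d > 0].sum()))
    # dist[s] = number of sign assignments with doubled W+ equal to s
    dist = np.zeros(ranks2.sum() + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r > 0 else dist
        dist = dist + shifted
    return float(dist[w_obs2:].sum() / 2**n)


def compare_methods(
    networks: Mapping[str, Mapping[str, CellTypeNetwork]],
    combined_tag: str = "combined",
    on: str = "scores",
) -> AgreementReport:
    """Pairwise network PCCs per dataset plus one-sided signed-rank tests.

    For each single-method reference m, the combined method's PCC-with-m
    series is tested against the best other single method's (highest
    median PCC with m), one-sided greater.  Exact enumeration for n <= 25
    datasets; all-zero difference vectors are flagged as undefined.
    """
    datasets = list(networks)
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    methods = sorted(networks[datasets[0]].keys())
    for d in datasets:
        if sorted(networks[d].keys()) != methods:
            raise AlignmentError(f"dataset {d}: method set mismatch")
    if combined_tag not in methods:
        raise ValueError(f"no {combined_tag!r} network supplied")
    M = len(methods)
    pcc: dict[str, np.ndarray] = {}
    for d in datasets:
        mat = np.eye(M)
        for i, j in combinations(range(M), 2):
            r = network_pcc(networks[d][methods[i]], networks[d][methods[j]], on=on)
            mat[i, j] = mat[j, i] = r
        pcc[d] = mat
    report = AgreementReport(methods=methods, datasets=datasets, pcc=pcc, wilcoxon={})

    singles = [m for m in methods if m != combined_tag]
    for ref in singles:
        rivals = [m for m in singles if m != ref]
        if not rivals or len(datasets) < 2:
            continue
        rival_med = {
            m: np.nanmedian(report.pcc_series(m, ref)) for m in rivals
        }
        second = max(rival_med, key=lambda m: (rival_med[m], m))
        diff = report.pcc_series(combined_tag, ref) - report.pcc_series(second, ref)
        diff = diff[~np.isnan(diff)]
        entry: dict = {"second_ranked": second, "n": int(diff.size)}
        if diff.size == 0 or np.all(diff == 0):
            entry.update(p_value=float("nan"), defined=False)
        else:
            if diff.size <= 25:
                entry.update(p_value=_exact_signed_rank_greater(diff), defined=True)
            else:
                res = stats.wilcoxon(diff, alternative="greater")
                entry.update(p_value=float(res.pvalue), defined=True)
        report.wilcoxon[ref] = entry
    return report
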
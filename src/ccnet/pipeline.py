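"""End-to-end runs: preprocess -> engines -> integrate -> network, plus the
post-hoc network and cross-run comparison commands.

Every artifact is a plain-text table or JSON and is byte-reproducible from
the run configuration and seed (no timestamps in outputs).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import CCNetError, PipelineError
from .engines import METHOD_TAGS, run_all_engines
from .integrate import IntegratedResult, build_result_table, integrate
from .io import (
    read_expression_input,
    read_json,
    write_json,
)
from .lrdb import filter_to_measured, load_lr_table
from .network import (
    CellTypeNetwork,
    build_network,
    cluster_network,
    compare_methods,
    largest_clique,
    pagerank_scores,
)
from .preprocess import (
    filter_genes_cells,
    log_transform,
    normalize_library_size,
    summarize_by_type,
)

__all__ = ["RunConfig", "run_infer", "run_network", "run_compare"]

log = logging.getLogger("ccnet")


@dataclass
class RunConfig:
    """All user-settable inference parameters; echoed into the manifest."""

    matrix_path: str
    annotation_path: str
    lr_path: str
    out_dir: str
    task_id: str = "run"
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    n_perm: int = 100
    top_n: int | None = None
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha: float = 0.05
    min_fraction: float = 0.1
    seed: int = 0
    refilter_renormalize: bool = False
    global_normalize: bool = False
    bh_correct: bool = False
    pcc_on: str = "scores"
    clique_edge: str = "both"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValueError("min_fraction must lie in [0, 1]")
        self.weights = tuple(float(w) for w in self.weights)

    @classmethod
    def from_manifest(cls, manifest: dict) -> "RunConfig":
        cfg = dict(manifest["config"])
        cfg["weights"] = tuple(cfg["weights"])
        return cls(**cfg)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


ENGINE_TABLE_COLUMNS = ["sender", "receiver", "lr_pair", "score", "p_value"]


def _engine_table(result) -> pd.DataFrame:
    rows = []
    for s, r, p in zip(*np.nonzero(result.tested)):
        rows.append(
            (result.cell_types[s], result.cell_types[r], result.pair_ids[p],
             float(result.scores[s, r, p]), float(result.pvalues[s, r, p]))
        )
    return pd.DataFrame(rows, columns=ENGINE_TABLE_COLUMNS)


def _network_tables(net: CellTypeNetwork):
    edges = pd.DataFrame(
        list(net.edges()),
        columns=["sender", "receiver", "weight_count", "weight_score"],
    )
    nodes = pd.DataFrame(
        [(t, net.cells_per_type.get(t, 0)) for t in net.cell_types],
        columns=["cell_type", "n_cells"],
    )
    return edges, nodes


def run_infer(cfg: RunConfig) -> dict:
    """Execute the full inference pipeline; returns the manifest dict.

    Output files: result_table.tsv, engine_<tag>.tsv (x3),
    network_edges.tsv, network_nodes.tsv, manifest.json.  Partial outputs
    are removed if any stage fails.
    """
    counts: dict[str, int] = {}
    with _stage("load"):
        X, ann, n_dropped = read_expression_input(cfg.matrix_path, cfg.annotation_path)
        db = load_lr_table(cfg.lr_path)
        counts.update(
            n_genes_in=X.n_genes, n_cells_in=X.n_cells,
            n_cells_unannotated=n_dropped, n_pairs_in=len(db),
        )

    with _stage("preprocess"):
        if cfg.refilter_renormalize:
            filt = filter_genes_cells(X, cfg.min_cells_per_gene, cfg.min_genes_per_cell)
            Xlog = log_transform(normalize_library_size(filt.matrix))
        else:
            Xn = normalize_library_size(X)
            filt = filter_genes_cells(X, cfg.min_cells_per_gene, cfg.min_genes_per_cell)
            Xlog = log_transform(Xn).subset(filt.gene_mask, filt.cell_mask)
        ann = ann.subset(Xlog.cell_barcodes)
        counts.update(
            n_genes_dropped=filt.n_genes_dropped,
            n_cells_dropped=filt.n_cells_dropped,
            n_genes=Xlog.n_genes, n_cells=Xlog.n_cells,
        )
        db = filter_to_measured(db, set(Xlog.gene_names))
        counts["n_pairs_measured"] = len(db)
        if len(db) == 0:
            raise CCNetError("no L-R pair has all subunits measured")

    with _stage("engines"):
        results = run_all_engines(
            Xlog, ann, db,
            n_perm=cfg.n_perm, seed=cfg.seed, min_fraction=cfg.min_fraction,
        )

    with _stage("integrate"):
        integrated = integrate(
            results, weights=cfg.weights, alpha=cfg.alpha,
            global_normalize=cfg.global_normalize, bh_correct=cfg.bh_correct,
        )
        table = build_result_table(integrated, results, cfg.task_id, cfg.top_n)
        counts["n_significant"] = int(integrated.significant.sum())

    with _stage("network"):
        summary = summarize_by_type(Xlog, ann)
        cells_per_type = dict(zip(summary.cell_types, map(int, summary.cells_per_type)))
        net = build_network(integrated, cells_per_type=cells_per_type)
        edges, nodes = _network_tables(net)

    manifest = {
        "version": __version__,
        "task_id": cfg.task_id,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "counts": counts,
    }

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with _stage("write"):
            def _w(df: pd.DataFrame, name: str):
                p = out / name
                df.to_csv(p, sep="\t", index=False)
                written.append(p)

            _w(table, "result_table.tsv")
            for res in results:
                _w(_engine_table(res), f"engine_{res.method}.tsv")
            _w(edges, "network_edges.tsv")
            _w(nodes, "network_nodes.tsv")
            write_json(manifest, out / "manifest.json")
            written.append(out / "manifest.json")
    except BaseException:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest


def _load_network(run_dir: Path) -> CellTypeNetwork:
    nodes = pd.read_csv(run_dir / "network_nodes.tsv", sep="\t")
    edges_path = run_dir / "network_edges.tsv"
    edges = pd.read_csv(edges_path, sep="\t") if edges_path.stat().st_size else None
    cell_types = [str(t) for t in nodes["cell_type"]]
    pos = {t: i for i, t in enumerate(cell_types)}
    T = len(cell_types)
    wc = np.zeros((T, T), dtype=np.int64)
    ws = np.zeros((T, T))
    if edges is not None and len(edges):
        for row in edges.itertuples(index=False):
            wc[pos[str(row.sender)], pos[str(row.receiver)]] = row.weight_count
            ws[pos[str(row.sender)], pos[str(row.receiver)]] = row.weight_score
    return CellTypeNetwork(
        cell_types, wc, ws,
        cells_per_type={t: int(n) for t, n in zip(cell_types, nodes["n_cells"])},
    )


def _engine_network(run_dir: Path, method: str, cell_types: list[str], alpha: float
                    ) -> CellTypeNetwork:
    df = pd.read_csv(run_dir / f"engine_{method}.tsv", sep="\t")
    pos = {t: i for i, t in enumerate(cell_types)}
    T = len(cell_types)
    wc = np.zeros((T, T), dtype=np.int64)
    ws = np.zeros((T, T))
    for row in df.itertuples(index=False):
        if row.p_value < alpha:
            s, r = pos[str(row.sender)], pos[str(row.receiver)]
            wc[s, r] += 1
            ws[s, r] += row.score
    return CellTypeNetwork(cell_types, wc, ws, mode=method)


def run_network(
    run_dir: str | Path,
    out_dir: str | Path | None = None,
    damping: float = 0.85,
    weight: str = "score",
    clique_edge: str = "both",
) -> dict:
    """Topology analytics for one finished run directory."""
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir is not None else run_dir
    out.mkdir(parents=True, exist_ok=True)
    net = _load_network(run_dir)
    pr = pagerank_scores(net, damping=damping, weight=weight)
    clique = largest_clique(net, presence_rule=clique_edge)
    clusters = cluster_network(net)
    pd.DataFrame(
        sorted(pr.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["cell_type", "pagerank"],
    ).to_csv(out / "pagerank.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(i, t) for i, cl in enumerate(clusters) for t in cl],
        columns=["cluster", "cell_type"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    report = {
        "pagerank": {k: pr[k] for k in sorted(pr)},
        "largest_clique": sorted(clique),
        "clusters": clusters,
    }
    write_json(report, out / "topology.json")
    return report


def run_compare(
    run_dirs: list[str | Path],
    out_path: str | Path,
    on: str = "scores",
) -> dict:
    """Cross-method agreement over >= 2 run directories."""
    if len(run_dirs) < 2:
        raise ValueError("compare requires at least two run directories")
    networks: dict[str, dict[str, CellTypeNetwork]] = {}
    for d in run_dirs:
        d = Path(d)
        manifest = read_json(d / "manifest.json")
        alpha = manifest["config"]["alpha"]
        combined = _load_network(d)
        per_method: dict[str, CellTypeNetwork] = {"combined": combined}
        for m in METHOD_TAGS:
            per_method[m] = _engine_network(d, m, combined.cell_types, alpha)
        networks[d.name] = per_method
    report = compare_methods(networks, on=on)
    payload = {
        "methods": report.methods,
        "datasets": report.datasets,
        "pcc": {d: report.pcc[d].tolist() for d in report.datasets},
        "wilcoxon": report.wilcoxon,
    }
    write_json(payload, Path(out_path))
    return payload
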
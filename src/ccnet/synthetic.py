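"""Synthetic scRNA-seq datasets with planted ligand-receptor channels.

Counts follow a negative binomial baseline whose per-cell mean is scaled by
a library-size factor; a planted channel multiplies the ligand subunits'
means by ``fold`` in the sender type and the receptor subunits' means by
``fold`` in the receiver type.  Decoy pairs connect untouched genes so
false-discovery metrics have a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .lrdb import GeneComplex, LRDatabase, LRPair
from .preprocess import CellAnnotation, CountMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryMetrics",
    "standard_spec",
    "generate_dataset",
    "evaluate_recovery",
    "significant_entries",
]


@dataclass
class SyntheticSpec:
    n_cell_types: int = 5
    cells_per_type: int | Sequence[int] = 100
    n_genes: int = 300
    baseline_mean: float = 1.0
    dispersion: float = 0.5
    planted_channels: list[tuple[str, str, LRPair, float]] = field(default_factory=list)
    n_decoy_pairs: int = 30
    library_size_spread: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValidationError("need at least one cell type and one gene")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("baseline_mean and dispersion must be positive")
        if self.library_size_spread < 1:
            raise ValidationError("library_size_spread must be >= 1")
        for sender, receiver, pair, fold in self.planted_channels:
            if fold < 1:
                raise ValidationError(f"fold must be >= 1 (pair {pair.pair_id})")
            for t in (sender, receiver):
                if t not in self.type_names:
                    raise ValidationError(f"unknown cell type {t!r}")
            for g in pair.genes:
                if g not in set(self.gene_names):
                    raise ValidationError(f"planted gene {g} outside n_genes")

    @property
    def type_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_cell_types)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def cells_per_type_list(self) -> list[int]:
        if isinstance(self.cells_per_type, int):
            return [self.cells_per_type] * self.n_cell_types
        return list(self.cells_per_type)


@dataclass
class GroundTruth:
    """Planted (sender, receiver, pair_id) triples plus the generating spec."""

    planted: frozenset[tuple[str, str, str]]
    spec: SyntheticSpec


@dataclass
class RecoveryMetrics:
    precision: float | None  # None when nothing was called significant
    recall: float
    fdp: float | None
    tp: int
    fp: int
    fn: int


def _gene(i: int) -> str:
    return f"G{i:04d}"


def _single(gene: str) -> GeneComplex:
    return GeneComplex(name=gene, subunits=(gene,))


def standard_spec(
    n_cell_types: int = 5,
    cells_per_type: int = 200,
    n_genes: int = 500,
    n_channels: int = 20,
    fold: float = 8.0,
    n_decoy_pairs: int = 30,
    baseline_mean: float = 1.0,
    dispersion: float = 0.5,
    library_size_spread: float = 1.5,
    seed: int = 0,
    complex_every: int = 5,
) -> SyntheticSpec:
    """Convenience builder: n_channels planted over distinct genes.

    Channels cycle deterministically over (sender, receiver) combinations;
    every ``complex_every``-th channel uses a two-subunit receptor to
    exercise complex handling.  Gene indices grow from 0, so decoys (drawn
    from the top of the gene range by generate_dataset) never collide.
    """
    channels = []
    gi = 0
    types = [f"T{i}" for i in range(n_cell_types)]
    sr = [(s, r) for s in types for r in types if s != r]
    for c in range(n_channels):
        lig = _single(_gene(gi)); gi += 1
        if complex_every and (c + 1) % complex_every == 0:
            subs = (_gene(gi), _gene(gi + 1)); gi += 2
            rec = GeneComplex(name="&".join(subs), subunits=subs)
        else:
            rec = _single(_gene(gi)); gi += 1
        sender, receiver = sr[c % len(sr)]
        pair = LRPair(lig, rec, frozenset({"synthetic"}))
        channels.append((sender, receiver, pair, float(fold)))
    if gi > n_genes:
        raise ValidationError("n_genes too small for requested channels")
    return SyntheticSpec(
        n_cell_types=n_cell_types,
        cells_per_type=cells_per_type,
        n_genes=n_genes,
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        planted_channels=channels,
        n_decoy_pairs=n_decoy_pairs,
        library_size_spread=library_size_spread,
        seed=seed,
    )


def generate_dataset(spec: SyntheticSpec):
    """Draw (CountMatrix, CellAnnotation, LRDatabase, GroundTruth).

    Fully deterministic given ``spec.seed``.  The returned database holds
    the planted pairs plus ``n_decoy_pairs`` decoys over genes untouched by
    any channel; a shortage of untouched genes raises a spec error.
    """
    rng = np.random.default_rng(spec.seed)
    types = spec.type_names
    genes = spec.gene_names
    sizes = spec.cells_per_type_list
    n_cells = sum(sizes)
    labels = [t for t, n in zip(types, sizes) for _ in range(n)]
    barcodes = [f"c{i:05d}" for i in range(n_cells)]

    gene_pos = {g: i for i, g in enumerate(genes)}
    type_pos = {t: i for i, t in enumerate(types)}
    # per-(gene, type) fold multipliers
    mult = np.ones((spec.n_genes, spec.n_cell_types))
    planted_genes: set[str] = set()
    for sender, receiver, pair, fold in spec.planted_channels:
        for g in pair.ligand.subunits:
            mult[gene_pos[g], type_pos[sender]] *= fold
        for g in pair.receptor.subunits:
            mult[gene_pos[g], type_pos[receiver]] *= fold
        planted_genes |= set(pair.genes)

    free = [g for g in genes if g not in planted_genes]
    if len(free) < 2 * spec.n_decoy_pairs:
        raise ValidationError(
            "not enough untouched genes for the requested decoy pairs"
        )
    decoy_genes = list(rng.choice(free, size=2 * spec.n_decoy_pairs, replace=False))
    decoys = [
        LRPair(_single(decoy_genes[2 * i]), _single(decoy_genes[2 * i + 1]),
               frozenset({"decoy"}))
        for i in range(spec.n_decoy_pairs)
    ]
    seen = {p.key for _, _, p, _ in spec.planted_channels}
    for d in decoys:
        if d.key in seen or (set(d.genes) & planted_genes):
            raise ValidationError(f"decoy pair {d.pair_id} collides with a channel")

    lib = rng.uniform(1.0, spec.library_size_spread, size=n_cells)
    codes = np.array([type_pos[t] for t in labels])
    mu = spec.baseline_mean * mult[:, codes] * lib[np.newaxis, :]
    size = 1.0 / spec.dispersion  # NB: var = mu + dispersion * mu^2
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.float64)

    X = CountMatrix(counts, genes, barcodes)
    ann = CellAnnotation.from_pairs(list(zip(barcodes, labels)))
    pairs = {p.key: p for _, _, p, _ in spec.planted_channels}
    for d in decoys:
        pairs[d.key] = d
    db = LRDatabase(sorted(pairs.values(), key=lambda p: p.pair_id))
    truth = GroundTruth(
        planted=frozenset(
            (s, r, p.pair_id) for s, r, p, _ in spec.planted_channels
        ),
        spec=spec,
    )
    return X, ann, db, truth


def significant_entries(integrated) -> set[tuple[str, str, str]]:
    """(sender, receiver, pair_id) triples flagged significant."""
    out = set()
    for s, r, p in zip(*np.nonzero(integrated.significant)):
        out.add(
            (integrated.cell_types[s], integrated.cell_types[r],
             integrated.pair_ids[p])
        )
    return out


def evaluate_recovery(
    significant: Iterable[tuple[str, str, str]], truth: GroundTruth
) -> RecoveryMetrics:
    """Precision / recall / false-discovery proportion against the truth.

    Precision and FDP are None (undefined) when nothing is significant.
    """
    sig = set(significant)
    tp = len(sig & truth.planted)
    fp = len(sig - truth.planted)
    fn = len(truth.planted - sig)
    precision = tp / (tp + fp) if sig else None
    recall = tp / len(truth.planted) if truth.planted else 0.0
    fdp = fp / (tp + fp) if sig else None
    return RecoveryMetrics(precision, recall, fdp, tp, fp, fn)
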
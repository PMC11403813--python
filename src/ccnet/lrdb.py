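"""Ligand-receptor pair knowledge: parsing, merging, and filtering.

Ligand and receptor units may be multi-subunit complexes.  The on-disk
dialect is a TSV with columns ``ligand`` and ``receptor`` (optionally
``source``); subunits within a cell are joined by ``&`` so that ``_`` stays
free for the canonical ``LIGAND_RECEPTOR`` pair id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

__all__ = [
    "GeneComplex",
    "LRPair",
    "LRDatabase",
    "load_lr_table",
    "merge_databases",
    "filter_to_measured",
    "write_lr_table",
    "demo_database",
]

SUBUNIT_SEP = "&"


@dataclass(frozen=True)
class GeneComplex:
    """A ligand or receptor unit: one gene, or an ordered subunit complex."""

    name: str
    subunits: tuple[str, ...]

    def __post_init__(self):
        if not self.subunits:
            raise ValidationError("complex requires at least one subunit")
        for s in self.subunits:
            if not s or any(c.isspace() for c in s):
                raise ValidationError(f"invalid subunit symbol: {s!r}")
        if len(set(self.subunits)) != len(self.subunits):
            raise ValidationError(f"duplicate subunits in complex {self.name!r}")
        if len(self.subunits) == 1 and self.name != self.subunits[0]:
            raise ValidationError(
                "single-gene complex must be named after its sole subunit"
            )

    @classmethod
    def from_token(cls, token: str) -> "GeneComplex":
        """Parse an ``A&B&C`` cell into a complex; symbols are uppercased."""
        token = token.strip().upper()
        if not token:
            raise ValidationError("empty complex token")
        subunits = tuple(token.split(SUBUNIT_SEP))
        return cls(name=SUBUNIT_SEP.join(subunits), subunits=subunits)

    @property
    def key(self) -> tuple[str, ...]:
        """Order-insensitive identity of the complex."""
        return tuple(sorted(self.subunits))


@dataclass(frozen=True)
class LRPair:
    ligand: GeneComplex
    receptor: GeneComplex
    sources: frozenset[str]

    def __post_init__(self):
        if not self.sources:
            raise ValidationError("pair requires at least one source tag")

    @property
    def pair_id(self) -> str:
        return f"{self.ligand.name}_{self.receptor.name}"

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Two pairs are duplicates iff their keys are equal."""
        return (self.ligand.key, self.receptor.key)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.ligand.subunits) | frozenset(self.receptor.subunits)

    def with_sources(self, sources: Iterable[str]) -> "LRPair":
        return LRPair(self.ligand, self.receptor, frozenset(sources))


@dataclass
class LRDatabase:
    pairs: list[LRPair] = field(default_factory=list)

    def __post_init__(self):
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValidationError("database contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def source_names(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p.sources
        return out

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def gene_set(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p.genes
        return out

    def summary(self) -> dict:
        per_source: dict[str, int] = {}
        for p in self.pairs:
            for s in p.sources:
                per_source[s] = per_source.get(s, 0) + 1
        return {
            "n_pairs": len(self.pairs),
            "sources": {k: per_source[k] for k in sorted(per_source)},
        }


def load_lr_table(path: str | Path, source_tag: str = "user") -> LRDatabase:
    """Load an L-R pair TSV.

    Rows carry ``source_tag`` unless the file has its own ``source`` column
    (``;``-separated tags).  Exact duplicate pairs within one file are
    collapsed, pooling their sources.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty L-R table")
    header = lines[0].split("\t")
    for col in ("ligand", "receptor"):
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    lig_i = header.index("ligand")
    rec_i = header.index("receptor")
    src_i = header.index("source") if "source" in header else None

    collapsed: dict[tuple, LRPair] = {}
    for row_num, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        lig_tok = cells[lig_i].strip() if lig_i < len(cells) else ""
        rec_tok = cells[rec_i].strip() if rec_i < len(cells) else ""
        if not lig_tok or not rec_tok:
            raise ValidationError(
                f"{path}: row {row_num}: empty ligand or receptor cell"
            )
        sources: frozenset[str]
        if src_i is not None and src_i < len(cells) and cells[src_i].strip():
            sources = frozenset(
                s.strip() for s in cells[src_i].split(";") if s.strip()
            )
        else:
            sources = frozenset({source_tag})
        pair = LRPair(
            GeneComplex.from_token(lig_tok), GeneComplex.from_token(rec_tok), sources
        )
        if pair.key in collapsed:
            pair = pair.with_sources(collapsed[pair.key].sources | pair.sources)
        collapsed[pair.key] = pair
    return LRDatabase(sorted(collapsed.values(), key=lambda p: p.pair_id))


def merge_databases(dbs: Sequence[LRDatabase]) -> LRDatabase:
    """Union of pair sets; duplicate pairs pool their source tags.

    Output order is deterministic (sorted by pair id), making the merge
    commutative and associative at the level of resulting pair sets.
    """
    if not dbs:
        raise ValueError("merge requires at least one database")
    collapsed: dict[tuple, LRPair] = {}
    for db in dbs:
        for pair in db:
            if pair.key in collapsed:
                pair = collapsed[pair.key].with_sources(
                    collapsed[pair.key].sources | pair.sources
                )
            collapsed[pair.key] = pair
    return LRDatabase(sorted(collapsed.values(), key=lambda p: p.pair_id))


def filter_to_measured(db: LRDatabase, gene_set: set[str]) -> LRDatabase:
    """Keep pairs whose every ligand and receptor subunit is in ``gene_set``."""
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    kept = [p for p in db if p.genes <= gene_set]
    return LRDatabase(kept)


def demo_database() -> LRDatabase:
    """Small bundled L-R table (45 human pairs incl. complexes).

    A stand-in for the full merged knowledge base, which is not
    redistributed; intended for demos and smoke tests.
    """
    return load_lr_table(Path(__file__).parent / "data" / "lr_pairs_demo.tsv")


def write_lr_table(db: LRDatabase, path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write the TSV dialect (and optionally a JSON summary)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ligand\treceptor\tsource\n")
        for p in db:
            fh.write(
                f"{SUBUNIT_SEP.join(p.ligand.subunits)}\t"
                f"{SUBUNIT_SEP.join(p.receptor.subunits)}\t"
                f"{';'.join(sorted(p.sources))}\n"
            )
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps(db.summary(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
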
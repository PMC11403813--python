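import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ccnet.lrdb import GeneComplex, LRDatabase, LRPair
from ccnet.preprocess import CellAnnotation, CountMatrix


def single(gene: str) -> GeneComplex:
    return GeneComplex(name=gene, subunits=(gene,))


def pair(lig: str, rec: str, sources=("s",)) -> LRPair:
    return LRPair(
        GeneComplex.from_token(lig), GeneComplex.from_token(rec), frozenset(sources)
    )


@pytest.fixture
def toy_db() -> LRDatabase:
    return LRDatabase([pair("L1", "R1"), pair("L2", "R2A&R2B")])


@pytest.fixture
def toy_matrix() -> CountMatrix:
    # 5 genes x 4 cells, hand-checkable
    values = np.array(
        [
            [1, 0, 2, 3],
            [0, 4, 0, 1],
            [2, 2, 2, 2],
            [0, 0, 5, 0],
            [3, 1, 0, 0],
        ],
        dtype=float,
    )
    return CountMatrix(values, [f"g{i}" for i in range(1, 6)],
                       [f"c{i}" for i in range(1, 5)])


@pytest.fixture
def toy_annotation() -> CellAnnotation:
    return CellAnnotation.from_pairs(
        [("c1", "A"), ("c2", "A"), ("c3", "B"), ("c4", "B")]
    )
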
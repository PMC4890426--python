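import numpy as np
import pytest

from pedigrisk import CellRecord, PedigreeForest


def make_full_binary_forest(depth: int, lifetime: float = 10.0) -> PedigreeForest:
    """Full binary tree: every cell up to `depth - 1` divides, cells at
    `depth` are leaves observed to divide as well (no children)."""
    records = []

    def build(cell_id, parent_id, gen, birth):
        end = (birth or 0.0) + lifetime
        records.append(CellRecord(cell_id, parent_id, "P", birth, end,
                                  "division", gen))
        if gen < depth:
            build(cell_id + ".0", cell_id, gen + 1, end)
            build(cell_id + ".1", cell_id, gen + 1, end)

    build("F", None, 0, None)
    return PedigreeForest(records)


@pytest.fixture
def tiny_forest():
    """Smallest complete pedigree: founder divides into two daughters."""
    return PedigreeForest([
        CellRecord("m", None, "P", None, 10.0, "division", 0),
        CellRecord("d1", "m", "P", 10.0, 25.0, "division", 1),
        CellRecord("d2", "m", "P", 10.0, 30.0, "division", 1),
    ])


@pytest.fixture
def depth2_forest():
    return make_full_binary_forest(2)


@pytest.fixture
def depth3_forest():
    return make_full_binary_forest(3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
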
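import sys
from pathlib import Path

import numpy as np
import pytest

import landfuse as lf

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


def pair_from_g2(g2_array, hierarchy=None):
    """Raster pair with g1 derived from a fine-grade code array."""
    g2 = np.asarray(g2_array, dtype=np.int64)
    h = hierarchy or lf.infer_hierarchy_from_codes(np.unique(g2).tolist())
    return lf.pair_rasters(None, lf.Grid(g2), h)


def cells_of(shape):
    """All (row, col) indices of a grid shape."""
    return [(r, c) for r in range(shape[0]) for c in range(shape[1])]


def composition_of(cells):
    """WindowComposition straight from (parent, child) tuples."""
    from collections import Counter

    return lf.composition_from_counts(Counter(cells))


@pytest.fixture(scope="session")
def w1_pair():
    """The 16-cell worked window: parent 1 = {11:4, 12:4}, parent 2 = {21:8}."""
    g2 = np.array([11] * 4 + [12] * 4 + [21] * 8).reshape(4, 4)
    return pair_from_g2(g2)


@pytest.fixture(scope="session")
def w1_composition(w1_pair):
    return lf.window_composition(w1_pair, cells_of((4, 4)))


@pytest.fixture(scope="session")
def ecotone_run():
    """128x128 ecotone landscape with PR surfaces at radius 5 (shared by the
    degree-of-changes and information-volume checks; ~10 s to build)."""
    spec = lf.SyntheticSpec(
        rows=128, cols=128, n_parents=4, subclasses_per_parent=4,
        clump=0.5, ecotone_band=(43, 86), seed=7,
    )
    pair, band = lf.generate_ecotone_landscape(spec)
    ws = lf.WindowSpec(5, units="cells")
    fli = lf.compute_surface(pair, "pr", "fli", ws)
    g1li = lf.compute_surface(pair, "pr", "g1li", ws)
    return {"pair": pair, "band": band, "fli": fli, "g1li": g1li}
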
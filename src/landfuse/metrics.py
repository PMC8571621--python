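"""Class-level landscape metric components and the fusion formula.

Three classic landscape pattern indicators are supported, each written as an
aggregation LI_X = sum_i LI_i of per-class components so that one generic
fusion step covers all of them:

- SHDI (Shannon's diversity index): LI_i = -p_i ln p_i
- PR (patch richness):              LI_i = 1 for each class present
- NP (number of patches):           LI_i = count of connected same-class
  components within the window footprint

The fused indicator injects the vertical-structure weights w_i from the
fine grade into the coarse-grade components:

    FLI_X = sum_i (1 + w_i) * LI_i

With all w_i = 0 (no subclass structure) the fused value reduces exactly to
the coarse metric; since 0 <= w_i <= 1 and LI_i >= 0, it is always sandwiched
between LI_X and 2 * LI_X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .entropy import EntropyWeights, WindowComposition
from .errors import EmptyWindowError, LookupError_
from .raster import CategoricalRasterPair

__all__ = [
    "MetricComponents",
    "FusedValue",
    "shdi_components",
    "pr_components",
    "np_components",
    "fuse",
    "METRICS",
    "Grade",
    "Connectivity",
]

METRICS = ("shdi", "pr", "np")
Grade = Literal["parent", "child"]
Connectivity = Literal[4, 8]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class MetricComponents:
    """Per-class components LI_i of one indicator in one window."""

    metric: str
    grade: str
    per_class: dict[int, float]

    @property
    def total(self) -> float:
        """The plain (unfused) indicator value LI_X."""
        return float(sum(self.per_class.values()))


@dataclass(frozen=True)
class FusedValue:
    """A fused indicator value FLI_X with its provenance."""

    metric: str
    value: float
    base: float
    weights_used: EntropyWeights


def _grade_proportions(c: WindowComposition, grade: Grade) -> dict[int, float]:
    if c.total_valid == 0:
        raise EmptyWindowError(f"metric undefined on an empty window")
    if grade == "parent":
        return dict(c.p_parent)
    return {
        child: n / c.total_valid for (_, child), n in c.child_counts.items()
    }


def shdi_components(c: WindowComposition, grade: Grade = "parent") -> MetricComponents:
    """Shannon diversity components -p_i ln p_i over the chosen grade."""
    props = _grade_proportions(c, grade)
    per = {code: float(-p * np.log(p)) for code, p in props.items()}
    return MetricComponents("shdi", grade, per)


def pr_components(c: WindowComposition, grade: Grade = "parent") -> MetricComponents:
    """Patch richness components: 1 per class present; total = richness."""
    props = _grade_proportions(c, grade)
    return MetricComponents("pr", grade, {code: 1.0 for code in props})


def np_components(
    pair: CategoricalRasterPair,
    cells: Iterable[tuple[int, int]] | np.ndarray,
    grade: Grade = "parent",
    connectivity: Connectivity = 8,
) -> MetricComponents:
    """Number-of-patches components within the window footprint.

    Patches are delineated inside the footprint only: a patch extending
    beyond the window counts once per in-window fragment.  Connectivity 8
    (queen, the common landscape-metric default) joins diagonal neighbours;
    connectivity 4 (rook) does not, so NP_8 <= NP_4 on any grid.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    idx = np.asarray(list(cells) if not isinstance(cells, np.ndarray) else cells)
    if idx.size == 0:
        raise EmptyWindowError("NP undefined on an empty window")
    rows, cols = idx[:, 0], idx[:, 1]
    keep = pair.valid_mask[rows, cols]
    rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        raise EmptyWindowError("NP undefined on an all-nodata window")

    r0, c0 = rows.min(), cols.min()
    sub = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    grid = pair.g1 if grade == "parent" else pair.g2
    values = grid.values[rows, cols]
    per: dict[int, float] = {}
    structure = _STRUCTURES[connectivity]
    for code in np.unique(values):
        sub[:] = False
        sel = values == code
        sub[rows[sel] - r0, cols[sel] - c0] = True
        _, n_patches = ndimage.label(sub, structure=structure)
        per[int(code)] = float(n_patches)
    return MetricComponents("np", grade, per)


def fuse(base: MetricComponents, weights: EntropyWeights) -> FusedValue:
    """Apply the fusion formula FLI_X = sum_i (1 + w_i) * LI_i.

    ``base`` must hold coarse-grade (parent) components.  Parents carrying
    components but no weight entry contribute with w_i = 0; a weight for a
    parent that has no component is a bookkeeping error and raises.
    """
    if base.grade != "parent":
        raise ValueError("fusion applies to coarse-grade (parent) components")
    stray = set(weights.w) - set(base.per_class)
    if stray:
        raise LookupError_(
            f"weights reference parents absent from components: {sorted(stray)}"
        )
    value = sum(
        (1.0 + weights.weight(parent)) * li
        for parent, li in base.per_class.items()
    )
    return FusedValue(base.metric, float(value), base.total, weights)
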
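"""Synthetic two-grade nested categorical landscapes.

Real hierarchical land-cover maps are large external downloads; every stage
of the fusion pipeline is instead exercised on generated landscapes whose
structure is controllable and whose ground truth is known by construction:

- the coarse grade (G1) is a clumped mosaic made by thresholding a
  Gaussian-smoothed random field into classes of roughly equal area
  (``clump`` sets the smoothing radius, 0 = salt-and-pepper, 1 = broad
  contiguous patches);
- within each coarse patch the fine grade (G2) is drawn i.i.d. from that
  parent's subclass distribution, itself drawn from a symmetric Dirichlet
  with concentration ``mix`` (small: one subclass dominates and the fusion
  weights vanish; large/inf: uniform subclasses, maximal weights);
- an optional ecotone band forces near-uniform subclass mixing inside a row
  interval and near-monosubclass composition outside it, emulating the
  transition zones where vertical structure concentrates.

All randomness flows from the single ``seed``; identical specs give
bit-identical rasters.  Codes follow the decimal-prefix convention
(child = parent*10 + index), so at most 9 subclasses per parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .hierarchy import ClassHierarchy, build_hierarchy
from .raster import (
    CategoricalRasterPair,
    DEFAULT_NODATA,
    Grid,
    GridTransform,
    pair_rasters,
)

__all__ = ["SyntheticSpec", "generate_landscape", "generate_ecotone_landscape"]

# near-monosubclass dominance outside an ecotone band
_ECOTONE_EPS = 0.02


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated two-grade landscape.

    ``subclasses_per_parent`` may be one int for all parents or a per-parent
    sequence; ``mix`` may be ``numpy.inf`` for exactly uniform subclass
    distributions.  ``ecotone_band`` is a half-open row interval (r0, r1).
    """

    rows: int = 128
    cols: int = 128
    n_parents: int = 4
    subclasses_per_parent: int | Sequence[int] = 4
    clump: float = 0.5
    mix: float = 1.0
    ecotone_band: tuple[int, int] | None = None
    seed: int = 0

    def subclass_counts(self) -> list[int]:
        if isinstance(self.subclasses_per_parent, int):
            return [self.subclasses_per_parent] * self.n_parents
        counts = list(self.subclasses_per_parent)
        if len(counts) != self.n_parents:
            raise ValueError(
                "subclasses_per_parent length must equal n_parents"
            )
        return counts

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.n_parents < 1:
            raise ValueError("need at least one parent class")
        counts = self.subclass_counts()
        if any(n < 1 for n in counts):
            raise ValueError("every parent needs at least one subclass")
        if any(n > 9 for n in counts):
            raise ValueError(
                "decimal-prefix codes allow at most 9 subclasses per parent"
            )
        if not 0.0 <= self.clump <= 1.0:
            raise ValueError("clump must lie in [0, 1]")
        if not self.mix > 0:
            raise ValueError("mix must be positive (numpy.inf for uniform)")
        if self.ecotone_band is not None:
            r0, r1 = self.ecotone_band
            if not (0 <= r0 < r1 <= self.rows):
                raise ValueError(
                    f"ecotone band {self.ecotone_band} outside grid rows"
                )


def _scheme_hierarchy(spec: SyntheticSpec) -> ClassHierarchy:
    rows = []
    for i, n_sub in enumerate(spec.subclass_counts(), start=1):
        rows.extend((i * 10 + k, i) for k in range(1, n_sub + 1))
    return build_hierarchy(rows)


def _parent_mosaic(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Clumped coarse mosaic: smoothed noise cut at equal-area quantiles."""
    noise = rng.standard_normal((spec.rows, spec.cols))
    sigma = spec.clump * min(spec.rows, spec.cols) / 8.0
    smooth = ndimage.gaussian_filter(noise, sigma) if sigma > 0 else noise
    if spec.n_parents == 1:
        return np.ones_like(smooth, dtype=np.int64)
    qs = np.quantile(smooth, np.linspace(0, 1, spec.n_parents + 1)[1:-1])
    return np.digitize(smooth, qs).astype(np.int64) + 1


def _subclass_probs(
    n_sub: int, mix: float, rng: np.random.Generator
) -> np.ndarray:
    if n_sub == 1:
        return np.ones(1)
    if np.isinf(mix):
        return np.full(n_sub, 1.0 / n_sub)
    return rng.dirichlet(np.full(n_sub, mix))


def _draw_children(
    parent: np.ndarray,
    probs_by_parent: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    g2 = np.zeros_like(parent)
    for p in sorted(probs_by_parent):
        sel = parent == p
        probs = probs_by_parent[p]
        picks = rng.choice(len(probs), size=int(sel.sum()), p=probs)
        g2[sel] = p * 10 + 1 + picks
    return g2


def _build_pair(
    spec: SyntheticSpec, g1: np.ndarray, g2: np.ndarray
) -> CategoricalRasterPair:
    transform = GridTransform(0.0, 0.0, 1.0)
    g1_grid = Grid(g1, DEFAULT_NODATA, transform)
    g2_grid = Grid(g2, DEFAULT_NODATA, transform)
    return pair_rasters(g1_grid, g2_grid, _scheme_hierarchy(spec), "error")


def generate_landscape(spec: SyntheticSpec) -> CategoricalRasterPair:
    """Generate a vertically consistent coarse/fine raster pair.

    With one subclass per parent the fine grade is a recoding of the coarse
    grade and every downstream fused surface equals its plain counterpart.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g1 = _parent_mosaic(spec, rng)
    probs = {
        i: _subclass_probs(n, spec.mix, rng)
        for i, n in enumerate(spec.subclass_counts(), start=1)
    }
    g2 = _draw_children(g1, probs, rng)
    return _build_pair(spec, g1, g2)


def generate_ecotone_landscape(
    spec: SyntheticSpec,
) -> tuple[CategoricalRasterPair, np.ndarray]:
    """Landscape with a horizontal band of maximal subclass mixing.

    Outside the band each parent is near-monosubclass (its first subclass
    carries probability ``1 - 0.02``); inside the band subclasses are
    exactly uniform.  Returns the pair and the boolean band mask, so tests
    can assert that fused-vs-plain differences concentrate in the band.
    """
    spec.validate()
    if spec.ecotone_band is None:
        raise ValueError("spec.ecotone_band is required")
    r0, r1 = spec.ecotone_band
    rng = np.random.default_rng(spec.seed)
    g1 = _parent_mosaic(spec, rng)

    counts = spec.subclass_counts()
    outside_probs: dict[int, np.ndarray] = {}
    inside_probs: dict[int, np.ndarray] = {}
    for i, n in enumerate(counts, start=1):
        if n == 1:
            outside_probs[i] = inside_probs[i] = np.ones(1)
            continue
        p_out = np.full(n, _ECOTONE_EPS / (n - 1))
        p_out[0] = 1.0 - _ECOTONE_EPS
        outside_probs[i] = p_out
        inside_probs[i] = np.full(n, 1.0 / n)

    band = np.zeros((spec.rows, spec.cols), dtype=bool)
    band[r0:r1, :] = True
    g2 = np.zeros_like(g1)
    g2[~band] = _draw_children(g1[~band], outside_probs, rng)
    g2[band] = _draw_children(g1[band], inside_probs, rng)
    return _build_pair(spec, g1, g2), band
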
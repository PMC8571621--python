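"""Information volume of metric surfaces via Huffman coding, and
surface-comparison statistics.

A metric surface's representational content is measured as the number of
bits an optimal binary prefix (Huffman) code needs to store it losslessly:
valid cells are min-max normalized, quantized to the first ``d`` decimal
places (default 4), a Huffman codebook is built from the symbol frequencies
of that surface, and each cell is charged its symbol's code length.  The
total over valid cells is the surface's information volume; richer, more
heterogeneous surfaces need longer codes.  Spatial topology is deliberately
ignored — only the value distribution is coded.

Comparison statistics between two surfaces of the same metric/geometry:

- ``degree_of_changes``: |difference| of the independently min-max
  normalized surfaces, in [0, 1] — where the fused and plain indicators
  disagree most.
- ``surface_correlation``: Pearson r over shared valid cells.
- ``compare_info_volume``: per-cell information-volume difference DIV, the
  area ratio RA (fraction of cells where the first surface carries more
  bits) and the ratio RV of positive to total absolute difference.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import GridAlignmentError
from .raster import Grid
from .window import MetricSurface, SURFACE_NODATA

__all__ = [
    "HuffmanCodebook",
    "InfoVolumeResult",
    "InfoVolumeComparison",
    "quantize_surface",
    "huffman_codebook",
    "info_volume",
    "degree_of_changes",
    "surface_correlation",
    "compare_info_volume",
]


def _as_grid(s) -> Grid:
    return s.grid if isinstance(s, MetricSurface) else s


@dataclass(frozen=True)
class HuffmanCodebook:
    """Optimal binary prefix-code lengths for a symbol frequency profile."""

    counts: dict[int, int]
    code_length: dict[int, int]

    @property
    def mean_code_length(self) -> float:
        """Frequency-weighted mean bits per symbol occurrence."""
        total = sum(self.counts.values())
        return (
            sum(self.counts[s] * l for s, l in self.code_length.items()) / total
        )

    def kraft_sum(self) -> float:
        """sum 2^-len; exactly 1 for a full binary tree (>= 2 symbols)."""
        return float(sum(2.0 ** -l for l in self.code_length.values()))


@dataclass(frozen=True)
class InfoVolumeResult:
    """Per-cell and total Huffman code lengths of one surface."""

    per_cell_bits: Grid
    total_bits: int
    mean_bits_per_cell: float
    codebook: HuffmanCodebook


@dataclass(frozen=True)
class InfoVolumeComparison:
    """Cellwise information-volume comparison of two surfaces (x vs y)."""

    div: Grid                  # per-cell bits(x) - bits(y)
    ra: float                  # fraction of valid cells with DIV > 0
    rv: float | None           # sum(+DIV) / sum(|DIV|); None when DIV == 0
    totals_ratio: float        # total_bits(x) / total_bits(y)


def quantize_surface(surface, decimals: int = 4) -> Grid:
    """Min-max normalize valid cells and quantize to integer symbols.

    Values map to ``round_half_up(normalized * 10**decimals)``, giving
    symbols in 0..10**decimals.  A constant surface normalizes to all-zero
    symbols.  Invalid cells carry symbol nodata (-1).
    """
    if decimals <= 0:
        raise ValueError(f"decimals must be positive, got {decimals}")
    grid = _as_grid(surface)
    valid = grid.valid_mask
    if not valid.any():
        raise ValueError("cannot quantize a surface with no valid cells")
    vals = grid.values.astype(np.float64)
    lo = vals[valid].min()
    hi = vals[valid].max()
    scale = 10 ** decimals
    out = np.full(grid.shape, -1, dtype=np.int64)
    if hi > lo:
        norm = (vals[valid] - lo) / (hi - lo)
        # round half up (not banker's rounding)
        out[valid] = np.floor(norm * scale + 0.5).astype(np.int64)
    else:
        out[valid] = 0
    return Grid(out, -1, grid.transform, grid.crs_tag)


def huffman_codebook(counts: Mapping[int, int]) -> HuffmanCodebook:
    """Build optimal binary prefix-code lengths from symbol frequencies.

    Ties in the merge queue break on (count, smallest symbol in subtree)
    ascending, making code lengths deterministic.  Symbols with zero count
    get no code; a single-symbol alphabet is assigned length 1 (one bit per
    cell — the tree degenerates but storage is never free).
    """
    counts = {int(s): int(n) for s, n in counts.items() if n > 0}
    if not counts:
        raise ValueError("huffman_codebook needs at least one positive count")
    if len(counts) == 1:
        (sym,) = counts
        return HuffmanCodebook(counts, {sym: 1})
    depth = {s: 0 for s in counts}
    heap = [(n, s, (s,)) for s, n in counts.items()]
    heapq.heapify(heap)
    while len(heap) > 1:
        n1, m1, syms1 = heapq.heappop(heap)
        n2, m2, syms2 = heapq.heappop(heap)
        merged = syms1 + syms2
        for s in merged:
            depth[s] += 1
        heapq.heappush(heap, (n1 + n2, min(m1, m2), merged))
    return HuffmanCodebook(counts, depth)


def info_volume(surface, decimals: int = 4) -> InfoVolumeResult:
    """Information volume of a surface under its own Huffman codebook."""
    grid = _as_grid(surface)
    symbols = quantize_surface(surface, decimals)
    valid = symbols.valid_mask
    syms = symbols.values[valid]
    uniq, n = np.unique(syms, return_counts=True)
    book = huffman_codebook(dict(zip(uniq.tolist(), n.tolist())))
    lengths = np.array([book.code_length[int(s)] for s in uniq], dtype=np.int64)
    per_cell = np.full(grid.shape, SURFACE_NODATA, dtype=np.float64)
    per_cell[valid] = lengths[np.searchsorted(uniq, syms)]
    total = int(per_cell[valid].sum())
    return InfoVolumeResult(
        per_cell_bits=Grid(per_cell, SURFACE_NODATA, grid.transform, grid.crs_tag),
        total_bits=total,
        mean_bits_per_cell=total / int(valid.sum()),
        codebook=book,
    )


def _shared_valid(a: Grid, b: Grid) -> np.ndarray:
    if a.shape != b.shape:
        raise GridAlignmentError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.valid_mask & b.valid_mask


def _minmax_norm(vals: np.ndarray) -> np.ndarray:
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        return (vals - lo) / (hi - lo)
    return np.zeros_like(vals)


def degree_of_changes(fli, g1li) -> Grid:
    """|difference| of independently min-max normalized surfaces, in [0,1].

    Symmetric in its arguments; a constant surface normalizes to zero, so
    against a constant baseline the result is the other surface's
    normalized values.
    """
    a, b = _as_grid(fli), _as_grid(g1li)
    shared = _shared_valid(a, b)
    out = np.full(a.shape, SURFACE_NODATA, dtype=np.float64)
    if shared.any():
        out[shared] = np.abs(
            _minmax_norm(a.values[shared].astype(np.float64))
            - _minmax_norm(b.values[shared].astype(np.float64))
        )
    return Grid(out, SURFACE_NODATA, a.transform, a.crs_tag)


def surface_correlation(a, b) -> float | None:
    """Pearson r between two surfaces over shared valid cells.

    Returns None (an explicit undefined flag, never NaN) when fewer than two
    shared cells exist or either surface is constant on them.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    shared = _shared_valid(ga, gb)
    if shared.sum() < 2:
        return None
    x = ga.values[shared].astype(np.float64)
    y = gb.values[shared].astype(np.float64)
    if x.var() == 0.0 or y.var() == 0.0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def compare_info_volume(
    x: InfoVolumeResult, y: InfoVolumeResult
) -> InfoVolumeComparison:
    """Cellwise comparison of two information-volume maps (x minus y).

    RA is the fraction of shared valid cells where x carries strictly more
    bits; RV the positive share of the total absolute difference (1.0 when
    every difference is positive, None when the surfaces code identically).
    """
    gx, gy = x.per_cell_bits, y.per_cell_bits
    shared = _shared_valid(gx, gy)
    div = np.full(gx.shape, SURFACE_NODATA, dtype=np.float64)
    d = gx.values[shared] - gy.values[shared]
    div[shared] = d
    n = int(shared.sum())
    ra = float((d > 0).sum() / n) if n else 0.0
    abs_sum = float(np.abs(d).sum())
    rv = float(d[d > 0].sum() / abs_sum) if abs_sum > 0 else None
    return InfoVolumeComparison(
        div=Grid(div, SURFACE_NODATA, gx.transform, gx.crs_tag),
        ra=ra,
        rv=rv,
        totals_ratio=x.total_bits / y.total_bits,
    )
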
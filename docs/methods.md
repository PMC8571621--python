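# Methods

## Model

A two-grade land-cover classification is a partition hierarchy: coarse
classes `x_i ∈ X`, fine classes `y_ij ∈ Y`, and for each `i` the subclass
set `Y_i ⊆ Y` with `n_i = |Y_i|`. On a co-registered raster pair (G1, G2)
the package requires *vertical consistency*: at every valid cell the G2 code
maps to the G1 code through the hierarchy. Pairing can enforce this by
erroring on the first offending cell, by masking offending cells, or by
deriving G1 from G2 outright (the default when only G2 is supplied).

Within a window, vertical structure is quantified in nats:

- global entropy `H(X) = -Σ p(x_i) ln p(x_i)`;
- per-parent conditional share
  `H_i' = -p(x_i) Σ_j p(y_ij|x_i) ln p(y_ij|x_i)`, with
  `H(Y|X) = Σ_i H_i'` (the chain-rule identity is property-tested);
- fusion weight `w_i = H_i' / ln(n_i)`.

All proportions are computed over valid cells only; NoData never enters a
denominator. The conditional proportion is taken as
`count(y_ij) / count(x_i)` — the one reading under which the entropy
formulae are internally consistent.

Each supported indicator is expressed as a sum of per-coarse-class
components `LI_X = Σ_i LI_i` so that one fusion formula,
`FLI_X = Σ_i (1 + w_i)·LI_i`, covers SHDI, PR and NP alike (FLI-PR
simplifies to `PR + Σ w_i` and FLI-NP to `Σ (1+w_i)·NP_i`, but both are
computed through the generic formula so it stays the single source of
truth). Two consequences are enforced as invariants: the sandwich bound
`LI_X ≤ FLI_X ≤ 2·LI_X`, and exact reduction `FLI_X = LI_X` when no parent
has subclass structure.

## Parameters that matter

- **`n_source`** (`window` default | `dataset` | `scheme`): what counts as
  `n_i` in the weight's denominator. The window-local choice keeps `w_i` a
  self-contained realized/maximum entropy ratio, consistent with every other
  window-local probability, and gives the sharp bound `w_i ≤ p(x_i)`; the
  dataset-wide and scheme-defined readings are selectable because published
  usage is ambiguous on this point. With `n_i = 1` the formula is 0/0 and
  `w_i` is defined as 0, the continuous limit of `H_i' → 0`.
- **Window radius** (map units, converted through the cell size; or cell
  units directly). A cell belongs to the window iff the Euclidean distance
  between cell centres is ≤ the radius, so radius 1.0 is the 5-cell cross
  and radius 1.5 the full 3×3 block. Typical analyses sweep radii of tens
  of cells (e.g. 10–50 km on 1 km data).
- **`edge_policy`** (`truncate` default | `nodata`) and
  **`min_valid_fraction`** (default 0.5): truncation keeps study-area
  coverage at edges while the threshold suppresses centres computed from
  near-empty windows; `nodata` reproduces the strict behaviour of
  conventional landscape-metric software that voids edge windows.
- **Patch connectivity** for NP (8 default, 4 selectable): 8-connectivity is
  the common landscape-metric convention; `NP_8 ≤ NP_4` always. Patches are
  delineated within the window footprint only, so a patch crossing the
  window boundary counts once per in-window fragment — the moving-window
  contract assigns the metric *of that window* to the centre.
- **Quantization decimals** for information volume (default 4): surfaces
  are min-max normalized and rounded half-up to `10^d + 1` possible symbols
  before coding. Natural log is used for all landscape entropies; the
  information volume uses log base 2 because Huffman codes are binary.

## Information volume

Each surface gets its own Huffman codebook built from its symbol
frequencies. Merge ties break on (count, smallest symbol) ascending, making
codebooks deterministic; Kraft equality `Σ 2^-len = 1` and the optimality
band `H₂ ≤ mean length < H₂ + 1` are property-tested, including against
randomized full-tree adversary codes. A single-symbol surface is charged one
bit per cell (storage is never free; also the natural limit of a two-symbol
alphabet as one count vanishes). Per-cell information volume is simply the
cell's code length; no smoothing is applied, and spatial topology is
deliberately not modelled — the measure reflects the value distribution
only.

For comparisons, the degree-of-changes map normalizes each surface
independently over the shared valid cells before differencing (joint
normalization would let one surface's range distort the other's; the
independent choice also makes the map symmetric in its arguments). The
information-volume comparison reports the per-cell difference DIV, the area
ratio RA = fraction of cells with DIV > 0, and RV = positive share of the
total absolute difference; Pearson correlation between surfaces is computed
with scipy over shared valid cells and returns an explicit undefined flag
(None) rather than NaN when either surface is constant.

## Synthetic landscapes

The generator emulates the structure the method responds to, not any real
region's composition. The coarse mosaic thresholds a Gaussian-smoothed
random field at equal-area quantiles (`clump` ∈ [0,1] scales the smoothing
sigma up to 1/8 of the short grid side); subclasses are drawn i.i.d. within
each coarse class from a per-parent distribution sampled from a symmetric
Dirichlet with concentration `mix` (`mix → 0` near-degenerate, `mix = ∞`
exactly uniform). The ecotone variant replaces the Dirichlet draw with
fixed vectors — dominant-subclass probability 0.98 outside the band,
exactly uniform inside — so the band contrast is a construction property
rather than a sampling accident. Defaults (128×128 cells, 4 coarse classes
with 4 subclasses each, `clump` 0.5) mirror the shape of national two-grade
LULC schemes (commonly ~6 coarse and ~24 fine classes) at a desk-scale grid.

What the generator does *not* emulate: spatially autocorrelated subclass
arrangement within coarse patches (subclasses are i.i.d. given the parent),
realistic class-area distributions, linear features, or registration error.
Passing tests therefore demonstrate the correctness of the computation and
the qualitative behaviour of the fusion (weights rise with subclass mixing,
differences concentrate where vertical structure is largest, fused surfaces
carry more Huffman bits) — not calibrated magnitudes for any real map.

## Numerical choices and degenerate inputs

- Entropy terms are summed only over strictly positive proportions, so
  `0·ln 0` never arises.
- Empty windows (no valid cells) are a flagged composition state; entropy
  and metric calls on them raise, and the moving window writes NoData.
- Constant surfaces min-max normalize to all-zero symbols.
- Quantization rounds half up (0.00005 at 4 decimals → symbol 1), not to
  even.
- The circular offset set uses a 1e-12 slack on the squared-distance
  comparison so exact integer radii include their boundary cells.
- Raster cells must be square; anisotropic grids are rejected because the
  window is defined on cell-centre Euclidean distance.
- Scale choices: test and acceptance runs use grids of 32–128 cells a side
  and radii of 2–5 cells, sizes at which every surface can also be verified
  against per-centre brute-force oracles.

## Known limitations

- Two grades only; deeper hierarchies would require the recursive
  (grade-by-grade) extension and are out of scope.
- Only SHDI, PR and NP are implemented; the component/fusion interfaces are
  written so additional decomposable indicators can be added, but none are.
- The moving window is computed per centre without incremental updates;
  fine for desk-scale rasters, not tuned for continental 1 km grids.
- TIFF georeferencing is carried in a JSON ImageDescription tag, not full
  GeoTIFF geo-keys; ESRI ASCII grid is the lossless interchange format.
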
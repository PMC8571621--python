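"""Rasterize plain and fused indicators with a circular moving window.

Generates a clumped 4-parent / 16-subclass synthetic landscape, sweeps a
radius-4 window, and summarizes the three Shannon-diversity surfaces: the
coarse G1LI, the fine G2LI, and the fused FLI between them.
"""

import tempfile
from pathlib import Path

import numpy as np

import landfuse as lf

spec = lf.SyntheticSpec(rows=64, cols=64, n_parents=4, subclasses_per_parent=4,
                        clump=0.5, mix=1.0, seed=42)
pair = lf.generate_landscape(spec)
ws = lf.WindowSpec(4, units="cells")

surfaces = {}
for variant in ("g1li", "fli", "g2li"):
    s = lf.compute_surface(pair, "shdi", variant, ws)
    surfaces[variant] = s
    vals = s.values[s.valid_mask]
    print(f"shdi {variant:5s}: mean={vals.mean():.4f}  min={vals.min():.4f}  "
          f"max={vals.max():.4f}  valid cells={vals.size}")

r_fg1 = lf.surface_correlation(surfaces["fli"], surfaces["g1li"])
r_fg2 = lf.surface_correlation(surfaces["fli"], surfaces["g2li"])
r_g12 = lf.surface_correlation(surfaces["g1li"], surfaces["g2li"])
print(f"Pearson r: FLI~G1LI={r_fg1:.4f}  FLI~G2LI={r_fg2:.4f}  G1LI~G2LI={r_g12:.4f}")

out = Path(tempfile.mkdtemp(prefix="landfuse_")) / "shdi_fli_r4.asc"
lf.write_surface(surfaces["fli"], out)
print(f"wrote fused surface to {out}")
print()
print("The fused surface tracks the coarse one (high FLI~G1LI correlation)")
print("while mixing in fine-grade information, so every value is >= its")
print("coarse counterpart and <= twice it.")
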
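"""Where the fusion matters: an ecotone band, and how many bits it adds.

Builds a landscape whose middle-third rows mix subclasses uniformly (an
ecotone: maximal vertical structure) while elsewhere each coarse class is
nearly pure.  The fused patch-richness surface diverges from the plain one
inside the band, and carries several times its Huffman information volume.
"""

import numpy as np

import landfuse as lf

spec = lf.SyntheticSpec(rows=96, cols=96, n_parents=4, subclasses_per_parent=4,
                        clump=0.5, ecotone_band=(32, 64), seed=7)
pair, band = lf.generate_ecotone_landscape(spec)
ws = lf.WindowSpec(5, units="cells")

fli = lf.compute_surface(pair, "pr", "fli", ws)
g1li = lf.compute_surface(pair, "pr", "g1li", ws)

doc = lf.degree_of_changes(fli, g1li)
valid = doc.valid_mask
inside = doc.values[valid & band].mean()
outside = doc.values[valid & ~band].mean()
print(f"degree of changes (FLI-PR vs G1LI-PR): inside band {inside:.4f}, "
      f"outside {outside:.4f}")

iv_fli = lf.info_volume(fli)
iv_g1li = lf.info_volume(g1li)
cmp_ = lf.compare_info_volume(iv_fli, iv_g1li)
print(f"information volume: FLI-PR {iv_fli.total_bits} bits, "
      f"G1LI-PR {iv_g1li.total_bits} bits (ratio {cmp_.totals_ratio:.2f})")
print(f"FLI carries more bits on {100 * cmp_.ra:.1f}% of the area "
      f"(RV = {cmp_.rv:.3f})")
print()
print("Differences between fused and plain indicators concentrate where the")
print("vertical structure is largest — the ecotone band — and the fused")
print("surface needs far more bits to encode: it resolves structure the")
print("coarse indicator cannot see.")
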
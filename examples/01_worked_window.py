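"""Fuse a single 16-cell window by hand-checkable arithmetic.

The window holds two coarse classes at equal share: class 1 splits evenly
into subclasses 11 and 12, class 2 is pure subclass 21.  Only class 1 has
vertical structure, so only its component gets boosted by the fusion.
"""

import math

import numpy as np

import landfuse as lf

g2 = np.array([11] * 4 + [12] * 4 + [21] * 8).reshape(4, 4)
hierarchy = lf.infer_hierarchy_from_codes([11, 12, 21])
pair = lf.pair_rasters(None, lf.Grid(g2), hierarchy)

cells = [(r, c) for r in range(4) for c in range(4)]
comp = lf.window_composition(pair, cells)
weights = lf.fusion_weights(comp)

print("coarse-class proportions:", comp.p_parent)
print(f"H(X)   = {lf.entropy_global(comp):.6f} nats  (ln 2 = {math.log(2):.6f})")
print(f"H(Y|X) = {lf.conditional_entropy(comp):.6f} nats")
print("fusion weights w_i:", {p: round(w, 6) for p, w in weights.w.items()})

shdi = lf.shdi_components(comp)
pr = lf.pr_components(comp)
print(f"SHDI     = {shdi.total:.6f}   FLI-SHDI = {lf.fuse(shdi, weights).value:.6f}")
print(f"PR       = {pr.total:.6f}   FLI-PR   = {lf.fuse(pr, weights).value:.6f}")
print(f"child-grade SHDI = {lf.shdi_components(comp, 'child').total:.6f}")
print()
print("FLI-SHDI sits between the coarse SHDI (ln 2) and the fine-grade SHDI")
print("(1.5 ln 2): the fused value recovers part of the subclass diversity,")
print("weighted by how much vertical disorder class 1 actually realizes (0.5).")
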
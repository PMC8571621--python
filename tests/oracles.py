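"""Structurally independent brute-force oracles.

Every function here works on raw Python lists of (parent_code, child_code)
cell tuples (or nested lists for grids) with `math.log` and explicit loops —
no numpy, no shared code with the package — so agreement with the package
is evidence, not tautology.
"""

import math
from collections import Counter


def bf_entropy_global(cells):
    """H(X) by counting parent codes and summing -p ln p."""
    n = len(cells)
    counts = Counter(p for p, _ in cells)
    return -sum((k / n) * math.log(k / n) for k in counts.values())


def bf_class_conditional_entropy(cells, parent):
    """H_i' = -p(x_i) * sum_j p(y_ij|x_i) ln p(y_ij|x_i)."""
    n = len(cells)
    mine = [c for p, c in cells if p == parent]
    ni = len(mine)
    if ni == 0:
        raise KeyError(parent)
    px = ni / n
    child_counts = Counter(mine)
    inner = sum((k / ni) * math.log(k / ni) for k in child_counts.values())
    return -px * inner


def bf_conditional_entropy(cells):
    parents = {p for p, _ in cells}
    return sum(bf_class_conditional_entropy(cells, p) for p in parents)


def bf_fusion_weights(cells):
    """w_i = H_i' / ln(n_i), n_i = subclasses present in the window."""
    weights = {}
    for parent in {p for p, _ in cells}:
        subclasses = {c for p, c in cells if p == parent}
        hi = bf_class_conditional_entropy(cells, parent)
        weights[parent] = 0.0 if len(subclasses) <= 1 else hi / math.log(len(subclasses))
    return weights


def bf_shdi(cells, grade="parent"):
    n = len(cells)
    key = 0 if grade == "parent" else 1
    counts = Counter(cell[key] for cell in cells)
    return -sum((k / n) * math.log(k / n) for k in counts.values())


def bf_pr(cells, grade="parent"):
    key = 0 if grade == "parent" else 1
    return float(len({cell[key] for cell in cells}))


def bf_np(cell_values, connectivity=8):
    """Number of patches by flood fill over a dict (row, col) -> code."""
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    patches = 0
    for start, code in cell_values.items():
        if start in seen:
            continue
        patches += 1
        stack = [start]
        seen.add(start)
        while stack:
            r, c = stack.pop()
            for dr, dc in steps:
                nb = (r + dr, c + dc)
                if nb in cell_values and nb not in seen and cell_values[nb] == code:
                    seen.add(nb)
                    stack.append(nb)
    return float(patches)


def bf_np_per_class(cell_values, connectivity=8):
    """Per-class patch counts from the same flood fill."""
    per = {}
    for code in {v for v in cell_values.values()}:
        sub = {k: v for k, v in cell_values.items() if v == code}
        per[code] = bf_np(sub, connectivity)
    return per


def bf_fli(per_class_components, weights):
    """FLI_X = sum_i (1 + w_i) * LI_i with plain dict arithmetic."""
    return sum((1.0 + weights.get(p, 0.0)) * li
               for p, li in per_class_components.items())


def bf_shdi_components(cells):
    n = len(cells)
    counts = Counter(p for p, _ in cells)
    return {p: -(k / n) * math.log(k / n) for p, k in counts.items()}


def random_composition(rng, max_parents=5, max_subclasses=4, max_count=30):
    """A random non-empty cell list with >= 2 parents present."""
    n_parents = rng.integers(2, max_parents + 1)
    cells = []
    for p in range(1, n_parents + 1):
        n_sub = rng.integers(1, max_subclasses + 1)
        for j in range(1, n_sub + 1):
            # first subclass of each parent gets >=1 cell so every chosen
            # parent is genuinely present in the window
            lo = 1 if j == 1 else 0
            k = int(rng.integers(lo, max_count + 1))
            cells.extend([(p, p * 10 + j)] * k)
    return cells
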
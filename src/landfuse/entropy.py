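"""Entropy of a window's class composition and the fusion weights.

The vertical structure of a two-grade landscape is quantified with Shannon
information entropy (natural log throughout).  For a window with coarse-class
proportions p(x_i) and conditional fine-class proportions p(y_ij | x_i):

    H(X)     = -sum_i p(x_i) ln p(x_i)                      (global entropy)
    H_i'     = -p(x_i) * sum_j p(y_ij|x_i) ln p(y_ij|x_i)   (per-parent share)
    H(Y|X)   = sum_i H_i'                                    (conditional entropy)
    w_i      = H_i' / ln(n_i)                                (fusion weight)

``n_i`` is the size of parent i's subclass set, whose maximum entropy is
``ln n_i`` under a uniform subclass distribution; ``w_i`` is therefore the
realized fraction of the maximum vertical disorder under parent i, and lies
in [0, p(x_i)] when n_i counts the subclasses present in the window.  A
parent whose only subclass is itself carries no vertical information and
gets ``w_i = 0`` (the ratio is 0/0 at n_i = 1; the H_i' -> 0 limit is 0).

Which subclass count plays the role of n_i is configurable (``n_source``):
the subclasses present in the window (default — keeps the ratio a
self-contained realized/maximum comparison, consistent with every other
window-local probability), present anywhere in the dataset, or defined by
the classification scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .errors import EmptyWindowError, LookupError_
from .hierarchy import ClassHierarchy
from .raster import CategoricalRasterPair

__all__ = [
    "WindowComposition",
    "EntropyWeights",
    "window_composition",
    "composition_from_counts",
    "entropy_global",
    "conditional_entropy",
    "class_conditional_entropy",
    "fusion_weights",
    "NSource",
]

NSource = Literal["window", "dataset", "scheme"]


@dataclass(frozen=True)
class WindowComposition:
    """Cell counts and proportions of one window.

    ``child_counts`` is keyed (parent, child) so subclass identity is never
    ambiguous across parents.  All proportions are over valid cells only;
    nodata cells never enter a denominator.  ``total_valid == 0`` flags an
    empty window — a state, not an error, until an entropy is requested.
    """

    total_valid: int
    parent_counts: dict[int, int]
    child_counts: dict[tuple[int, int], int]
    p_parent: dict[int, float] = field(repr=False)
    p_child_given_parent: dict[tuple[int, int], float] = field(repr=False)

    @property
    def parents_present(self) -> list[int]:
        return sorted(self.parent_counts)

    def children_of(self, parent: int) -> list[int]:
        return sorted(c for (p, c) in self.child_counts if p == parent)


@dataclass(frozen=True)
class EntropyWeights:
    """Per-parent conditional-entropy shares H_i' (nats) and weights w_i."""

    h_prime: dict[int, float]
    n_used: dict[int, int]
    w: dict[int, float]

    def weight(self, parent: int) -> float:
        return self.w.get(parent, 0.0)


def composition_from_counts(
    child_counts: Mapping[tuple[int, int], int]
) -> WindowComposition:
    """Build a composition from (parent, child) -> cell-count pairs."""
    counts = {k: int(v) for k, v in child_counts.items() if v > 0}
    total = sum(counts.values())
    parent_counts: dict[int, int] = {}
    for (p, _), n in counts.items():
        parent_counts[p] = parent_counts.get(p, 0) + n
    if total == 0:
        return WindowComposition(0, {}, {}, {}, {})
    p_parent = {p: n / total for p, n in parent_counts.items()}
    p_cgp = {(p, c): n / parent_counts[p] for (p, c), n in counts.items()}
    return WindowComposition(total, parent_counts, counts, p_parent, p_cgp)


def window_composition(
    pair: CategoricalRasterPair, cells: Iterable[tuple[int, int]] | np.ndarray
) -> WindowComposition:
    """Tally the class composition of the given cells of a raster pair.

    ``cells`` is an iterable of (row, col) indices or an (N, 2) array; they
    must be in bounds.  Invalid (nodata / masked) cells are skipped.
    """
    idx = np.asarray(list(cells) if not isinstance(cells, np.ndarray) else cells)
    if idx.size == 0:
        return composition_from_counts({})
    rows, cols = idx[:, 0], idx[:, 1]
    keep = pair.valid_mask[rows, cols]
    g1 = pair.g1.values[rows[keep], cols[keep]]
    g2 = pair.g2.values[rows[keep], cols[keep]]
    counts: dict[tuple[int, int], int] = {}
    if g1.size:
        stacked = np.stack([g1, g2], axis=1)
        uniq, n = np.unique(stacked, axis=0, return_counts=True)
        counts = {(int(p), int(c)): int(k) for (p, c), k in zip(uniq, n)}
    return composition_from_counts(counts)


def _require_nonempty(c: WindowComposition) -> None:
    if c.total_valid == 0:
        raise EmptyWindowError("entropy undefined on an empty composition")


def entropy_global(c: WindowComposition) -> float:
    """Shannon entropy H(X) of the coarse-class proportions, in nats."""
    _require_nonempty(c)
    p = np.array(list(c.p_parent.values()))
    return float(-(p * np.log(p)).sum())


def class_conditional_entropy(c: WindowComposition, parent: int) -> float:
    """Parent i's contribution H_i' to the conditional entropy, in nats."""
    _require_nonempty(c)
    if parent not in c.parent_counts:
        raise LookupError_(f"parent {parent} absent from composition")
    q = np.array(
        [v for (p, _), v in c.p_child_given_parent.items() if p == parent]
    )
    return float(-c.p_parent[parent] * (q * np.log(q)).sum())


def conditional_entropy(c: WindowComposition) -> float:
    """Conditional entropy H(Y|X) of fine classes given coarse, in nats."""
    _require_nonempty(c)
    return float(sum(class_conditional_entropy(c, p) for p in c.parent_counts))


def fusion_weights(
    c: WindowComposition,
    hierarchy: ClassHierarchy | None = None,
    n_source: NSource = "window",
    dataset_n: Mapping[int, int] | None = None,
) -> EntropyWeights:
    """Entropy-derived fusion weight w_i = H_i' / ln(n_i) per parent present.

    Parameters
    ----------
    n_source
        Where n_i comes from: ``window`` — subclasses of parent i present in
        this window; ``dataset`` — present anywhere in the dataset (supply
        ``dataset_n``); ``scheme`` — defined by the classification scheme
        (supply ``hierarchy``).
    """
    _require_nonempty(c)
    h_prime: dict[int, float] = {}
    n_used: dict[int, int] = {}
    w: dict[int, float] = {}
    for parent in c.parents_present:
        hp = class_conditional_entropy(c, parent)
        if n_source == "window":
            n_i = len(c.children_of(parent))
        elif n_source == "dataset":
            if dataset_n is None or parent not in dataset_n:
                raise LookupError_(
                    f"dataset subclass count missing for parent {parent}"
                )
            n_i = int(dataset_n[parent])
        elif n_source == "scheme":
            if hierarchy is None or parent not in hierarchy.scheme_n:
                raise LookupError_(
                    f"scheme subclass count missing for parent {parent}"
                )
            n_i = hierarchy.scheme_n[parent]
        else:
            raise ValueError(f"unknown n_source {n_source!r}")
        h_prime[parent] = hp
        n_used[parent] = n_i
        w[parent] = 0.0 if n_i <= 1 else float(hp / np.log(n_i))
    return EntropyWeights(h_prime, n_used, w)
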
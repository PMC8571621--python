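"""Two-grade land-cover class taxonomy.

A hierarchical land-use/land-cover (LULC) classification assigns every
fine-grade (second-grade, G2) class code to exactly one coarse-grade
(first-grade, G1) parent code.  The coarse codes form the set X, the fine
codes the set Y, and the fine codes under parent ``i`` the subclass set
``Y_i`` with ``n_i = |Y_i|`` classes defined by the scheme.  This vertical
subordination is the structure the entropy weights quantify.

Codes are plain integers; class names are presentation metadata and never
enter computation.  Hierarchies deeper than two grades are out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import HierarchyError, LookupError_

__all__ = [
    "ClassHierarchy",
    "build_hierarchy",
    "infer_hierarchy_from_codes",
    "parent_of",
    "read_hierarchy_csv",
]


@dataclass(frozen=True)
class ClassHierarchy:
    """Validated child→parent mapping of a two-grade classification scheme.

    Attributes
    ----------
    parents : frozenset[int]
        Coarse-grade codes (the set X).
    children : frozenset[int]
        Fine-grade codes (the set Y).
    child_to_parent : dict[int, int]
        Total mapping; every child has exactly one parent.
    subclass_sets : dict[int, frozenset[int]]
        Per-parent subclass set Y_i; these partition ``children``.
    scheme_n : dict[int, int]
        Per-parent subclass count n_i as defined by the scheme.
    """

    parents: frozenset[int]
    children: frozenset[int]
    child_to_parent: dict[int, int]
    subclass_sets: dict[int, frozenset[int]] = field(repr=False)
    scheme_n: dict[int, int] = field(repr=False)

    def to_table(self) -> list[tuple[int, int]]:
        """Flatten back to (child, parent) rows, sorted by child code."""
        return sorted(self.child_to_parent.items())


def build_hierarchy(mapping_table: Iterable[tuple[int, int]]) -> ClassHierarchy:
    """Build and validate a :class:`ClassHierarchy` from (child, parent) rows.

    Duplicate rows are tolerated; a child appearing under two different
    parents is a contradiction and raises :class:`HierarchyError`, as does
    an empty table.
    """
    child_to_parent: dict[int, int] = {}
    for child, parent in mapping_table:
        child = int(child)
        parent = int(parent)
        prev = child_to_parent.get(child)
        if prev is not None and prev != parent:
            raise HierarchyError(
                f"child code {child} mapped to both parent {prev} and {parent}"
            )
        child_to_parent[child] = parent
    if not child_to_parent:
        raise HierarchyError("empty hierarchy mapping table")

    subclass_sets: dict[int, set[int]] = {}
    for child, parent in child_to_parent.items():
        subclass_sets.setdefault(parent, set()).add(child)
    frozen = {p: frozenset(s) for p, s in subclass_sets.items()}
    return ClassHierarchy(
        parents=frozenset(frozen),
        children=frozenset(child_to_parent),
        child_to_parent=dict(child_to_parent),
        subclass_sets=frozen,
        scheme_n={p: len(s) for p, s in frozen.items()},
    )


def infer_hierarchy_from_codes(child_codes: Iterable[int]) -> ClassHierarchy:
    """Infer the hierarchy from fine-grade codes under the decimal-prefix rule.

    Many national LULC schemes encode subordination numerically: subclass 23
    belongs to class 2, subclass 123 to class 12 — the parent is the child
    integer-divided by 10.  Every code must be >= 10 for the rule to apply.
    An explicit mapping table always takes precedence over this convenience.
    """
    codes = sorted({int(c) for c in child_codes})
    if not codes:
        raise HierarchyError("no child codes supplied")
    bad = [c for c in codes if c < 10]
    if bad:
        raise HierarchyError(
            f"decimal-prefix rule needs codes >= 10, got {bad[:5]}"
        )
    return build_hierarchy((c, c // 10) for c in codes)


def parent_of(h: ClassHierarchy, child: int) -> int:
    """Return the unique parent of ``child``; unknown codes raise."""
    try:
        return h.child_to_parent[int(child)]
    except KeyError:
        raise LookupError_(f"child code {child} not in hierarchy") from None


def read_hierarchy_csv(path: str | Path) -> ClassHierarchy:
    """Read a two-column ``child,parent`` CSV (header required)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"child", "parent"} <= set(
            name.strip().lower() for name in reader.fieldnames
        ):
            raise HierarchyError(
                f"{path}: expected CSV header with 'child' and 'parent' columns"
            )
        rows = [
            (int(row["child"]), int(row["parent"]))
            for row in (
                {k.strip().lower(): v for k, v in r.items()} for r in reader
            )
        ]
    return build_hierarchy(rows)


def hierarchy_names(mapping: Mapping[int, str]) -> dict[int, str]:
    """Optional human-readable names keyed by code; metadata only."""
    return {int(k): str(v) for k, v in mapping.items()}
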
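"""Static geometry of the symmetric binary airway tree.

The lung is idealized as a symmetric dichotomously branching tree of
cylindrical airways: generation 0 is the trachea and generation ``G-1``
(23 by default) the alveolar level, so a full tree has ``2**G - 1``
airways and ``2**(G-1)`` terminal alveolar units.

Airways are addressed with 1-based heap indices: airway ``k`` has parent
``k // 2`` and children ``2k`` and ``2k + 1``, and its generation is
``floor(log2(k))``.  Only per-generation aggregate geometry is stored;
per-airway quantities are derived from the index arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "GenerationDims",
    "AirwayTree",
    "build_tree",
    "load_default_tree",
    "total_surface_area",
    "fill_time",
    "accessible_alveoli",
]

DEFAULT_TABLE = "weibel_model_a.csv"


class GeometryError(ValueError):
    """Raised for malformed geometry tables or invalid airway indices."""


@dataclass(frozen=True)
class GenerationDims:
    """Idealized cylinder dimensions shared by every airway of a generation."""

    generation: int
    diameter_mm: float
    length_mm: float

    @property
    def count(self) -> int:
        """Number of airways in this generation (``2**generation``)."""
        return 1 << self.generation

    @property
    def airway_volume_mm3(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2 * self.length_mm

    @property
    def airway_surface_mm2(self) -> float:
        return math.pi * self.diameter_mm * self.length_mm


class AirwayTree:
    """Immutable symmetric binary airway tree with heap indexing.

    Parameters
    ----------
    dims
        One :class:`GenerationDims` per generation ``0..G-1``, in order.
    """

    def __init__(self, dims: Sequence[GenerationDims]):
        if not dims:
            raise GeometryError("geometry table is empty")
        for g, d in enumerate(dims):
            if d.generation != g:
                raise GeometryError(
                    f"geometry table row {g} has generation {d.generation}; "
                    f"expected a contiguous run starting at 0"
                )
            if not (d.diameter_mm > 0 and d.length_mm > 0):
                raise GeometryError(
                    f"non-positive dimension in generation {g}: "
                    f"diameter={d.diameter_mm}, length={d.length_mm}"
                )
        self.dims: tuple[GenerationDims, ...] = tuple(dims)
        self.n_generations = len(dims)
        self.diameter_mm = np.array([d.diameter_mm for d in dims])
        self.length_mm = np.array([d.length_mm for d in dims])
        self.airway_volume_mm3 = np.array([d.airway_volume_mm3 for d in dims])
        self.airway_surface_mm2 = np.array([d.airway_surface_mm2 for d in dims])
        self.counts = 1 << np.arange(self.n_generations, dtype=np.int64)

    # -- index arithmetic ---------------------------------------------------

    @property
    def total_airways(self) -> int:
        return (1 << self.n_generations) - 1

    @property
    def deepest_generation(self) -> int:
        return self.n_generations - 1

    @property
    def n_alveoli(self) -> int:
        """One alveolar unit per deepest-generation (leaf) airway."""
        return 1 << self.deepest_generation

    @property
    def leaf_lo(self) -> int:
        return 1 << self.deepest_generation

    def validate_index(self, k: int) -> None:
        if not (1 <= int(k) <= self.total_airways):
            raise GeometryError(
                f"airway index {k} outside 1..{self.total_airways}"
            )

    def generation_of(self, idx):
        """Generation of airway index/indices (``floor(log2 k)``)."""
        arr = np.asarray(idx, dtype=np.int64)
        if arr.size and (arr.min() < 1 or arr.max() > self.total_airways):
            bad = arr[(arr < 1) | (arr > self.total_airways)][0]
            raise GeometryError(
                f"airway index {bad} outside 1..{self.total_airways}"
            )
        gen = np.floor(np.log2(arr)).astype(np.int64)
        return gen if arr.shape else int(gen)

    def leaf_spans(self, idx):
        """Half-open leaf-index intervals ``[lo, hi)`` covered by subtrees.

        The leaves below airway ``k`` of generation ``g`` occupy the heap
        index range ``[k << (G-1-g), (k+1) << (G-1-g))``.
        """
        arr = np.atleast_1d(np.asarray(idx, dtype=np.int64))
        shift = self.deepest_generation - self.generation_of(arr)
        lo = arr << shift
        hi = (arr + 1) << shift
        return lo, hi

    def ancestors(self, k: int) -> list[int]:
        self.validate_index(k)
        out = []
        k = int(k) // 2
        while k >= 1:
            out.append(k)
            k //= 2
        return out

    # -- aggregate queries --------------------------------------------------

    def total_surface_area(self) -> float:
        """Exact summed luminal surface over all airways, in mm^2."""
        return float(np.sum(self.counts * self.airway_surface_mm2))

    def total_airway_volume(self) -> float:
        return float(np.sum(self.counts * self.airway_volume_mm3))

    def fill_time(self, generation: int, v_c: float) -> float:
        """Months for one airway of ``generation`` to fill at mucus rate ``v_c``.

        ``v_c`` is the mucus volume growth rate in mm^3/month.
        """
        if v_c <= 0:
            raise GeometryError(f"v_c must be positive, got {v_c}")
        if not (0 <= generation < self.n_generations):
            raise GeometryError(
                f"generation {generation} outside 0..{self.deepest_generation}"
            )
        return float(self.airway_volume_mm3[generation] / v_c)

    def accessible_alveoli(self, blocked: Iterable[int]) -> int:
        """Number of leaves whose root-to-leaf path avoids every blocked airway.

        ``blocked`` airways (and everything distal to them) are unreachable;
        the count is computed exactly via a union of leaf-index intervals.
        """
        blocked = np.asarray(sorted(set(int(b) for b in blocked)), dtype=np.int64)
        if blocked.size == 0:
            return self.n_alveoli
        lo, hi = self.leaf_spans(blocked)
        starts, ends = merge_intervals(lo, hi)
        return self.n_alveoli - int(np.sum(ends - starts))


def merge_intervals(starts, ends):
    """Merge half-open intervals into a disjoint, sorted set (touching merge)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    running = np.maximum.accumulate(e)
    new_group = np.empty(s.shape, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] > running[:-1]
    group_start = np.flatnonzero(new_group)
    merged_s = s[group_start]
    merged_e = running[np.append(group_start[1:] - 1, s.size - 1)]
    return merged_s, merged_e


def build_tree(geometry_table: pd.DataFrame) -> AirwayTree:
    """Build an :class:`AirwayTree` from a per-generation dimension table.

    The table needs columns ``generation``, ``diameter_mm`` and ``length_mm``
    with one row per generation ``0..G-1``.
    """
    required = {"generation", "diameter_mm", "length_mm"}
    missing = required - set(geometry_table.columns)
    if missing:
        raise GeometryError(f"geometry table lacks columns: {sorted(missing)}")
    table = geometry_table.sort_values("generation").reset_index(drop=True)
    gens = table["generation"].to_numpy()
    expected = np.arange(len(table))
    if not np.array_equal(gens, expected):
        missing_rows = sorted(set(expected) - set(gens))
        raise GeometryError(
            f"geometry table must cover generations {expected[0]}..{expected[-1]} "
            f"exactly once; missing or duplicated rows near generations {missing_rows or list(gens)}"
        )
    dims = [
        GenerationDims(int(r.generation), float(r.diameter_mm), float(r.length_mm))
        for r in table.itertuples()
    ]
    return AirwayTree(dims)


def load_default_tree() -> AirwayTree:
    """The vendored 24-row Weibel-style adult-lung tree."""
    with resources.files("cflung.data").joinpath(DEFAULT_TABLE).open() as fh:
        table = pd.read_csv(fh, comment="#")
    return build_tree(table)


# Module-level functional aliases matching the operation vocabulary.

def total_surface_area(tree: AirwayTree) -> float:
    return tree.total_surface_area()


def fill_time(tree: AirwayTree, generation: int, v_c: float) -> float:
    return tree.fill_time(generation, v_c)


def accessible_alveoli(tree: AirwayTree, blocked: Iterable[int]) -> int:
    return tree.accessible_alveoli(blocked)
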
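"""Factorial design layout: nutrition arms, sampling ages and the array map.

The study design crosses three lactation-period nutrition arms with five
sampling ages.  Each (arm, age) pair is a *design cell*; expression for a
cell is measured on replicate arrays hybridized with a single RNA pool.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class NutritionArm(str, enum.Enum):
    """Nutrition condition applied from birth to weaning."""

    CONTROL = "CONTROL"
    LUN = "LUN"  # lactation under-nutrition (dam food-restricted to 50%)
    LON = "LON"  # lactation over-nutrition (litter of 4, dam on high-fat diet)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ARMS: tuple[NutritionArm, ...] = (
    NutritionArm.CONTROL,
    NutritionArm.LUN,
    NutritionArm.LON,
)

#: Ages (days) at which tissue/phenotypes are sampled.
AGES: tuple[int, ...] = (5, 10, 21, 56, 112)

Cell = tuple[NutritionArm, int]


def design_cells() -> list[Cell]:
    """The 15 (arm, age) design cells in canonical order (arm-major)."""
    return [(arm, age) for arm in ARMS for age in AGES]


def cell_label(cell: Cell) -> str:
    arm, age = cell
    return f"{arm.value}_d{age:03d}"


def parse_cell_label(label: str) -> Cell:
    arm_s, age_s = label.rsplit("_d", 1)
    return NutritionArm(arm_s), int(age_s)


def array_id(cell: Cell, replicate: int) -> str:
    return f"{cell_label(cell)}_r{replicate}"


class DesignError(ValueError):
    """Raised for malformed or inconsistent design specifications."""


@dataclass
class DesignSpec:
    """Maps array ids to design cells.

    Parameters
    ----------
    cells
        Ordered list of design cells (defaults to the full 15-cell layout).
    array_map
        Mapping from array id to the cell it measures.
    """

    cells: list[Cell] = field(default_factory=design_cells)
    array_map: dict[str, Cell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.cells:
            if c in seen:
                raise DesignError(f"duplicate design cell {c}")
            seen.add(c)
        for aid, cell in self.array_map.items():
            if cell not in seen:
                raise DesignError(f"array {aid!r} maps to unknown cell {cell}")
        if self.array_map:
            empty = [c for c in self.cells if not self.arrays_for_cell(c)]
            if empty:
                raise DesignError(f"design cells without arrays: {empty}")

    @classmethod
    def default(cls, replicates: int = 3) -> "DesignSpec":
        """The 15-cell layout with ``replicates`` arrays per cell."""
        cells = design_cells()
        amap = {
            array_id(c, r): c for c in cells for r in range(1, replicates + 1)
        }
        return cls(cells=cells, array_map=amap)

    def arrays_for_cell(self, cell: Cell) -> list[str]:
        return [a for a, c in self.array_map.items() if c == cell]

    @property
    def array_ids(self) -> list[str]:
        return list(self.array_map)

    def replicate_counts(self) -> dict[Cell, int]:
        counts: dict[Cell, int] = {c: 0 for c in self.cells}
        for cell in self.array_map.values():
            counts[cell] += 1
        return counts
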
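"""The genes × arrays expression container shared by every pipeline stage."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Cell, DesignSpec


@dataclass
class ExpressionMatrix:
    """Linear-scale signals for genes (rows) across arrays (columns).

    ``values`` is indexed by gene id; every column must be mapped to a
    design cell by ``design.array_map``.
    """

    values: pd.DataFrame
    design: DesignSpec

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene ids: {dup}")
        unmapped = [c for c in self.values.columns if c not in self.design.array_map]
        if unmapped:
            raise ValueError(f"arrays not mapped to a design cell: {unmapped}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def cell_of(self, array: str) -> Cell:
        return self.design.array_map[array]

    def arrays_for_cell(self, cell: Cell) -> list[str]:
        return [a for a in self.values.columns if self.design.array_map[a] == cell]

    def cell_means(self) -> pd.DataFrame:
        """Per-gene mean of replicate arrays for every design cell.

        Columns follow ``design.cells`` order and are labelled with cell
        labels.
        """
        from .design import cell_label

        cols = {}
        for cell in self.design.cells:
            arrays = self.arrays_for_cell(cell)
            if not arrays:
                continue
            cols[cell_label(cell)] = self.values[arrays].mean(axis=1)
        return pd.DataFrame(cols)

    def subset(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.design)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.design)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.design.array_map == other.design.array_map
        )
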
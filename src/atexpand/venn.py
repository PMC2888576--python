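"""Directional differential-expression sets and their intersection cascade.

The biological filtering strategy: five directional comparisons (A, B over
the neonatal under-nutrition contrast; C, D, E over the adult chow-to-high-
fat contrast within each arm), intersected as F = A∩B, G = C∩D∩E and the
final adiposity-tracking set F∩G.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .design import Cell, NutritionArm
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "ComparisonSpec",
    "GeneSet",
    "VennResult",
    "default_comparisons",
    "differential_set",
    "venn_cascade",
    "run_venn",
]


class Direction(str, Enum):
    UP = "UP"      # cell_hi mean above cell_lo mean
    DOWN = "DOWN"
    BOTH = "BOTH"


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    cell_hi: Cell
    cell_lo: Cell
    direction: Direction = Direction.UP
    min_fold: float = 1.6
    alpha: float = 0.01
    equal_var: bool = True

    def __post_init__(self) -> None:
        if self.cell_hi == self.cell_lo:
            raise ValueError("cell_hi and cell_lo must differ")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def default_comparisons(
    alpha: float = 0.01, min_fold: float = 1.6
) -> list[ComparisonSpec]:
    """The five standard comparisons.

    A/B contrast control against under-nutrition at days 5 and 10 (the
    over-nutrition arm is excluded to avoid pure high-fat-diet effects);
    C/D/E contrast day 112 (high-fat) against day 56 (chow) within each arm.
    """
    C, U, O = NutritionArm.CONTROL, NutritionArm.LUN, NutritionArm.LON
    kw = dict(direction=Direction.UP, min_fold=min_fold, alpha=alpha)
    return [
        ComparisonSpec("A", (C, 5), (U, 5), **kw),
        ComparisonSpec("B", (C, 10), (U, 10), **kw),
        ComparisonSpec("C", (C, 112), (C, 56), **kw),
        ComparisonSpec("D", (U, 112), (U, 56), **kw),
        ComparisonSpec("E", (O, 112), (O, 56), **kw),
    ]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def differential_set(
    matrix: ExpressionMatrix, spec: ComparisonSpec
) -> GeneSet:
    """Genes significantly and directionally different between two cells.

    Inclusion requires a two-tailed t-test p below ``alpha`` on the
    replicate arrays, a fold change of at least ``min_fold`` in the
    requested direction, and the directional mean ordering.  A zero
    denominator mean with a positive numerator counts as passing the fold
    criterion (logged).
    """
    hi_arrays = matrix.arrays_for_cell(spec.cell_hi)
    lo_arrays = matrix.arrays_for_cell(spec.cell_lo)
    if len(hi_arrays) < 2 or len(lo_arrays) < 2:
        raise ValueError(
            f"comparison {spec.name}: both cells need >=2 replicate arrays"
        )
    hi = matrix.values[hi_arrays].to_numpy(float)
    lo = matrix.values[lo_arrays].to_numpy(float)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*[Pp]recision loss.*")
        p = stats.ttest_ind(hi, lo, axis=1, equal_var=spec.equal_var).pvalue
    m_hi, m_lo = hi.mean(axis=1), lo.mean(axis=1)

    def _dir_ok(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(den > 0, num / den, np.inf)
        zero_den = (den <= 0) & (num > 0)
        if np.any(zero_den):
            log.warning(
                "comparison %s: %d gene(s) with nonpositive denominator mean "
                "treated as passing fold", spec.name, int(zero_den.sum()),
            )
        return (num > den) & (fold >= spec.min_fold)

    if spec.direction is Direction.UP:
        ok = _dir_ok(m_hi, m_lo)
    elif spec.direction is Direction.DOWN:
        ok = _dir_ok(m_lo, m_hi)
    else:
        ok = _dir_ok(m_hi, m_lo) | _dir_ok(m_lo, m_hi)
    include = ok & (p < spec.alpha)
    return GeneSet(spec.name, frozenset(matrix.values.index[include]))


@dataclass
class VennResult:
    """Per-comparison sets, the intersections and per-gene provenance."""

    sets: dict[str, GeneSet]
    F: GeneSet
    G: GeneSet
    ate: GeneSet
    provenance: pd.DataFrame = field(repr=False)  # genes x comparisons bool

    @property
    def cardinalities(self) -> dict[str, int]:
        out = {name: len(s) for name, s in self.sets.items()}
        out.update({"F": len(self.F), "G": len(self.G), "ATE": len(self.ate)})
        return out


def venn_cascade(sets: dict[str, GeneSet] | list[GeneSet]) -> VennResult:
    """Intersect the five comparison sets: F = A∩B, G = C∩D∩E, final = F∩G."""
    if isinstance(sets, list):
        sets = {s.name: s for s in sets}
    missing = [n for n in "ABCDE" if n not in sets]
    if missing:
        raise ValueError(f"missing comparison set(s): {missing}")
    F = frozenset(sets["A"].genes & sets["B"].genes)
    G = frozenset(sets["C"].genes & sets["D"].genes & sets["E"].genes)
    ate = F & G
    universe = sorted(set().union(*(s.genes for s in sets.values())))
    prov = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in sets.items()},
        index=pd.Index(universe, name="gene_id"),
    )
    return VennResult(
        sets=dict(sets),
        F=GeneSet("F", F),
        G=GeneSet("G", G),
        ate=GeneSet("ATE", frozenset(ate)),
        provenance=prov,
    )


def run_venn(
    matrix: ExpressionMatrix,
    comparisons: list[ComparisonSpec] | None = None,
) -> VennResult:
    """Convenience wrapper: build all five sets and cascade them."""
    comparisons = comparisons or default_comparisons()
    return venn_cascade([differential_set(matrix, c) for c in comparisons])
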
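"""Quantile normalization and the three-criterion gene-selection filter."""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "FilterCriteria",
    "FilterReport",
    "quantile_normalize",
    "filter_genes",
    "benjamini_hochberg",
    "pairwise_cell_pvalues",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common reference distribution.

    The reference is the row-wise mean of the per-array sorted signal
    vectors; after normalization every column holds the identical sorted
    multiset.  Tied values within a column receive the mean of the
    reference values their positions span.  Gene order is preserved and
    the operation is idempotent.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    bad = [
        col for j, col in enumerate(matrix.values.columns)
        if not np.all(np.isfinite(X[:, j]))
    ]
    if bad:
        raise ValueError(f"non-finite signals in array(s): {bad}")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref
        col = pd.Series(out[:, j]).groupby(X[:, j]).transform("mean")
        out[:, j] = col.to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.design)


def _looks_normalized(matrix: ExpressionMatrix, rtol: float = 1e-9) -> bool:
    X = matrix.values.to_numpy(dtype=float)
    s0 = np.sort(X[:, 0])
    return all(
        np.allclose(np.sort(X[:, j]), s0, rtol=rtol) for j in range(1, X.shape[1])
    )


@dataclass(frozen=True)
class FilterCriteria:
    """Selection thresholds for the three-criterion gene filter.

    Defaults mirror the study: group signal >= 5000 in at least 3 of the 15
    cells, a >= 1.6-fold spread between the extreme group means, and a
    two-tailed t-test P < 0.01 for at least one pairwise cell comparison.
    """

    min_signal: float = 5000.0
    min_groups_at_signal: int = 3
    min_fold: float = 1.6
    alpha: float = 0.01
    signal_on_any_array: bool = False  # alternative reading of criterion 1
    equal_var: bool = True             # pooled-variance t-test (Welch if False)

    def __post_init__(self) -> None:
        if self.min_signal <= 0:
            raise ValueError("min_signal must be positive")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FilterReport:
    n_input: int
    n_pass_signal: int
    n_pass_fold: int
    n_pass_ttest: int
    n_pass_all: int
    passing: list[str]
    mask: pd.DataFrame = field(repr=False)  # per-gene booleans per criterion

    def __post_init__(self) -> None:
        per = min(self.n_pass_signal, self.n_pass_fold, self.n_pass_ttest)
        assert self.n_pass_all <= per <= self.n_input


def pairwise_cell_pvalues(
    matrix: ExpressionMatrix, equal_var: bool = True
) -> pd.DataFrame:
    """Two-tailed two-sample t-test p-values per gene for every cell pair.

    Returns genes x pairs; pairs involving a cell with fewer than two
    replicate arrays are skipped with a warning.
    """
    cells = matrix.design.cells
    groups = {c: matrix.values[matrix.arrays_for_cell(c)].to_numpy(float)
              for c in cells}
    thin = [c for c, g in groups.items() if g.shape[1] < 2]
    if thin:
        warnings.warn(
            f"cells with <2 replicate arrays skipped in t-tests: {thin}",
            UserWarning, stacklevel=2,
        )
    cols = {}
    with warnings.catch_warnings():
        # near-identical replicate values trigger scipy's precision-loss
        # warning; for this screen a p-value near 1 is the right answer
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*[Pp]recision loss.*")
        for a, b in itertools.combinations(cells, 2):
            if a in thin or b in thin:
                continue
            res = stats.ttest_ind(groups[a], groups[b], axis=1, equal_var=equal_var)
            name = f"{a[0].value}_d{a[1]}|{b[0].value}_d{b[1]}"
            cols[name] = res.pvalue
    return pd.DataFrame(cols, index=matrix.values.index)


def filter_genes(
    matrix: ExpressionMatrix, crit: FilterCriteria | None = None
) -> FilterReport:
    """Apply the three-criterion selection filter to a normalized matrix.

    A gene passes iff (1) its group signal reaches ``min_signal`` in at
    least ``min_groups_at_signal`` cells, (2) the ratio of the largest to
    the smallest group mean is at least ``min_fold`` and (3) at least one
    pairwise cell comparison is significant at ``alpha``.
    """
    crit = crit or FilterCriteria()
    if not _looks_normalized(matrix):
        warnings.warn(
            "matrix does not look quantile-normalized; filtering anyway",
            UserWarning, stacklevel=2,
        )
    means = matrix.cell_means().to_numpy(float)  # genes x cells

    if crit.signal_on_any_array:
        per_cell_hits = np.zeros_like(means, dtype=bool)
        for k, cell in enumerate(matrix.design.cells):
            arrs = matrix.values[matrix.arrays_for_cell(cell)].to_numpy(float)
            per_cell_hits[:, k] = (arrs >= crit.min_signal).any(axis=1)
        pass_signal = per_cell_hits.sum(axis=1) >= crit.min_groups_at_signal
    else:
        pass_signal = (means >= crit.min_signal).sum(axis=1) >= crit.min_groups_at_signal

    hi = means.max(axis=1)
    lo = means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    if np.any(lo <= 0):
        warnings.warn(
            "nonpositive group means encountered; fold treated as infinite "
            "where the maximum is positive", UserWarning, stacklevel=2,
        )
    pass_fold = fold >= crit.min_fold

    pvals = pairwise_cell_pvalues(matrix, equal_var=crit.equal_var)
    pass_ttest = (pvals.to_numpy(float) < crit.alpha).any(axis=1) if pvals.shape[1] else (
        np.zeros(len(means), dtype=bool)
    )

    pass_all = pass_signal & pass_fold & pass_ttest
    mask = pd.DataFrame(
        {"signal": pass_signal, "fold": pass_fold, "ttest": pass_ttest,
         "all": pass_all},
        index=matrix.values.index,
    )
    return FilterReport(
        n_input=len(mask),
        n_pass_signal=int(pass_signal.sum()),
        n_pass_fold=int(pass_fold.sum()),
        n_pass_ttest=int(pass_ttest.sum()),
        n_pass_all=int(pass_all.sum()),
        passing=list(mask.index[pass_all]),
        mask=mask,
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional post-hoc report; not used by default)."""
    p = np.asarray(pvalues, dtype=float)
    return stats.false_discovery_control(p, method="bh")
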
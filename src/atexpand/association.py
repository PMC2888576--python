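"""Correlation, cumulative-frequency and summary-statistic testing.

Implements the statistical toolkit used to relate gene expression to
adiposity phenotypes: Pearson correlation with the t-transformation
p-value, pairwise-complete correlation matrices with significance masks,
percent relative cumulative frequency (PRCF) curves, variance explained,
t-tests from group summaries and one-way ANOVA with a compact letter
display.
"""
from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson",
    "pearson_pvalue",
    "CorrelationReport",
    "correlation_matrix",
    "PRCFCurve",
    "prcf",
    "variance_explained",
    "t_from_summary",
    "anova_oneway",
    "AnovaResult",
    "compact_letter_display",
]


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-tailed p-value from the t transformation.

    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` referred to the t distribution with
    ``n-2`` degrees of freedom.  Requires at least 3 paired finite values
    and nonzero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired finite values, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed significance of a correlation coefficient alone.

    Same t transformation as :func:`pearson`, for when only (r, n) are
    available (e.g. printed coefficients).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


@dataclass
class CorrelationReport:
    """Symmetric pairwise-complete Pearson matrix with p-values and n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        """Boolean mask of off-diagonal significance at ``alpha``."""
        mask = self.p < alpha
        np.fill_diagonal(mask.values, False)
        return mask


def correlation_matrix(variables: pd.DataFrame) -> CorrelationReport:
    """All-pairs Pearson correlation of the table's columns.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    rows (or zero variance) are flagged absent as NaN.
    """
    cols = list(variables.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(variables))
    for i, j in itertools.combinations(range(k), 2):
        xi = variables[cols[i]].to_numpy(float)
        xj = variables[cols[j]].to_numpy(float)
        try:
            rij, pij, nij = pearson(xi, xj)
        except ValueError:
            rij, pij, nij = np.nan, np.nan, 0
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
        n[i, j] = n[j, i] = nij
    idx = pd.Index(cols)
    return CorrelationReport(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


@dataclass(frozen=True)
class PRCFCurve:
    """Sorted values against cumulative percent (right-continuous ECDF)."""

    values: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.values) >= 0)
        assert np.all(np.diff(self.percent) >= 0)
        assert self.percent[-1] == 100.0


def prcf(values, bins: int | None = None) -> PRCFCurve:
    """Percent relative cumulative frequency of a sample.

    Exact empirical CDF by default: sorted values with percent
    ``100*i/n``.  With ``bins`` the curve is reported at fixed-width bin
    edges instead (plotting parity with binned-frequency presentations).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("prcf requires at least one finite value")
    v = np.sort(v)
    if bins is None:
        pct = 100.0 * np.arange(1, v.size + 1) / v.size
        return PRCFCurve(v, pct)
    counts, edges = np.histogram(v, bins=bins)
    pct = 100.0 * np.cumsum(counts) / v.size
    return PRCFCurve(edges[1:], pct)


def variance_explained(r: float) -> float:
    """Percent of variance associated with a correlation: ``100 * r**2``."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return 100.0 * r * r


def t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test from group summaries.

    Returns ``(t, df, p)``.  ``variant`` selects the classical
    pooled-variance test or Welch's unequal-variance test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        if mean1 == mean2:
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compact_letter_display(
    names: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Shared-letter grouping over a pairwise significance relation.

    Insert-and-absorb: start from one letter covering all groups; for every
    significantly different pair split each letter containing both; absorb
    letters that become subsets of others.  Letters are assigned in the
    order the groups were given.
    """
    letters: list[set[str]] = [set(names)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for L in [L for L in letters if a in L and b in L]:
            letters.remove(L)
            for drop in (a, b):
                cand = L - {drop}
                if cand and not any(cand <= M for M in letters):
                    letters.append(cand)
    # deterministic ordering: by first member position
    pos = {g: i for i, g in enumerate(names)}
    letters.sort(key=lambda L: min(pos[g] for g in L))
    out = {g: "" for g in names}
    for ch, L in zip(string.ascii_lowercase, letters):
        for g in names:
            if g in L:
                out[g] += ch
    return out


@dataclass
class AnovaResult:
    F: float
    p: float
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]


def anova_oneway(
    groups: dict[str, np.ndarray], alpha: float = 0.01
) -> AnovaResult:
    """One-way ANOVA with post-hoc pairwise t-tests and letter grouping.

    Groups sharing a letter are not significantly different at ``alpha`` by
    a two-tailed pooled-variance t-test.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    if all(np.std(v) == 0 for v in arrays.values()) and (
        len({v[0] for v in arrays.values()}) == 1
    ):
        # all observations identical: F is 0/0; report the degenerate case
        names = list(arrays)
        pairs = {p: 1.0 for p in itertools.combinations(names, 2)}
        return AnovaResult(0.0, 1.0, pairs, {g: "a" for g in names})
    F, p = stats.f_oneway(*arrays.values())
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(arrays, 2):
        pairwise[(a, b)] = stats.ttest_ind(
            arrays[a], arrays[b], equal_var=True
        ).pvalue
    sig = {pair: pv < alpha for pair, pv in pairwise.items()}
    letters = compact_letter_display(list(arrays), sig)
    return AnovaResult(float(F), float(p), pairwise, letters)
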
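"""Correlation / PRCF / summary-statistic testing oracles and examples."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import betainc

from atexpand import (
    anova_oneway,
    correlation_matrix,
    pearson,
    prcf,
    t_from_summary,
    variance_explained,
)
from atexpand.association import compact_letter_display


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------

def test_perfect_correlation():
    x = np.arange(10.0)
    r, p, n = pearson(x, x)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p == pytest.approx(0.0, abs=1e-30)
    assert n == 10


def test_printed_significance_threshold():
    # r = 0.3 at n = 83 sits at the study's P = 0.01 boundary
    rng = np.random.default_rng(0)
    x = rng.normal(size=83)
    # construct data with exactly r = 0.3 via orthogonalization
    y0 = rng.normal(size=83)
    y0 -= y0.mean()
    x_c = x - x.mean()
    y_orth = y0 - (y0 @ x_c) / (x_c @ x_c) * x_c
    y = 0.3 * x_c / np.std(x_c) + np.sqrt(1 - 0.09) * y_orth / np.std(y_orth)
    r, p, n = pearson(x, y)
    assert r == pytest.approx(0.3, abs=1e-12)
    assert p <= 0.01


def test_printed_extreme_pvalue_order_of_magnitude():
    # r = 0.76, n = 249 printed as P = 2.2e-48
    r = 0.76
    n = 249
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(t, n - 2)
    assert abs(np.log10(p) - np.log10(2.2e-48)) <= 1


def test_agrees_with_incomplete_beta_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        r, p, _ = pearson(x, y)
        df = n - 2
        t2 = r * r * df / (1 - r * r)
        oracle = betainc(df / 2.0, 0.5, df / (df + t2))
        assert p == pytest.approx(oracle, abs=1e-10)


def test_permutation_rank_ordering_small_n():
    """The parametric p preserves the ordering given by an exhaustive
    permutation test on n = 7 samples."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=7)
    datasets = [rng.normal(size=7) + k * x for k in (0.0, 0.5, 1.0, 2.0)]

    def perm_p(y):
        robs = abs(np.corrcoef(x, y)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            hits += abs(np.corrcoef(x, perm)[0, 1]) >= robs - 1e-12
        return hits / total

    parametric = [pearson(x, y)[1] for y in datasets]
    permutation = [perm_p(y) for y in datasets]
    assert np.argsort(parametric).tolist() == np.argsort(permutation).tolist()


def test_pearson_errors():
    with pytest.raises(ValueError, match="at least 3"):
        pearson([1, 2], [3, 4])
    with pytest.raises(ValueError, match="zero-variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_nan_pairs_dropped():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 4.0, 6.0, 8.0, np.nan]
    r, p, n = pearson(x, y)
    assert n == 3
    assert r == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def test_diagonal_and_symmetry():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
    rep = correlation_matrix(df)
    assert np.allclose(np.diag(rep.r), 1.0)
    assert np.allclose(rep.r, rep.r.T)


def test_null_simulation_small_r():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        hits += abs(correlation_matrix(df).r.loc["a", "b"]) < 0.1
    assert hits >= 95


def test_all_missing_pair_flagged():
    df = pd.DataFrame({
        "a": [1.0, 2.0, 3.0, 4.0],
        "b": [np.nan] * 4,
    })
    rep = correlation_matrix(df)
    assert np.isnan(rep.r.loc["a", "b"])


def test_planted_structure_day112():
    # wiggle-free nulls mirror the expressed-but-uncorrelated control genes
    from atexpand import GeneratorConfig, generate_expression, generate_phenotypes

    cfg = GeneratorConfig(
        seed=33, mice_per_cell=40,
        n_genes_per_class={"ATE": 5, "FLAT": 5},
        profile_wiggle_sd={"ATE": 0.0, "FLAT": 0.0},
    )
    phen = generate_phenotypes(cfg)
    b = generate_expression(cfg, phen)
    sub = phen[phen.age_days == 112]
    cols = [f"{m}@d112" for m in sub.mouse_id]
    ate = [g for g in b.truth.index if b.truth[g] == "ATE"]
    flat = [g for g in b.truth.index if b.truth[g] == "FLAT"][0]
    table = pd.DataFrame({"fat_mass": sub.fm_g.to_numpy()})
    for g in ate + [flat]:
        table[g] = b.per_mouse.loc[g, cols].to_numpy()
    rep = correlation_matrix(table)
    sig = rep.significant(alpha=0.01)
    for a, bb in itertools.combinations(ate, 2):
        assert sig.loc[a, bb]
    # null gene mirrors the negative-control profile: no association
    assert not sig.loc[flat, ate].any()


# ---------------------------------------------------------------------------
# PRCF
# ---------------------------------------------------------------------------

def test_single_value():
    c = prcf([5.0])
    assert c.values.tolist() == [5.0]
    assert c.percent.tolist() == [100.0]


def test_four_values():
    c = prcf([3, 1, 4, 2])
    assert c.values.tolist() == [1, 2, 3, 4]
    assert c.percent.tolist() == [25.0, 50.0, 75.0, 100.0]


def test_empty_rejected():
    with pytest.raises(ValueError):
        prcf([])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
def test_monotone_and_order_invariant(values):
    c = prcf(values)
    assert np.all(np.diff(c.values) >= 0)
    assert np.all(np.diff(c.percent) >= 0)
    c2 = prcf(values[::-1])
    assert np.array_equal(c.values, c2.values)


def test_binned_variant():
    c = prcf(np.arange(100.0), bins=10)
    assert len(c.percent) == 10
    assert c.percent[-1] == 100.0


def test_undernutrition_curve_left_shifted(phenotypes):
    # stochastic dominance: the under-nutrition fat-mass distribution sits
    # left of control at every quantile
    d10 = phenotypes[phenotypes.age_days == 10]
    lun = np.sort(d10[d10.arm == "LUN"].fm_g.to_numpy())
    ctl = np.sort(d10[d10.arm == "CONTROL"].fm_g.to_numpy())
    assert np.all(lun < ctl)


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def test_printed_worked_example():
    assert round(variance_explained(0.63)) == 40


@pytest.mark.parametrize("r,expected", [(1.0, 100.0), (-0.5, 25.0), (0.0, 0.0)])
def test_variance_explained_cases(r, expected):
    assert variance_explained(r) == pytest.approx(expected)


def test_variance_explained_range_check():
    with pytest.raises(ValueError):
        variance_explained(1.5)


# ---------------------------------------------------------------------------
# summary-statistic t-tests
# ---------------------------------------------------------------------------

def test_identical_groups():
    t, df, p = t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert t == 0.0 and p == 1.0


def test_table_day10_bodyweight_significant():
    for variant in ("pooled", "welch"):
        t, df, p = t_from_summary(5.53, 0.71, 44, 3.79, 0.46, 26, variant)
        assert p < 0.01


def _sample_with_moments(mean, sd, n, rng):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def test_summary_equals_raw_data_oracle():
    rng = np.random.default_rng(4)
    a = _sample_with_moments(5.53, 0.71, 44, rng)
    b = _sample_with_moments(3.79, 0.46, 26, rng)
    for variant, equal_var in (("pooled", True), ("welch", False)):
        t, df, p = t_from_summary(5.53, 0.71, 44, 3.79, 0.46, 26, variant)
        raw = stats.ttest_ind(a, b, equal_var=equal_var)
        assert t == pytest.approx(raw.statistic, abs=1e-10)
        assert p == pytest.approx(raw.pvalue, abs=1e-10)


def test_summary_validation():
    with pytest.raises(ValueError):
        t_from_summary(1, 1, 1, 2, 1, 10)
    with pytest.raises(ValueError):
        t_from_summary(1, -1, 5, 2, 1, 10)
    with pytest.raises(ValueError):
        t_from_summary(1, 1, 5, 2, 1, 10, variant="bootstrap")


# ---------------------------------------------------------------------------
# ANOVA + compact letter display
# ---------------------------------------------------------------------------

def test_identical_groups_single_letter():
    g = {"a": np.ones(5), "b": np.ones(5), "c": np.ones(5)}
    res = anova_oneway(g)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert set(res.letters.values()) == {"a"}


def test_two_groups_F_equals_t_squared():
    rng = np.random.default_rng(5)
    g = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.5, 1, 30)}
    res = anova_oneway(g)
    t, df, p = t_from_summary(
        g["a"].mean(), g["a"].std(ddof=1), 30,
        g["b"].mean(), g["b"].std(ddof=1), 30,
    )
    assert res.F == pytest.approx(t * t, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_shifted_group_gets_distinct_letter():
    rng = np.random.default_rng(6)
    g = {
        "ctrl": rng.normal(0, 1, 200),
        "same": rng.normal(0, 1, 200),
        "shift": rng.normal(2.0, 1, 200),
    }
    res = anova_oneway(g, alpha=0.01)
    assert res.letters["ctrl"] == res.letters["same"]
    assert res.letters["shift"] != res.letters["ctrl"]


def test_small_group_rejected():
    with pytest.raises(ValueError):
        anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


def test_letter_display_chain():
    # a ~ b, b ~ c, but a != c: b shares letters with both
    sig = {("a", "b"): False, ("b", "c"): False, ("a", "c"): True}
    letters = compact_letter_display(["a", "b", "c"], sig)
    assert set(letters["b"]) & set(letters["a"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
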
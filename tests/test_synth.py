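"""Generator tests: calibration fidelity, couplings, pooling, determinism."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from atexpand import (
    AGES,
    ARMS,
    Couplings,
    GeneratorConfig,
    NutritionArm,
    generate_cohort3,
    generate_expression,
    generate_phenotypes,
)
from atexpand.calibrate import lognormal_corr
from atexpand.synth import (
    BMP3_LIKE,
    MEST_LIKE,
    PHENOTYPE_COLUMNS,
    ConfigError,
    build_gene_specs,
)

C, U, O = NutritionArm.CONTROL, NutritionArm.LUN, NutritionArm.LON


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

def test_pool_larger_than_cell_rejected():
    with pytest.raises(ConfigError, match="pool_size"):
        GeneratorConfig(mice_per_cell=5, pool_size=12)


def test_negative_sd_rejected():
    params = dict(GeneratorConfig().table1_params)
    params[(C, 10, "bw")] = (5.53, -0.1)
    with pytest.raises(ConfigError, match="negative sd"):
        GeneratorConfig(table1_params=params)


def test_unknown_gene_class_rejected():
    with pytest.raises(ConfigError, match="unknown gene class"):
        GeneratorConfig(n_genes_per_class={"WAT": 3})


def test_out_of_range_coupling_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(couplings=Couplings(fatmass_bodyweight=1.2))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def test_schema_and_mass_invariants(phenotypes):
    for col in PHENOTYPE_COLUMNS:
        assert col in phenotypes.columns
    assert set(phenotypes["age_days"]) == set(AGES)
    assert (phenotypes["fm_g"] > 0).all()
    assert (phenotypes["lm_g"] > 0).all()
    assert (
        phenotypes["fm_g"] + phenotypes["lm_g"] <= phenotypes["bw_g"] + 1e-9
    ).all()


def test_determinism_bit_identical(default_config):
    a = generate_phenotypes(default_config)
    b = generate_phenotypes(default_config)
    pd.testing.assert_frame_equal(a, b)
    ea = generate_expression(default_config, a)
    eb = generate_expression(default_config, b)
    pd.testing.assert_frame_equal(ea.matrix.values, eb.matrix.values)
    pd.testing.assert_frame_equal(ea.per_mouse, eb.per_mouse)


def test_day10_control_body_weight_calibration():
    # printed group summary: (5.53, 0.71); tolerance 3*sd/sqrt(n)
    cfg = GeneratorConfig(seed=11, mice_per_cell=10_000,
                          n_genes_per_class={"FLAT": 1})
    phen = generate_phenotypes(cfg)
    sub = phen[(phen.arm == "CONTROL") & (phen.age_days == 10)]
    assert abs(sub.bw_g.mean() - 5.53) < 3 * 0.71 / np.sqrt(10_000)


def test_mass_calibration_all_consistent_cells():
    """Large-n means converge to the configured values for every mass cell
    whose printed means are internally consistent (fm + lm <= bw)."""
    cfg = GeneratorConfig(seed=5, mice_per_cell=4000,
                          n_genes_per_class={"FLAT": 1})
    phen = generate_phenotypes(cfg)
    n = 4000
    for arm in ARMS:
        for age in AGES:
            mu_b, sd_b = cfg.param(arm, age, "bw")
            mu_f, sd_f = cfg.param(arm, age, "fm")
            mu_l, sd_l = cfg.param(arm, age, "lm")
            sub = phen[(phen.arm == arm.value) & (phen.age_days == age)]
            assert abs(sub.fm_g.mean() - mu_f) < 3 * sd_f / np.sqrt(n) + 1e-3
            assert abs(sub.lm_g.mean() - mu_l) < 3 * sd_l / np.sqrt(n) + 1e-3
            if mu_b >= mu_f + mu_l:  # printed means internally consistent
                tol = 3 * sd_b / np.sqrt(n) + 0.011  # +residual floor
                assert abs(sub.bw_g.mean() - mu_b) < tol


def test_zero_variance_cells_are_degenerate_and_flagged():
    params = {
        k: (m, 0.0) if k[2] in ("bw", "fm", "lm") else (m, s)
        for k, (m, s) in GeneratorConfig().table1_params.items()
    }
    cfg = GeneratorConfig(seed=0, table1_params=params, residual_cv=0.25)
    with pytest.warns(UserWarning, match="zero-variance"):
        phen = generate_phenotypes(cfg)
    sub = phen[(phen.arm == "CONTROL") & (phen.age_days == 5)]
    assert np.allclose(sub.fm_g, 0.31)
    assert np.allclose(sub.lm_g, 2.75)
    assert np.allclose(sub.bw_g, 3.16)  # fm + lm + deterministic residual


def test_crossage_correlation_matches_closed_form():
    # independent oracle: with per-age loadings lambda the cross-age
    # correlation of the latent-factor construction is exactly their
    # product; sqrt(0.63) each -> 0.63
    lam = 0.63**0.5
    assert lam * lam == pytest.approx(0.63)
    cfg = GeneratorConfig(seed=9, mice_per_cell=10_000,
                          n_genes_per_class={"FLAT": 1})
    phen = generate_phenotypes(cfg)
    for arm, expected in ((C, 0.63), (O, 0.63), (U, 0.0)):
        sub = phen[phen.arm == arm.value]
        f10 = sub[sub.age_days == 10].sort_values("mouse_id").fm_g.to_numpy()
        f112 = sub[sub.age_days == 112].sort_values("mouse_id").fm_g.to_numpy()
        assert np.corrcoef(f10, f112)[0, 1] == pytest.approx(expected, abs=0.03)


def test_lun_leptin_mostly_below_detection():
    # matched to "5 quantifiable out of 24" at the default floor
    cfg = GeneratorConfig(seed=21, mice_per_cell=4000,
                          n_genes_per_class={"FLAT": 1})
    phen = generate_phenotypes(cfg)
    lun10 = phen[(phen.arm == "LUN") & (phen.age_days == 10)]
    frac = (lun10.leptin_ngml > 0).mean()
    assert frac == pytest.approx(5 / 24, abs=0.03)


def test_leptin_mrna_coupling_recovered():
    cfg = GeneratorConfig(seed=13, mice_per_cell=2000,
                          n_genes_per_class={"FLAT": 1})
    phen = generate_phenotypes(cfg)
    early = phen[phen.age_days <= 21]
    r = np.corrcoef(early.leptin_ngml, early.leptin_mrna_au)[0, 1]
    assert r == pytest.approx(0.894, abs=0.02)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_ate_profile_shape(bundle):
    spec = next(s for s in bundle.gene_specs if s.gene_id == BMP3_LIKE)
    assert spec.multiplier((C, 10)) > spec.multiplier((U, 10))
    for arm in ARMS:
        assert spec.multiplier((arm, 112)) > spec.multiplier((arm, 56))


def test_zero_noise_replicates_identical():
    cfg = GeneratorConfig(seed=3, noise_cv=0.0,
                          n_genes_per_class={"ATE": 3, "FLAT": 3})
    phen = generate_phenotypes(cfg)
    b = generate_expression(cfg, phen)
    for arm in ARMS:
        for age in AGES:
            arrs = b.matrix.arrays_for_cell((arm, age))
            vals = b.matrix.values[arrs].to_numpy()
            assert np.allclose(vals, vals[:, [0]])


def test_pooling_is_mean_of_members():
    cfg = GeneratorConfig(seed=3, noise_cv=0.0, qpcr_cv=0.0,
                          n_genes_per_class={"ATE": 3, "FLAT": 3})
    phen = generate_phenotypes(cfg)
    b = generate_expression(cfg, phen)
    cell = (C, 10)
    members = sorted(
        phen[(phen.arm == "CONTROL") & (phen.age_days == 10)].mouse_id
    )[: cfg.pool_size]
    cols = [f"{m}@d010" for m in members]
    expected = b.per_mouse[cols].mean(axis=1)
    arr = b.matrix.arrays_for_cell(cell)[0]
    assert np.allclose(b.matrix.values[arr], expected, rtol=1e-12)


def test_truth_labels_match_counts(bundle, default_config):
    counts = bundle.truth.value_counts().to_dict()
    assert counts == default_config.n_genes_per_class
    assert bundle.truth[MEST_LIKE] == "ATE"


def test_missing_cell_is_error(default_config, phenotypes):
    broken = phenotypes[
        ~((phenotypes.arm == "LUN") & (phenotypes.age_days == 21))
    ]
    with pytest.raises(ConfigError, match="pool_size"):
        generate_expression(default_config, broken)


def test_empty_gene_universe_is_clean(phenotypes, default_config):
    cfg = default_config.with_(n_genes_per_class={})
    b = generate_expression(cfg, phenotypes)
    assert b.matrix.values.shape[0] == 0
    assert len(b.truth) == 0


def test_mest_loading_stronger_than_generic(bundle):
    mest = next(s for s in bundle.gene_specs if s.gene_id == MEST_LIKE)
    bmp3 = next(s for s in bundle.gene_specs if s.gene_id == BMP3_LIKE)
    assert mest.fat_loading > bmp3.fat_loading > 0


# ---------------------------------------------------------------------------
# cohort III
# ---------------------------------------------------------------------------

def test_cohort3_shapes_and_litter_range(small_config):
    phen, expr = generate_cohort3(small_config)
    assert len(phen) == 249
    assert (phen.sex == "M").sum() == 119
    assert phen.litter_size.between(6, 12).all()
    assert expr.shape == (10, 249)  # planted adiposity genes only


def test_cohort3_bodyweight_coupling():
    rs = []
    for seed in range(50):
        phen, _ = generate_cohort3(
            GeneratorConfig(seed=seed, n_genes_per_class={"ATE": 2}))
        rs.append(np.corrcoef(phen.fm_g, phen.bw_g)[0, 1])
    assert np.mean(rs) == pytest.approx(0.76, abs=0.05)


def test_cohort3_adipocyte_coupling_large_n():
    cfg = GeneratorConfig(seed=17, cohort3_n=5000,
                          n_genes_per_class={"ATE": 2})
    phen, _ = generate_cohort3(cfg)
    r = np.corrcoef(phen.fm_g, phen.adipocyte_area_au)[0, 1]
    assert r == pytest.approx(0.648, abs=0.03)


def test_cohort3_zero_litter_coupling():
    cfg = GeneratorConfig(
        seed=23, cohort3_n=5000, n_genes_per_class={"ATE": 2},
        couplings=Couplings(littersize_fatmass=0.0),
    )
    phen, _ = generate_cohort3(cfg)
    assert abs(np.corrcoef(phen.litter_size, phen.fm_g)[0, 1]) < 0.05


def test_cohort3_litter_coupling_sign_and_size():
    cfg = GeneratorConfig(seed=29, cohort3_n=5000,
                          n_genes_per_class={"ATE": 2})
    phen, _ = generate_cohort3(cfg)
    r = np.corrcoef(phen.litter_size, phen.fm_g)[0, 1]
    assert r == pytest.approx(-0.325, abs=0.05)


def test_cohort3_small_n_warns():
    cfg = GeneratorConfig(seed=1, cohort3_n=5,
                          n_genes_per_class={"ATE": 2})
    with pytest.warns(UserWarning, match="not meaningful"):
        generate_cohort3(cfg)


def test_cohort3_marker_coupling_tracks_configured_target():
    """Monte-Carlo check: the generic planted-gene correlation with fat
    mass stays within ±0.1 of the analytic single-cell value over 100
    cohort draws."""
    cfg = GeneratorConfig(seed=0, cohort3_n=119, n_genes_per_class={"ATE": 2})
    spec = next(s for s in build_gene_specs(cfg) if s.gene_id == BMP3_LIKE)
    predicted = lognormal_corr(spec.fat_loading, cfg.qpcr_cv)
    rs = []
    for seed in range(100):
        phen, expr = generate_cohort3(cfg.with_(seed=seed))
        rs.append(np.corrcoef(phen.fm_g, expr.loc[BMP3_LIKE])[0, 1])
    assert np.mean(rs) == pytest.approx(predicted, abs=0.1)
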
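"""Coupling calibration helpers for the synthetic-data generator.

The generator promises that certain Pearson correlations of its output match
configured targets (fat-mass couplings of marker genes, the plasma-leptin /
leptin-mRNA coupling).  Because expression noise is multiplicative-lognormal
and plasma leptin is left-censored at a detection floor, the raw latent
loading that achieves a target correlation must be solved for.  Closed forms
are used where they exist; pooled, censored cases fall back to a
deterministic Monte-Carlo root-find with an internal fixed seed.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

_MC_SEED = 0x5EED  # internal; independent of user-facing seeds


def lognormal_corr(gamma: float, noise_cv: float = 0.0) -> float:
    """Pearson corr between a standard normal Z and ``exp(gamma*Z)*N``.

    ``N`` is independent multiplicative noise with mean 1 and coefficient of
    variation ``noise_cv``.  Closed form:
    ``gamma / sqrt(exp(gamma^2) * (1 + cv^2) - 1)``.
    """
    if gamma == 0:
        return 0.0
    g2 = gamma * gamma
    # exp(g2)*(1+cv^2) - 1 via expm1 to stay finite for tiny loadings
    denom = np.expm1(g2) + noise_cv**2 * np.exp(g2)
    return gamma / np.sqrt(denom)


def loading_for_corr(target: float, noise_cv: float = 0.0) -> float:
    """Invert :func:`lognormal_corr`: loading gamma achieving ``target``.

    Raises ``ValueError`` when the target exceeds the attainable maximum for
    the given noise level.
    """
    if not 0 <= target < 1:
        raise ValueError("target correlation must be in [0, 1)")
    if target == 0:
        return 0.0
    # with noise the curve rises from 0 to a maximum and then decays; solve
    # on the rising branch (smallest loading achieving the target)
    f = lambda g: lognormal_corr(g, noise_cv) - target
    grid = np.linspace(0.0, 8.0, 161)
    prev = 0.0
    for g in grid[1:]:
        if f(g) >= 0:
            return float(brentq(f, prev, g, xtol=1e-12))
        prev = g
    raise ValueError(
        f"target correlation {target} not attainable with noise_cv={noise_cv}"
    )


def _pooled_censored_corr(
    rho: float,
    means: np.ndarray,
    sds: np.ndarray,
    floor: float,
    mrna_scale: float,
    n_per_cell: int,
    rng: np.random.Generator,
) -> float:
    """Pooled Pearson corr of (censored plasma, mRNA) over design cells.

    Within each cell the two variables share a standard-normal drive with
    correlation ``rho``; plasma below ``floor`` is recorded as 0 (assay
    non-detect), mRNA is clipped at a tiny positive value.
    """
    k = len(means)
    d = rng.standard_normal((k, n_per_cell))
    e = rng.standard_normal((k, n_per_cell))
    pz = d
    mz = rho * d + np.sqrt(max(0.0, 1 - rho * rho)) * e
    plasma = means[:, None] + sds[:, None] * pz
    mrna = mrna_scale * (means[:, None] + sds[:, None] * mz)
    plasma = np.where(plasma < floor, 0.0, plasma)
    mrna = np.maximum(mrna, 0.01)
    return float(np.corrcoef(plasma.ravel(), mrna.ravel())[0, 1])


def solve_leptin_rho(
    means: np.ndarray,
    sds: np.ndarray,
    target: float,
    floor: float,
    mrna_scale: float = 1.0,
    n_per_cell: int = 40_000,
) -> float:
    """Within-cell drive correlation reproducing a pooled plasma/mRNA corr.

    Deterministic (fixed internal seed).  Uses common random numbers across
    brentq evaluations so the objective is continuous in ``rho``.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)

    def obj(rho: float) -> float:
        rng = np.random.default_rng(_MC_SEED)
        return _pooled_censored_corr(
            rho, means, sds, floor, mrna_scale, n_per_cell, rng
        ) - target

    lo, hi = obj(0.0), obj(1.0)
    if lo >= 0:
        return 0.0
    if hi <= 0:
        raise ValueError(
            f"pooled leptin correlation target {target} not attainable "
            f"(max {hi + target:.3f}); lower the target or the detection floor"
        )
    return float(brentq(obj, 0.0, 1.0, xtol=1e-6))


def solve_pooled_expression_loading(
    fat_means: np.ndarray,
    fat_sds: np.ndarray,
    multipliers: np.ndarray,
    target: float,
    noise_cv: float,
    n_per_cell: int = 40_000,
) -> float:
    """Loading gamma such that pooled corr(fat mass, expression) hits target.

    Expression in cell c is ``mult_c * exp(gamma*z - gamma^2/2) * noise`` and
    fat mass is ``mean_c + sd_c * z``; pooling across cells adds a
    between-cell component (cells with more fat also have larger
    multipliers), so the pooled correlation exceeds the within-cell one.
    Deterministic Monte-Carlo root-find, common random numbers.
    """
    fat_means = np.asarray(fat_means, float)
    fat_sds = np.asarray(fat_sds, float)
    multipliers = np.asarray(multipliers, float)
    sig = np.sqrt(np.log1p(noise_cv**2))

    def realized(gamma: float) -> float:
        rng = np.random.default_rng(_MC_SEED + 1)
        k = len(fat_means)
        z = rng.standard_normal((k, n_per_cell))
        noise = np.exp(sig * rng.standard_normal((k, n_per_cell)) - sig**2 / 2)
        fat = np.maximum(fat_means[:, None] + fat_sds[:, None] * z, 0.01)
        expr = multipliers[:, None] * np.exp(gamma * z - gamma**2 / 2) * noise
        return float(np.corrcoef(fat.ravel(), expr.ravel())[0, 1])

    obj = lambda g: realized(g) - target
    if obj(0.0) >= 0:
        return 0.0
    # the pooled correlation rises then falls in gamma; bracket the first
    # upward crossing on a coarse grid and refine with brentq
    grid = np.linspace(0.0, 4.0, 41)
    prev_g, prev_v = 0.0, obj(0.0)
    for g in grid[1:]:
        v = obj(g)
        if v >= 0:
            return float(brentq(obj, prev_g, g, xtol=1e-6))
        prev_g, prev_v = g, v
    raise ValueError(f"expression/fat correlation target {target} not attainable")
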
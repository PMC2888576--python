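"""Synthetic phenotype and expression generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a
3-arm × 5-age factorial of per-mouse adiposity phenotypes calibrated to the
published group summary table, pooled triplicate expression arrays for the
15 design cells, and planted gene classes (adiposity-tracking, diet-induced,
developmental, null, ...) whose recoverability by the filtering/Venn cascade
is known by construction.

Conventions
-----------
* Phenotypes are truncated normals per design cell; a persistent per-mouse
  latent factor produces configurable cross-age fat-mass correlations
  (positive for CONTROL/LON, zero for LUN by default).
* Body weight is fat + lean + a small positive residual so the mass
  identity ``fm + lm <= bw`` holds for every record.
* Array noise is multiplicative lognormal with mean 1 and a configured CV.
* Plasma leptin is left-censored at a detection floor (non-detects recorded
  as 0), which under the default floor leaves most under-nutrition pups
  non-quantifiable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibrate
from .design import AGES, ARMS, Cell, DesignSpec, NutritionArm, array_id, cell_label
from .matrix import ExpressionMatrix
from .tables import (
    DEFAULT_INSULIN,
    DEFAULT_PROFILES,
    DEFAULT_TABLE1,
    GENE_CLASSES,
    profile_vector,
)

__all__ = [
    "GeneratorConfig",
    "Couplings",
    "GeneSpec",
    "ExpressionBundle",
    "ConfigError",
    "generate_phenotypes",
    "generate_expression",
    "generate_cohort3",
    "PHENOTYPE_COLUMNS",
    "MEST_LIKE",
    "BMP3_LIKE",
]

#: Documented public schema of a phenotype table (CSV header order).
PHENOTYPE_COLUMNS = [
    "mouse_id", "arm", "sex", "litter_size", "age_days",
    "bw_g", "fm_g", "lm_g", "leptin_ngml", "insulin_au",
    "leptin_mrna_au", "adipocyte_area_au",
]

#: Ids of the two planted marker genes used for template construction.
MEST_LIKE = "ATE_mest"
BMP3_LIKE = "ATE_bmp3"


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Couplings:
    """Named correlation targets the generator is calibrated to.

    ``crossage_fat`` holds per-arm latent-factor loadings; the implied
    fat-mass correlation between any two ages equals the product of the
    loadings (``sqrt(0.63)`` each reproduces the printed cross-age R=0.63).
    """

    leptin_mrna_plasma: float = 0.894
    fatmass_bodyweight: float = 0.76
    fatmass_adipocyte: float = 0.648
    littersize_fatmass: float = -0.325  # sign is a modelling choice
    mest_fatmass_d112: float = 0.83
    crossage_fat_loading: tuple[float, float, float] = (
        0.63**0.5,  # CONTROL
        0.0,        # LUN: no cross-age tracking under negative energy balance
        0.63**0.5,  # LON
    )

    def loading(self, arm: NutritionArm) -> float:
        return dict(zip(ARMS, self.crossage_fat_loading))[arm]


@dataclass(frozen=True)
class GeneSpec:
    """One planted gene: class archetype, baseline and couplings."""

    gene_id: str
    gene_class: str
    baseline: float
    profile: np.ndarray  # 15 multipliers, canonical cell order
    fat_loading: float = 0.0  # lognormal loading on the mouse fat z-score
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigError(f"{self.gene_id}: baseline must be positive")
        if np.any(np.asarray(self.profile) <= 0):
            raise ConfigError(f"{self.gene_id}: profile multipliers must be positive")
        if self.noise_cv < 0:
            raise ConfigError(f"{self.gene_id}: noise_cv must be nonnegative")

    def multiplier(self, cell: Cell) -> float:
        cells = [(arm, age) for arm in ARMS for age in AGES]
        return float(self.profile[cells.index(cell)])


def _default_gene_counts() -> dict[str, int]:
    return {
        "ATE": 30,
        "HFD_INDUCED": 40,
        "LUN_INDUCED": 40,
        "DEV_EARLY": 40,
        "MATERNAL_HFD": 40,
        "FLAT": 310,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs; all randomness flows from ``seed``."""

    seed: int = 0
    mice_per_cell: int = 12
    arrays_per_pool: int = 3
    pool_size: int = 12
    n_genes_per_class: dict[str, int] = field(default_factory=_default_gene_counts)
    table1_params: dict[tuple[NutritionArm, int, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TABLE1)
    )
    couplings: Couplings = field(default_factory=Couplings)
    profiles: dict[str, dict[NutritionArm, tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    noise_cv: float = 0.05       # technical CV of replicate arrays
    qpcr_cv: float = 0.10        # per-mouse expression measurement CV
    ate_fat_coupling: float = 0.5  # single-cell corr target of generic planted genes
    leptin_floor: float = 2.6    # ng/ml; ELISA detection limit
    leptin_fat_share: float = 0.5
    lean_latent_loading: float = 0.5
    residual_cv: float = 0.25
    mrna_scale: float = 1.0
    insulin_means: dict[tuple[NutritionArm, int], float] = field(
        default_factory=lambda: dict(DEFAULT_INSULIN)
    )
    cohort3_n: int = 249
    cohort3_n_males: int = 119
    cohort3_litter_range: tuple[int, int] = (6, 12)
    # per-gene lognormal jitter of the archetype multipliers; FLAT jitter is
    # kept below the fold threshold so null genes never acquire a real
    # >=1.6-fold contrast, while making their shapes diverse
    profile_wiggle_sd: dict[str, float] = field(
        default_factory=lambda: {
            "ATE": 0.0, "HFD_INDUCED": 0.08, "LUN_INDUCED": 0.08,
            "DEV_EARLY": 0.08, "MATERNAL_HFD": 0.08, "FLAT": 0.15,
        }
    )

    def __post_init__(self) -> None:
        if self.mice_per_cell < self.pool_size:
            raise ConfigError(
                f"mice_per_cell ({self.mice_per_cell}) must be >= pool_size "
                f"({self.pool_size})"
            )
        if self.arrays_per_pool < 1:
            raise ConfigError("arrays_per_pool must be >= 1")
        for key, (mean, sd) in self.table1_params.items():
            if sd < 0:
                raise ConfigError(f"negative sd for {key}")
            if mean <= 0:
                raise ConfigError(f"nonpositive mean for {key}")
        if self.noise_cv < 0 or self.qpcr_cv < 0:
            raise ConfigError("noise CVs must be nonnegative")
        for cls in self.n_genes_per_class:
            if cls not in GENE_CLASSES:
                raise ConfigError(f"unknown gene class {cls!r}")
        for coupling in (
            self.couplings.leptin_mrna_plasma,
            self.couplings.fatmass_bodyweight,
            self.couplings.fatmass_adipocyte,
            self.couplings.littersize_fatmass,
            self.couplings.mest_fatmass_d112,
        ):
            if abs(coupling) > 1:
                raise ConfigError("couplings must lie in [-1, 1]")

    def param(self, arm: NutritionArm, age: int, var: str) -> tuple[float, float]:
        try:
            return self.table1_params[(arm, age, var)]
        except KeyError:
            raise ConfigError(f"no table parameters for ({arm}, {age}, {var!r})")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# calibration caches (pure functions of config values; safe to memoize)
# ---------------------------------------------------------------------------
_rho_cache: dict[tuple, float] = {}
_mest_cache: dict[tuple, float] = {}


def _leptin_rho(config: GeneratorConfig) -> float:
    """Within-cell plasma/mRNA drive correlation (cached)."""
    cells = [(arm, age) for arm in ARMS for age in (5, 10, 21)]
    means = np.array([config.param(a, d, "leptin")[0] for a, d in cells])
    sds = np.array([config.param(a, d, "leptin")[1] for a, d in cells])
    key = (tuple(means), tuple(sds), config.couplings.leptin_mrna_plasma,
           config.leptin_floor, config.mrna_scale)
    if key not in _rho_cache:
        _rho_cache[key] = calibrate.solve_leptin_rho(
            means, sds, config.couplings.leptin_mrna_plasma,
            config.leptin_floor, config.mrna_scale,
        )
    return _rho_cache[key]


def _mest_loading(config: GeneratorConfig) -> float:
    """Lognormal loading of the Mest-like gene (cached).

    Calibrated so that fat mass vs per-mouse expression, pooled over the
    three arms at day 112, hits the configured target.
    """
    fm = np.array([config.param(arm, 112, "fm")[0] for arm in ARMS])
    fs = np.array([config.param(arm, 112, "fm")[1] for arm in ARMS])
    mult = np.array(
        [config.profiles["ATE"][arm][AGES.index(112)] for arm in ARMS]
    )
    key = (tuple(fm), tuple(fs), tuple(mult),
           config.couplings.mest_fatmass_d112, config.qpcr_cv)
    if key not in _mest_cache:
        _mest_cache[key] = calibrate.solve_pooled_expression_loading(
            fm, fs, mult, config.couplings.mest_fatmass_d112, config.qpcr_cv
        )
    return _mest_cache[key]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _leptin_pair(
    config: GeneratorConfig,
    arm: NutritionArm,
    age: int,
    fat_z: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Censored plasma leptin and its mRNA for one design cell."""
    mu, sd = config.param(arm, age, "leptin")
    n = len(fat_z)
    a = config.leptin_fat_share
    drive = a * fat_z + np.sqrt(1 - a * a) * rng.standard_normal(n)
    rho = _leptin_rho(config)
    mz = rho * drive + np.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(n)
    plasma_raw = mu + sd * drive
    plasma = np.where(plasma_raw < config.leptin_floor, 0.0, plasma_raw)
    mrna = np.maximum(config.mrna_scale * (mu + sd * mz), 0.01)
    return plasma, mrna


def generate_phenotypes(config: GeneratorConfig) -> pd.DataFrame:
    """Longitudinal per-mouse phenotype records for the 15 design cells.

    Each arm carries ``mice_per_cell`` mice measured at all five ages; a
    persistent latent adiposity factor gives the configured cross-age
    fat-mass correlations.  Returns a table with :data:`PHENOTYPE_COLUMNS`
    plus a private ``_fat_z`` column (the standardized within-cell fat
    deviate) used to couple expression to adiposity.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.mice_per_cell
    degenerate = any(
        sd == 0 for (_, _, v), (_, sd) in config.table1_params.items()
        if v in ("bw", "fm", "lm")
    )
    if degenerate:
        warnings.warn(
            "zero-variance phenotype cell(s): cross-age correlations are "
            "undefined for them", UserWarning, stacklevel=2,
        )
    rows: list[dict] = []
    for arm in ARMS:
        lam = config.couplings.loading(arm)
        z = rng.standard_normal(n)  # persistent per-mouse latent factor
        litter = 4 if arm is NutritionArm.LON else 8
        sexes = np.where(np.arange(n) % 2 == 0, "M", "F")
        for age in AGES:
            mu_f, sd_f = config.param(arm, age, "fm")
            mu_l, sd_l = config.param(arm, age, "lm")
            mu_b, sd_b = config.param(arm, age, "bw")
            fat_z = lam * z + np.sqrt(max(0.0, 1 - lam * lam)) * rng.standard_normal(n)
            fm = np.maximum(mu_f + sd_f * fat_z, 0.01)
            b = config.lean_latent_loading
            lean_z = b * z + np.sqrt(1 - b * b) * rng.standard_normal(n)
            lm = np.maximum(mu_l + sd_l * lean_z, 0.01)
            slack = max(mu_b - mu_f - mu_l, 0.01)
            if sd_b > 0 and config.residual_cv > 0:
                shape = 1.0 / config.residual_cv**2
                resid = rng.gamma(shape, slack / shape, size=n)
            else:
                resid = np.full(n, slack)
            bw = fm + lm + resid
            plasma, mrna = _leptin_pair(config, arm, age, fat_z, rng)
            mu_i = config.insulin_means[(arm, age)]
            insulin = np.maximum(
                mu_i * (1 + 0.3 * (0.4 * fat_z
                                   + np.sqrt(1 - 0.16) * rng.standard_normal(n))),
                0.0,
            )
            mu_a = 1000.0 * mu_f ** (2.0 / 3.0)
            rho_a = config.couplings.fatmass_adipocyte
            area_z = rho_a * fat_z + np.sqrt(1 - rho_a**2) * rng.standard_normal(n)
            area = np.maximum(mu_a * (1 + 0.3 * area_z), 1.0)
            for i in range(n):
                rows.append({
                    "mouse_id": f"{arm.value}_m{i:04d}",
                    "arm": arm.value,
                    "sex": sexes[i],
                    "litter_size": litter,
                    "age_days": age,
                    "bw_g": bw[i],
                    "fm_g": fm[i],
                    "lm_g": lm[i],
                    "leptin_ngml": plasma[i],
                    "insulin_au": insulin[i],
                    "leptin_mrna_au": mrna[i],
                    "adipocyte_area_au": area[i],
                    "_fat_z": fat_z[i],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionBundle:
    """Generated expression data plus planted ground truth."""

    matrix: ExpressionMatrix
    per_mouse: pd.DataFrame          # genes x mouse_id, measured values
    truth: pd.Series                 # gene_id -> gene_class
    gene_specs: list[GeneSpec]


def build_gene_specs(config: GeneratorConfig) -> list[GeneSpec]:
    """Materialize gene specs from class counts with seeded baselines."""
    rng = np.random.default_rng([config.seed, 7])
    specs: list[GeneSpec] = []
    generic_loading = calibrate.loading_for_corr(
        config.ate_fat_coupling, config.qpcr_cv
    )
    for cls, count in config.n_genes_per_class.items():
        if count == 0:
            continue
        prof = profile_vector(config.profiles[cls])
        if cls == "ATE":
            lo, hi = 4000.0, 8000.0
        elif cls == "FLAT":
            lo, hi = 500.0, 50000.0
        else:
            lo, hi = 2000.0, 20000.0
        baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=count))
        wiggle = config.profile_wiggle_sd.get(cls, 0.0)
        for i in range(count):
            gene_prof = prof
            if wiggle > 0:
                gene_prof = prof * np.exp(wiggle * rng.standard_normal(len(prof)))
            if cls == "ATE" and i == 0 and count >= 2:
                gid, loading = MEST_LIKE, _mest_loading(config)
            elif cls == "ATE" and i == 1 and count >= 2:
                gid, loading = BMP3_LIKE, generic_loading
            else:
                gid = f"{cls}{i:04d}"
                loading = generic_loading if cls == "ATE" else 0.0
            specs.append(GeneSpec(
                gene_id=gid, gene_class=cls, baseline=float(baselines[i]),
                profile=gene_prof, fat_loading=loading, noise_cv=config.noise_cv,
            ))
    return specs


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sig = np.sqrt(np.log1p(cv * cv))
    return np.exp(sig * rng.standard_normal(shape) - sig * sig / 2)


def generate_expression(
    config: GeneratorConfig, phen: pd.DataFrame
) -> ExpressionBundle:
    """Pooled replicate arrays plus per-mouse expression for planted genes.

    Per-mouse true expression is ``baseline * profile[(arm, age)] *
    exp(loading * fat_z - loading^2/2)`` (mean-preserving lognormal
    adiposity coupling, nonzero only for planted adiposity-tracking genes).
    Each design cell's pool value is the arithmetic mean over its
    ``pool_size`` members and every replicate array is the pool value times
    multiplicative lognormal noise.
    """
    specs = build_gene_specs(config)
    rng = np.random.default_rng([config.seed, 2])
    if not specs:
        # empty gene universe is legal: emit an empty matrix over the design
        design = DesignSpec.default(config.arrays_per_pool)
        empty = pd.DataFrame(
            np.empty((0, len(design.array_ids))),
            index=pd.Index([], name="gene_id"),
            columns=design.array_ids,
        )
        return ExpressionBundle(
            matrix=ExpressionMatrix(empty, design),
            per_mouse=pd.DataFrame(index=pd.Index([], name="gene_id")),
            truth=pd.Series(dtype=object, name="gene_class"),
            gene_specs=[],
        )
    gene_ids = [s.gene_id for s in specs]
    baselines = np.array([s.baseline for s in specs])
    loadings = np.array([s.fat_loading for s in specs])
    profiles = np.stack([s.profile for s in specs])  # genes x 15

    cells = [(arm, age) for arm in ARMS for age in AGES]
    pool_cols: dict[str, np.ndarray] = {}
    mouse_cols: dict[str, np.ndarray] = {}
    for ci, (arm, age) in enumerate(cells):
        sub = phen[(phen["arm"] == arm.value) & (phen["age_days"] == age)]
        sub = sub.sort_values("mouse_id")
        if len(sub) < config.pool_size:
            raise ConfigError(
                f"cell {(arm.value, age)} has {len(sub)} mice; "
                f"pool_size is {config.pool_size}"
            )
        fat_z = sub["_fat_z"].to_numpy()
        mult = baselines[:, None] * profiles[:, ci][:, None]
        true = mult * np.exp(
            loadings[:, None] * fat_z[None, :] - (loadings**2)[:, None] / 2
        )  # genes x mice-in-cell
        measured = true * _lognormal_noise(rng, config.qpcr_cv, true.shape)
        for j, mid in enumerate(sub["mouse_id"]):
            mouse_cols[f"{mid}@d{age:03d}"] = measured[:, j]
        pool = true[:, : config.pool_size].mean(axis=1)
        for r in range(1, config.arrays_per_pool + 1):
            noise = _lognormal_noise(rng, config.noise_cv, pool.shape)
            pool_cols[array_id((arm, age), r)] = pool * noise

    design = DesignSpec.default(config.arrays_per_pool)
    values = pd.DataFrame(pool_cols, index=pd.Index(gene_ids, name="gene_id"))
    per_mouse = pd.DataFrame(mouse_cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.Series(
        {s.gene_id: s.gene_class for s in specs}, name="gene_class"
    ).loc[gene_ids]
    return ExpressionBundle(
        matrix=ExpressionMatrix(values, design),
        per_mouse=per_mouse,
        truth=truth,
        gene_specs=specs,
    )


# ---------------------------------------------------------------------------
# cohort III: control-raised mice phenotyped/expressed at day 10
# ---------------------------------------------------------------------------

def generate_cohort3(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-cell cohort (control, day 10) with litter-size competition.

    Returns ``(phenotypes, per_mouse_expression)``.  Couplings: fat mass is
    weakly tied to litter size (sign per config), body weight and adipocyte
    area are tied to fat mass at the configured correlations, and planted
    adiposity genes follow their day-10 control multiplier with their
    lognormal fat-mass loading.
    """
    n = config.cohort3_n
    if n < 10:
        warnings.warn(
            "cohort size < 10: correlation targets are not meaningful",
            UserWarning, stacklevel=2,
        )
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.cohort3_litter_range
    if not (0 < lo <= hi):
        raise ConfigError("invalid litter size range")
    sizes: list[int] = []
    litter_of_mouse: list[int] = []
    while len(litter_of_mouse) < n:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(s)
        litter_of_mouse.extend([s] * s)
    litter = np.array(litter_of_mouse[:n], dtype=int)
    # theoretical moments of the discrete-uniform litter size
    mu_L = (lo + hi) / 2.0
    sd_L = np.sqrt(((hi - lo + 1) ** 2 - 1) / 12.0)
    litter_z = (litter - mu_L) / sd_L

    arm = NutritionArm.CONTROL
    rho_L = config.couplings.littersize_fatmass
    fat_z = rho_L * litter_z + np.sqrt(1 - rho_L**2) * rng.standard_normal(n)
    mu_f, sd_f = config.param(arm, 10, "fm")
    fm = np.maximum(mu_f + sd_f * fat_z, 0.01)
    rho_b = config.couplings.fatmass_bodyweight
    mu_b, sd_b = config.param(arm, 10, "bw")
    bw = mu_b + sd_b * (rho_b * fat_z + np.sqrt(1 - rho_b**2) * rng.standard_normal(n))
    bw = np.maximum(bw, fm + 0.01)
    lm = 0.97 * (bw - fm)
    rho_a = config.couplings.fatmass_adipocyte
    mu_a = 1000.0 * mu_f ** (2.0 / 3.0)
    area = np.maximum(
        mu_a * (1 + 0.3 * (rho_a * fat_z
                           + np.sqrt(1 - rho_a**2) * rng.standard_normal(n))),
        1.0,
    )
    plasma, mrna = _leptin_pair(config, arm, 10, fat_z, rng)
    mu_i = config.insulin_means[(arm, 10)]
    insulin = np.maximum(
        mu_i * (1 + 0.3 * rng.standard_normal(n)), 0.0
    )
    n_males = min(config.cohort3_n_males, n)
    sex = np.array(["F"] * n, dtype=object)
    sex[rng.permutation(n)[:n_males]] = "M"

    phen = pd.DataFrame({
        "mouse_id": [f"C3_m{i:04d}" for i in range(n)],
        "arm": arm.value,
        "sex": sex,
        "litter_size": litter,
        "age_days": 10,
        "bw_g": bw,
        "fm_g": fm,
        "lm_g": lm,
        "leptin_ngml": plasma,
        "insulin_au": insulin,
        "leptin_mrna_au": mrna,
        "adipocyte_area_au": area,
        "_fat_z": fat_z,
    })

    specs = [s for s in build_gene_specs(config) if s.gene_class == "ATE"]
    cell: Cell = (arm, 10)
    cols = {}
    if specs:
        baselines = np.array([s.baseline for s in specs])
        loadings = np.array([s.fat_loading for s in specs])
        mults = np.array([s.multiplier(cell) for s in specs])
        true = (baselines * mults)[:, None] * np.exp(
            loadings[:, None] * fat_z[None, :] - (loadings**2)[:, None] / 2
        )
        measured = true * _lognormal_noise(rng, config.qpcr_cv, true.shape)
        cols = {mid: measured[:, j] for j, mid in enumerate(phen["mouse_id"])}
    expr = pd.DataFrame(
        cols, index=pd.Index([s.gene_id for s in specs], name="gene_id")
    )
    return phen, expr
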
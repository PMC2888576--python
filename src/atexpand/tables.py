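"""Default calibration constants for the synthetic-data generator.

Group phenotype means/SDs are transcribed from the published summary table
of the nutrition study (body weight, fat mass, lean mass per arm and age;
plasma leptin at days 10/112; a Mest-like marker at day 112).  Cells the
table does not cover (e.g. plasma leptin at days 5/21/56) carry invented
values consistent with the described developmental profiles; they are
plain config defaults and can be overridden.
"""
from __future__ import annotations

import numpy as np

from .design import AGES, ARMS, NutritionArm

C, U, O = NutritionArm.CONTROL, NutritionArm.LUN, NutritionArm.LON

#: (arm, age_days, variable) -> (mean, sd).  Variables: bw (body weight, g),
#: fm (fat mass, g), lm (lean mass, g), leptin (plasma, ng/ml),
#: mest (marker mRNA, AU/ng RNA).
DEFAULT_TABLE1: dict[tuple[NutritionArm, int, str], tuple[float, float]] = {
    # day 5
    (C, 5, "bw"): (3.16, 0.40), (U, 5, "bw"): (2.40, 0.30), (O, 5, "bw"): (2.95, 0.43),
    (C, 5, "fm"): (0.31, 0.08), (U, 5, "fm"): (0.11, 0.05), (O, 5, "fm"): (0.32, 0.12),
    (C, 5, "lm"): (2.75, 0.39), (U, 5, "lm"): (2.18, 0.38), (O, 5, "lm"): (2.55, 0.34),
    # day 10
    (C, 10, "bw"): (5.53, 0.71), (U, 10, "bw"): (3.79, 0.46), (O, 10, "bw"): (5.71, 1.01),
    (C, 10, "fm"): (0.69, 0.20), (U, 10, "fm"): (0.28, 0.11), (O, 10, "fm"): (0.83, 0.31),
    (C, 10, "lm"): (4.77, 0.46), (U, 10, "lm"): (3.56, 0.36), (O, 10, "lm"): (4.47, 0.63),
    # day 21
    (C, 21, "bw"): (9.67, 1.08), (U, 21, "bw"): (6.45, 1.16), (O, 21, "bw"): (10.09, 1.25),
    (C, 21, "fm"): (1.06, 0.261), (U, 21, "fm"): (0.57, 0.20), (O, 21, "fm"): (1.41, 0.32),
    (C, 21, "lm"): (8.06, 0.86), (U, 21, "lm"): (5.56, 0.81), (O, 21, "lm"): (8.21, 0.91),
    # day 56
    (C, 56, "bw"): (22.96, 1.39), (U, 56, "bw"): (21.50, 1.24), (O, 56, "bw"): (22.50, 1.52),
    (C, 56, "fm"): (1.75, 0.44), (U, 56, "fm"): (1.51, 0.27), (O, 56, "fm"): (2.04, 0.38),
    (C, 56, "lm"): (17.95, 1.36), (U, 56, "lm"): (16.90, 1.18), (O, 56, "lm"): (17.70, 1.32),
    # day 112
    (C, 112, "bw"): (35.95, 4.20), (U, 112, "bw"): (30.70, 2.78), (O, 112, "bw"): (35.48, 4.42),
    (C, 112, "fm"): (10.92, 3.23), (U, 112, "fm"): (7.18, 2.13), (O, 112, "fm"): (10.36, 3.43),
    (C, 112, "lm"): (21.99, 1.31), (U, 112, "lm"): (20.50, 0.85), (O, 112, "lm"): (21.68, 1.43),
    # plasma leptin, published at days 10 and 112
    (C, 10, "leptin"): (7.24, 5.75), (U, 10, "leptin"): (0.66, 2.42), (O, 10, "leptin"): (8.51, 10.15),
    (C, 112, "leptin"): (24.80, 7.91), (U, 112, "leptin"): (12.48, 7.58), (O, 112, "leptin"): (20.60, 10.01),
    # plasma leptin, invented for uncovered ages (suckling rise, LUN suppressed,
    # low on chow at day 56)
    (C, 5, "leptin"): (3.50, 2.50), (U, 5, "leptin"): (0.30, 0.80), (O, 5, "leptin"): (4.00, 3.50),
    (C, 21, "leptin"): (5.00, 3.50), (U, 21, "leptin"): (0.80, 1.50), (O, 21, "leptin"): (6.00, 4.00),
    (C, 56, "leptin"): (2.50, 1.20), (U, 56, "leptin"): (2.20, 1.10), (O, 56, "leptin"): (2.50, 1.20),
    # marker mRNA (AU/ng RNA), published at day 112
    (C, 112, "mest"): (40.76, 26.05), (U, 112, "mest"): (20.10, 14.50), (O, 112, "mest"): (34.88, 31.73),
}

#: Invented plasma-insulin means (AU): LON precociously hyper-insulinemic
#: during suckling, LUN suppressed; converge after weaning.
DEFAULT_INSULIN: dict[tuple[NutritionArm, int], float] = {
    (C, 5): 1.0, (C, 10): 1.2, (C, 21): 1.5, (C, 56): 2.0, (C, 112): 3.0,
    (U, 5): 0.3, (U, 10): 0.3, (U, 21): 0.6, (U, 56): 1.8, (U, 112): 2.5,
    (O, 5): 2.0, (O, 10): 2.5, (O, 21): 2.2, (O, 56): 2.0, (O, 112): 3.2,
}


def table1_means(var: str) -> dict[tuple[NutritionArm, int], float]:
    return {
        (arm, age): ms[0]
        for (arm, age, v), ms in DEFAULT_TABLE1.items()
        if v == var
    }


# ---------------------------------------------------------------------------
# Expression archetype profiles
# ---------------------------------------------------------------------------
# Per gene class, a positive multiplier for each of the 15 design cells,
# given as arm -> multipliers over ages (5, 10, 21, 56, 112).  Shapes follow
# the four heat-map archetypes plus the adiposity-tracking profile: high
# during suckling under positive energy balance, suppressed by
# under-nutrition, nadir around weaning/chow, re-induced on high-fat diet.

GENE_CLASSES = ("ATE", "HFD_INDUCED", "LUN_INDUCED", "DEV_EARLY",
                "MATERNAL_HFD", "FLAT")

_P = dict  # alias for brevity

DEFAULT_PROFILES: dict[str, dict[NutritionArm, tuple[float, ...]]] = {
    # adiposity-tracking: up at d5/d10 except under LUN, nadir d21-d56,
    # strongly re-induced at d112 in every arm (less so in LUN)
    "ATE": _P({
        C: (3.0, 3.5, 0.8, 0.5, 2.8),
        U: (1.2, 1.2, 0.7, 0.5, 2.0),
        O: (3.0, 3.5, 0.8, 0.5, 2.8),
    }),
    # silent until the adult high-fat diet, then induced in every arm
    "HFD_INDUCED": _P({
        C: (0.5, 0.5, 0.5, 0.6, 3.0),
        U: (0.5, 0.5, 0.5, 0.6, 3.0),
        O: (0.5, 0.5, 0.5, 0.6, 3.0),
    }),
    # induced by under-nutrition during suckling only
    "LUN_INDUCED": _P({
        C: (1.0, 1.0, 1.0, 0.8, 0.8),
        U: (3.0, 3.0, 2.5, 0.8, 0.8),
        O: (1.0, 1.0, 1.0, 0.8, 0.8),
    }),
    # early developmental program, nutrition-independent
    "DEV_EARLY": _P({
        C: (3.0, 3.0, 1.5, 0.6, 0.6),
        U: (3.0, 3.0, 1.5, 0.6, 0.6),
        O: (3.0, 3.0, 1.5, 0.6, 0.6),
    }),
    # constitutively up in pups whose dam ate the high-fat diet
    "MATERNAL_HFD": _P({
        C: (1.0, 1.0, 1.0, 1.0, 1.0),
        U: (1.0, 1.0, 1.0, 1.0, 1.0),
        O: (3.0, 3.0, 3.0, 1.0, 1.0),
    }),
    # null genes: no structure at all
    "FLAT": _P({
        C: (1.0, 1.0, 1.0, 1.0, 1.0),
        U: (1.0, 1.0, 1.0, 1.0, 1.0),
        O: (1.0, 1.0, 1.0, 1.0, 1.0),
    }),
}


def profile_vector(profile: dict[NutritionArm, tuple[float, ...]]) -> np.ndarray:
    """Flatten an arm->ages profile into the canonical 15-cell order."""
    out = []
    for arm in ARMS:
        vals = profile[arm]
        if len(vals) != len(AGES):
            raise ValueError(f"profile for {arm} has {len(vals)} ages, want {len(AGES)}")
        out.extend(vals)
    return np.asarray(out, dtype=float)
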
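"""File I/O: tabular formats, GEO series-matrix reading and run manifests.

All deliverable formats are plain text: phenotype tables as CSV with a
documented header, expression as TSV (first column gene id) with a sidecar
design CSV mapping arrays to cells, ground-truth labels as two-column TSV.
"""
from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Cell, DesignSpec, NutritionArm, parse_cell_label
from .matrix import ExpressionMatrix
from .synth import PHENOTYPE_COLUMNS

__all__ = [
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_expression_tsv", "read_expression_tsv",
    "write_truth_tsv", "read_truth_tsv",
    "read_geo_series_matrix",
    "config_hash", "write_manifest",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes_csv(phen: pd.DataFrame, path) -> None:
    """Write the public phenotype schema (private columns dropped)."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phen.columns]
    if missing:
        raise FormatError(f"phenotype table missing column(s): {missing}")
    phen[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, tsv_path, design_path) -> None:
    """Expression TSV (gene_id + one column per array) and design sidecar."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(tsv_path, sep="\t")
    rows = []
    for aid, (arm, age) in matrix.design.array_map.items():
        rep = aid.rsplit("_r", 1)[-1]
        rows.append({
            "array_id": aid, "arm": arm.value, "age_days": age,
            "replicate_index": int(rep) if rep.isdigit() else 0,
        })
    pd.DataFrame(rows).to_csv(design_path, index=False)


def read_expression_tsv(tsv_path, design_path) -> ExpressionMatrix:
    df = pd.read_csv(tsv_path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(
            f"{tsv_path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{tsv_path}: duplicate gene ids: {dup}")
    sidecar = pd.read_csv(design_path)
    need = {"array_id", "arm", "age_days"}
    if not need <= set(sidecar.columns):
        raise FormatError(f"{design_path}: needs columns {sorted(need)}")
    amap: dict[str, Cell] = {}
    for _, row in sidecar.iterrows():
        amap[str(row["array_id"])] = (NutritionArm(row["arm"]), int(row["age_days"]))
    unmapped = [c for c in df.columns if c not in amap]
    if unmapped:
        raise FormatError(f"{tsv_path}: arrays not in design sidecar: {unmapped}")
    cells = sorted(set(amap.values()), key=lambda c: (list(NutritionArm).index(c[0]), c[1]))
    design = DesignSpec(cells=cells, array_map={c: amap[c] for c in df.columns})
    return ExpressionMatrix(df, design)


def write_truth_tsv(truth: pd.Series, path) -> None:
    truth.rename("gene_class").rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")["gene_class"]


# ---------------------------------------------------------------------------
# GEO series matrix
# ---------------------------------------------------------------------------

#: Default regex mapping sample titles to design coordinates.  Expects named
#: groups ``arm`` (C/Control, LUN/U, LON/O), ``age`` (days) and optionally
#: ``rep``.  Deposited sample-title conventions vary, so this map is a
#: user-editable argument, not a fixed rule.
DEFAULT_TITLE_PATTERN = (
    r"(?P<arm>CONTROL|CTRL|CON|C|LUN|U|LON|O)[ _-]*"
    r"(?:d|day)?[ _-]*(?P<age>\d+)(?:[ _-]*(?:r|rep)?(?P<rep>\d+))?"
)

_ARM_ALIASES = {
    "C": NutritionArm.CONTROL, "CON": NutritionArm.CONTROL,
    "CTRL": NutritionArm.CONTROL, "CONTROL": NutritionArm.CONTROL,
    "U": NutritionArm.LUN, "LUN": NutritionArm.LUN,
    "O": NutritionArm.LON, "LON": NutritionArm.LON,
}


def read_geo_series_matrix(
    path, title_pattern: str = DEFAULT_TITLE_PATTERN
) -> tuple[ExpressionMatrix, list[str]]:
    """Parse a GEO series-matrix file into an expression matrix.

    Metadata lines are ``!``-prefixed; the expression block sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    Sample titles are translated to (arm, age, replicate) through
    ``title_pattern``; samples that do not match are reported back (second
    return value), never guessed.
    """
    path = Path(path)
    titles: list[str] = []
    accessions: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_title"):
                titles = [t.strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_geo_accession"):
                accessions = [t.strip('"') for t in line.split("\t")[1:]]
    if not table_lines:
        raise FormatError(f"{path}: no expression block found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    df = df.rename(columns={df.columns[0]: "gene_id"}).set_index("gene_id")
    df.index = df.index.astype(str).str.strip('"')
    if not titles:
        titles = list(df.columns)
    if not accessions:
        accessions = list(df.columns)

    rx = re.compile(title_pattern, re.IGNORECASE)
    amap: dict[str, Cell] = {}
    renames: dict[str, str] = {}
    unparsed: list[str] = []
    rep_counter: dict[Cell, int] = {}
    for acc, title in zip(accessions, titles):
        m = rx.search(title)
        if not m:
            unparsed.append(title)
            continue
        arm = _ARM_ALIASES.get(m.group("arm").upper())
        if arm is None:
            unparsed.append(title)
            continue
        cell = (arm, int(m.group("age")))
        rep_counter[cell] = rep_counter.get(cell, 0) + 1
        rep = m.groupdict().get("rep") or rep_counter[cell]
        aid = f"{arm.value}_d{cell[1]:03d}_r{int(rep)}"
        renames[acc] = aid
        amap[aid] = cell
    keep = [c for c in df.columns if c in renames]
    df = df[keep].rename(columns=renames)
    if df.empty or not amap:
        raise FormatError(f"{path}: no samples could be mapped to design cells")
    cells = sorted(set(amap.values()), key=lambda c: (list(NutritionArm).index(c[0]), c[1]))
    design = DesignSpec(cells=cells, array_map=amap)
    return ExpressionMatrix(df.astype(float), design), unparsed


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    """Recursively coerce configs (dataclasses, tuple-keyed dicts, numpy
    scalars) into plain JSON-compatible structures."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    if isinstance(obj, NutritionArm):
        return obj.value
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        def key(k):
            if isinstance(k, tuple):
                return "|".join(str(_jsonable(p)) for p in k)
            return str(_jsonable(k))
        return {key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_jsonable(v) for v in obj]
    return str(obj)


def config_hash(config) -> str:
    """Stable SHA-256 over a canonical JSON rendering of a config object."""
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path, *, seed: int, config, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "seed": seed,
        "version": __version__,
        "config_hash": config_hash(config),
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
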
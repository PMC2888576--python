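"""End-to-end pipeline driver: simulate → normalize → filter → cluster →
Venn cascade → association, with manifest-stamped tabular outputs."""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .association import correlation_matrix, prcf
from .clustering import (
    ProfileTemplate,
    default_template,
    kmeans_profiles,
    select_cluster_by_template,
    standardize_profiles,
)
from .matrix import ExpressionMatrix
from .preprocess import FilterCriteria, filter_genes, quantile_normalize
from .synth import (
    GeneratorConfig,
    generate_expression,
    generate_phenotypes,
)
from .venn import ComparisonSpec, default_comparisons, run_venn

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 50
    seed: int = 0
    n_restarts: int = 10
    template_rate_weight: float = 0.5


@dataclass(frozen=True)
class AssociationConfig:
    alpha: float = 0.01
    age_days: int = 112
    top_genes: int = 10  # planted adiposity genes to correlate


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    venn: tuple[ComparisonSpec, ...] = field(
        default_factory=lambda: tuple(default_comparisons())
    )
    association: AssociationConfig = field(default_factory=AssociationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a (possibly partial) nested YAML mapping."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "generator" in raw:
            kw["generator"] = GeneratorConfig(**raw["generator"])
        if "filter" in raw:
            kw["filter"] = FilterCriteria(**raw["filter"])
        if "clustering" in raw:
            kw["clustering"] = ClusteringConfig(**raw["clustering"])
        if "association" in raw:
            kw["association"] = AssociationConfig(**raw["association"])
        return cls(**kw)


@dataclass
class PipelineResult:
    phenotypes: pd.DataFrame
    normalized: ExpressionMatrix
    filter_report: object
    cluster_result: object
    template_cluster: int
    template_corr: float
    venn_result: object
    correlations: object
    prcf_tables: dict[str, pd.DataFrame]
    truth: pd.Series


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute every stage on freshly generated synthetic data.

    When ``out_dir`` is given, writes phenotypes/expression/filter/cluster/
    Venn/correlation/PRCF tables plus a run manifest carrying the seed and
    the config hash.
    """
    gen = config.generator
    phen = _stage("simulate-phenotypes")(generate_phenotypes)(gen)
    bundle = _stage("simulate-expression")(generate_expression)(gen, phen)
    normalized = _stage("normalize")(quantile_normalize)(bundle.matrix)
    report = _stage("filter")(filter_genes)(normalized, config.filter)

    filtered = normalized.subset(report.passing) if report.passing else normalized
    if report.passing and len(report.passing) > config.clustering.k:
        profiles = _stage("standardize")(standardize_profiles)(filtered)
        clusters = _stage("cluster")(kmeans_profiles)(
            profiles,
            k=config.clustering.k,
            seed=config.clustering.seed,
            n_restarts=config.clustering.n_restarts,
        )
        template = default_template(
            gen, rate_weight=config.clustering.template_rate_weight
        )
        tpl_idx, tpl_r = _stage("template-match")(select_cluster_by_template)(
            clusters, template
        )
    else:
        clusters, tpl_idx, tpl_r = None, -1, float("nan")
        log.warning("too few passing genes for clustering; stage skipped")

    venn = _stage("venn")(run_venn)(filtered, list(config.venn)) if report.passing else None

    # association: planted adiposity genes vs fat mass at the configured age
    assoc_cfg = config.association
    age = assoc_cfg.age_days
    sub = phen[phen["age_days"] == age]
    cols = [f"{m}@d{age:03d}" for m in sub["mouse_id"]]
    ate_genes = [g for g in bundle.truth.index if bundle.truth[g] == "ATE"]
    flat_genes = [g for g in bundle.truth.index if bundle.truth[g] == "FLAT"]
    chosen = ate_genes[: assoc_cfg.top_genes] + flat_genes[:1]
    table = pd.DataFrame({"fat_mass": sub["fm_g"].to_numpy()})
    for g in chosen:
        table[g] = bundle.per_mouse.loc[g, cols].to_numpy()
    correlations = _stage("associate")(correlation_matrix)(table)

    prcf_tables: dict[str, pd.DataFrame] = {}
    for arm in sorted(sub["arm"].unique()):
        vals = sub.loc[sub["arm"] == arm, "fm_g"]
        curve = prcf(vals)
        prcf_tables[f"fat_mass_{arm}"] = pd.DataFrame(
            {"value": curve.values, "percent": curve.percent}
        )

    result = PipelineResult(
        phenotypes=phen,
        normalized=normalized,
        filter_report=report,
        cluster_result=clusters,
        template_cluster=tpl_idx,
        template_corr=tpl_r,
        venn_result=venn,
        correlations=correlations,
        prcf_tables=prcf_tables,
        truth=bundle.truth,
    )
    if out_dir is not None:
        _write_outputs(result, bundle, config, Path(out_dir))
    return result


def _write_outputs(result, bundle, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    chash = aio.config_hash(config)
    aio.write_phenotypes_csv(result.phenotypes, out / "phenotypes.csv")
    aio.write_expression_tsv(
        result.normalized, out / "expression_normalized.tsv", out / "design.csv"
    )
    aio.write_truth_tsv(result.truth, out / "truth_labels.tsv")
    rep = result.filter_report
    pd.DataFrame([{
        "n_input": rep.n_input, "n_pass_signal": rep.n_pass_signal,
        "n_pass_fold": rep.n_pass_fold, "n_pass_ttest": rep.n_pass_ttest,
        "n_pass_all": rep.n_pass_all, "config_hash": chash,
    }]).to_csv(out / "filter_report.csv", index=False)
    if result.cluster_result is not None:
        cr = result.cluster_result
        df = cr.assignments.rename("cluster").rename_axis("gene_id").reset_index()
        df["config_hash"] = chash
        df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.venn_result is not None:
        vr = result.venn_result
        prov = vr.provenance.copy()
        prov["in_final"] = [g in vr.ate for g in prov.index]
        prov["config_hash"] = chash
        prov.to_csv(out / "venn_sets.tsv", sep="\t")
        pd.Series(sorted(vr.ate.genes), name="gene_id").to_csv(
            out / "ate_genes.tsv", sep="\t", index=False
        )
    result.correlations.r.to_csv(out / "correlations_r.tsv", sep="\t")
    result.correlations.p.to_csv(out / "correlations_p.tsv", sep="\t")
    for name, df in result.prcf_tables.items():
        df.to_csv(out / f"prcf_{name}.tsv", sep="\t", index=False)
    aio.write_manifest(
        out / "manifest.json",
        seed=config.generator.seed,
        config=config,
        extra={"stages": ["simulate", "normalize", "filter", "cluster",
                          "venn", "associate"]},
    )
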
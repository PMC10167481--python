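"""End-to-end orchestration on synthetic data.

``run_all`` wires every stage together at demo scale: simulate a compendium
with planted coexpression modules plus developmental and tissue datasets,
assemble and normalize the compendium, score expression variability, compute
pairwise coexpression, compute coflux on a metabolic model whose pathways
mirror the planted modules, cluster the product matrix, run the pathway
self-enrichment screen, and rank activation conditions.  Every artifact is
written as TSV under the run directory together with a JSON manifest of
parameters and per-stage seeds.

Each stage draws from its own generator seeded by a stable hash of
``(master_seed, stage_name)`` so stages are individually reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import RELAXED, STRINGENT, cluster_product, product_matrix
from .coexpression import pairwise_pcc
from .coflux import coflux_pipeline
from .conditions import cluster_dataset_coexpression, rank_conditions
from .enrichment import (
    PathwayAnnotation,
    n_coexpressed,
    results_table,
    self_enrichment_screen,
    write_gmt,
)
from .gpr import parse_gpr
from .model import MetabolicModel
from .preprocess import assemble_compendium, filter_low_expression_dev, \
    filter_low_expression_tissue, fit_bimodal_expression
from .synthetic import (
    ToyModelSpec,
    make_toy_model,
    planted_compendium_params,
    simulate_compendium,
    simulate_dev_timecourse,
    simulate_tissue_matrix,
)
from .variation import (
    categorize_compendium,
    categorize_dev,
    categorize_tissue,
    coefficient_of_variation,
    compendium_cv_table,
    flat_envelope,
    variation_scores,
    vs_threshold,
)


@dataclass
class PipelineConfig:
    """All thresholds and scales of the pipeline, with printed defaults."""

    seed: int = 0
    out_dir: str = "coexflux_run"
    # synthetic scale
    n_modules: int = 4
    module_size: int = 8
    n_datasets: int = 20
    n_active: int = 4
    n_genes: int = 120
    loading: float = 0.9
    noise_sd: float = 0.1
    n_random_pathways: int = 4
    dev_n_genes: int = 2000
    dev_n_flat: int = 400
    dev_n_timepoints: int = 25
    tissue_n_genes: int = 700
    # thresholds
    vs_quantile: float = 0.97
    cv_high: float = 0.75
    cv_low: float = 0.3
    min_high_datasets: int = 3
    invariant_fraction: float = 0.95
    fdr: float = 0.05
    nes: float = 2.0
    n_perm: int = 1000
    min_overlap: int = 10
    skew_threshold: float = 0.5
    top_k: int = 30

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


def model_for_modules(module_members: dict[str, frozenset[str]]) -> MetabolicModel:
    """A parallel-chain toy model whose per-chain genes are the planted
    module genes: within-module coflux 1, between-module coflux 0."""
    n_chains = len(module_members)
    size = max(len(m) for m in module_members.values())
    base = make_toy_model(
        ToyModelSpec(
            topology="parallel_independent",
            n_internal_reactions=size,
            n_chains=n_chains,
        )
    )
    gprs = {}
    for k, (_, members) in enumerate(sorted(module_members.items()), start=1):
        for i, gene in enumerate(sorted(members), start=1):
            gprs[f"c{k}R{i}"] = parse_gpr(gene)
    base.gprs = gprs
    return base


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts and writes TSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # --- simulate ------------------------------------------------------
    params = planted_compendium_params(
        n_modules=config.n_modules,
        module_size=config.module_size,
        n_datasets=config.n_datasets,
        n_active=config.n_active,
        n_genes=config.n_genes,
        loading=config.loading,
        noise_sd=config.noise_sd,
        seed=stage_seed(config.seed, "compendium"),
    )
    datasets, gt = simulate_compendium(params)
    dev, dev_gt = simulate_dev_timecourse(
        n_genes=config.dev_n_genes,
        n_flat=config.dev_n_flat,
        n_timepoints=config.dev_n_timepoints,
        seed=stage_seed(config.seed, "dev"),
    )
    tissue, tissue_gt = simulate_tissue_matrix(
        n_genes=config.tissue_n_genes, seed=stage_seed(config.seed, "tissue")
    )
    model = model_for_modules(gt.module_members)
    artifacts.update(datasets=datasets, ground_truth=gt, model=model)

    # --- preprocess ----------------------------------------------------
    comp, manifest = assemble_compendium(
        datasets, skew_threshold=config.skew_threshold
    )
    _write(manifest, out / "compendium_manifest.tsv", index=False)
    artifacts["compendium"] = comp

    # --- variation -----------------------------------------------------
    fit = fit_bimodal_expression(
        np.log2(dev.values.mean(axis=1)), seed=stage_seed(config.seed, "mixture")
    )
    dev_kept = filter_low_expression_dev(dev, fit)
    env = flat_envelope(dev_kept)
    vs = variation_scores(dev_kept, env)
    thr = vs_threshold(
        vs.loc[sorted(dev_kept.flat_gene_ids), "vs"].to_numpy(), config.vs_quantile
    )
    lowly = set(dev.values.index) - set(dev_kept.values.index)
    dev_cat = categorize_dev(vs["vs"].to_dict(), thr, lowly)
    _write(vs.assign(category=dev_cat), out / "dev_variation.tsv")

    tissue_kept = filter_low_expression_tissue(tissue)
    t_cv = pd.Series(
        {
            g: coefficient_of_variation(tissue_kept.values.loc[g].to_numpy())
            for g in tissue_kept.values.index
        },
        name="cv",
    )
    t_cat = t_cv.map(
        lambda c: categorize_tissue(c, cv_low=config.cv_low, cv_high=config.cv_high)
    )
    _write(pd.DataFrame({"cv": t_cv, "category": t_cat}), out / "tissue_variation.tsv")

    cv_table = compendium_cv_table(datasets)
    comp_cat = pd.Series(
        {
            g: categorize_compendium(
                cv_table.loc[g].dropna().to_dict(),
                cv_low=config.cv_low,
                cv_high=config.cv_high,
                min_high_datasets=config.min_high_datasets,
                invariant_fraction=config.invariant_fraction,
            )
            for g in cv_table.index
        },
        name="category",
    )
    _write(comp_cat.to_frame(), out / "compendium_categories.tsv")
    artifacts.update(
        dev_fit=fit, vs=vs, vs_threshold=thr, dev_categories=dev_cat,
        tissue_categories=t_cat, compendium_categories=comp_cat,
    )

    # --- coexpression --------------------------------------------------
    coexpr = pairwise_pcc(comp, min_overlap=config.min_overlap)
    _write(coexpr.values, out / "coexpression.tsv")
    artifacts["coexpression"] = coexpr

    # --- coflux --------------------------------------------------------
    gene_cf, reaction_cf, opened = coflux_pipeline(model)
    _write(gene_cf.values, out / "coflux.tsv")
    artifacts["coflux"] = gene_cf

    # --- clustering ----------------------------------------------------
    pm = product_matrix(gene_cf, coexpr)
    _write(pm.values, out / "product_matrix.tsv")
    stringent = cluster_product(pm, **STRINGENT)
    relaxed = cluster_product(pm, **RELAXED)
    labels = pd.DataFrame(
        {"stringent_cluster": stringent.labels, "relaxed_cluster": relaxed.labels}
    )
    _write(labels, out / "cluster_labels.tsv")
    mss = pd.DataFrame(
        [(k, v) for k, v in stringent.mss.items()], columns=["cluster", "mss"]
    )
    _write(mss, out / "cluster_mss.tsv", index=False)
    artifacts.update(product=pm, stringent=stringent, relaxed=relaxed)

    # --- enrichment ----------------------------------------------------
    pathways = [
        PathwayAnnotation(pathway_id=name, gene_ids=members)
        for name, members in gt.module_members.items()
    ]
    rng = np.random.default_rng(stage_seed(config.seed, "random_pathways"))
    genes = list(coexpr.values.index)
    for i in range(config.n_random_pathways):
        pathways.append(
            PathwayAnnotation(
                pathway_id=f"random{i}",
                gene_ids=frozenset(
                    rng.choice(genes, size=config.module_size, replace=False)
                ),
            )
        )
    write_gmt(pathways, out / "pathways.gmt")
    screen = self_enrichment_screen(
        coexpr.values, pathways, n_perm=config.n_perm,
        seed=stage_seed(config.seed, "enrichment"),
    )
    _write(results_table(screen), out / "self_enrichment.tsv", index=False)
    artifacts.update(pathways=pathways, screen=screen)

    # --- conditions ----------------------------------------------------
    if stringent.n_clusters >= 2:
        mean_coexpr = cluster_dataset_coexpression(stringent, datasets)
        ranking = rank_conditions(
            mean_coexpr, k=config.top_k, datasets=datasets, clusters=stringent
        )
        _write(mean_coexpr, out / "cluster_dataset_mean_coexpr.tsv")
        _write(ranking.zscores, out / "cluster_dataset_zscores.tsv")
        top = pd.DataFrame(
            [
                (cid, rank + 1, ds)
                for cid, ds_list in ranking.top_datasets.items()
                for rank, ds in enumerate(ds_list)
            ],
            columns=["cluster", "rank", "dataset_id"],
        )
        _write(top, out / "cluster_top_datasets.tsv", index=False)
        artifacts["condition_ranking"] = ranking

    run_manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("compendium", "dev", "tissue", "mixture",
                      "random_pathways", "enrichment")
        },
        "n_coexpressed_pathways": n_coexpressed(screen),
        "n_stringent_clusters": stringent.n_clusters,
        "n_relaxed_clusters": relaxed.n_clusters,
        "vs_threshold": thr,
        "amended_uptakes": opened,
    }
    (out / "manifest.json").write_text(json.dumps(run_manifest, indent=1))
    artifacts["manifest"] = run_manifest
    return artifacts
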
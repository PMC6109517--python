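"""End-to-end orchestration on a synthetic three-disease study.

Stage order: simulate -> QC (samples, then probes) -> BMIQ-style
normalization -> cytokine-chip subsetting -> per-disease differential
testing (with inverse-variance meta-analysis for the multi-dataset
disease) -> DMR calling -> cross-disease comparison (shared sites,
similarity/difference classification, ANOVA) -> FEM hotspot detection ->
over-representation analysis -> summary report.

Per-disease significance modes follow the cross-disease design the
pipeline targets: BH FDR < 0.05 for the single-dataset diseases and the
meta-analyzed disease, with a stringent mode (Bonferroni-adjusted
p < 0.05 and |delta-beta| >= 0.01) for a disease whose controls come
from stochastic resampling of another study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import bmiq, crosscompare, dmr, enrichment, fem, meta, qc, report, simulate
from .chip import GeneList, chip_composition, subset_chip
from .containers import BetaMatrix
from .differential import STRINGENT, TestConfig, dmp_test, select_significant

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    diseases: tuple[str, ...] = ("SLE", "RA", "pSS")
    stringent_diseases: tuple[str, ...] = ("pSS",)
    n_similarity: int = 40
    n_difference: int = 30
    n_specific: int = 15
    n_cases: dict[str, int] | None = None      # per-disease; default cfg.sim.n_cases
    n_controls: dict[str, int] | None = None
    shared_dmrs: tuple = (("CYT0001", 6, "similarity"), ("CYT0002", 5, "similarity"))
    normalize: bool = True
    qc_cfg: qc.QCConfig = field(default_factory=qc.QCConfig)
    dmr_cfg: dmr.DMRConfig = field(default_factory=dmr.DMRConfig)
    fem_cfg: fem.FEMConfig = field(default_factory=lambda: fem.FEMConfig(n_seeds=25, n_mc=200))
    run_fem: bool = True
    run_enrichment: bool = True
    meta_model: str = "auto"


@dataclass
class PipelineResult:
    study: simulate.CrossDiseaseStudy
    chip_annotation: pd.DataFrame
    chip_composition: dict
    qc_reports: dict
    dmps: dict[str, pd.DataFrame]          # full per-disease record tables
    significant: dict[str, pd.DataFrame]   # selected significant DMPs
    dmrs: dict[str, pd.DataFrame]
    shared: pd.DataFrame
    classified: pd.DataFrame
    anova: pd.DataFrame
    shared_dmr_table: pd.DataFrame
    hotspots: dict[str, list]
    enrichment: dict[str, pd.DataFrame]
    summary: dict


def sort_by_position(records: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Order DMP records by genomic (chrom, pos) for DMR calling."""
    key = ann.loc[records.index, ["chrom", "pos"]]
    order = key.sort_values(["chrom", "pos"], kind="stable").index
    return records.loc[order]


def run_pipeline(cfg: PipelineConfig | None = None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    study = simulate.simulate_cross_disease(
        cfg.sim,
        diseases=cfg.diseases,
        n_datasets=None,
        n_cases=cfg.n_cases,
        n_controls=cfg.n_controls,
        n_similarity=cfg.n_similarity,
        n_difference=cfg.n_difference,
        n_specific=cfg.n_specific,
        shared_dmrs=cfg.shared_dmrs,
    )
    ann = study.annotation

    # QC + normalization per dataset
    qc_reports: dict = {}
    cleaned: dict[str, dict[str, BetaMatrix]] = {}
    kept_probes = None
    for disease, datasets in study.datasets.items():
        cleaned[disease] = {}
        for ds_id, bm in datasets.items():
            bm2, ann_ds, rep = qc.run_qc(bm, ann, cfg.qc_cfg)
            if cfg.normalize:
                bm2, failed = bmiq.bmiq_normalize(bm2, ann_ds)
                rep["bmiq_failed_samples"] = failed
            qc_reports[ds_id] = rep
            cleaned[disease][ds_id] = bm2
            ids = set(bm2.probe_ids)
            kept_probes = ids if kept_probes is None else kept_probes & ids

    # cytokine chip: here the synthetic gene list is the full universe
    genes = GeneList.from_frame(simulate.cytokine_gene_list(ann))
    chip_ann = subset_chip(ann.loc[sorted(kept_probes)], genes)
    chip_ann = chip_ann.sort_values(["chrom", "pos"], kind="stable")
    composition = chip_composition(chip_ann)

    # per-disease differential testing
    bh_cfg = TestConfig()
    dmps: dict[str, pd.DataFrame] = {}
    significant: dict[str, pd.DataFrame] = {}
    for disease, datasets in cleaned.items():
        per_ds = [
            dmp_test(bm.select_probes(chip_ann.index), bh_cfg, dataset_id=ds_id)
            for ds_id, bm in datasets.items()
        ]
        if len(per_ds) > 1:
            records = meta.meta_analyze(per_ds, model=cfg.meta_model)
        else:
            records = per_ds[0]
        mode = STRINGENT if disease in cfg.stringent_diseases else bh_cfg
        if disease in cfg.stringent_diseases:
            from .differential import adjust_pvalues

            records = records.copy()
            records["adj_p"] = adjust_pvalues(records["p"].to_numpy(), "bonferroni")
        dmps[disease] = records
        significant[disease] = select_significant(records, mode)

    # DMRs per disease
    dmrs_by_disease = {
        disease: dmr.call_dmrs(sort_by_position(sig, chip_ann), chip_ann, cfg.dmr_cfg)
        for disease, sig in significant.items()
    }

    # cross-disease comparison
    shared = crosscompare.find_shared(
        {d: sig.index for d, sig in significant.items()}, chip_ann
    )
    classified = crosscompare.classify_sites(shared, dmps)
    if len(shared):
        case_betas = {
            d: pd.concat(
                [bm.values[bm.samples_in_group("case")] for bm in cleaned[d].values()],
                axis=1,
            )
            for d in cfg.diseases
        }
        anova = crosscompare.anova_across(case_betas, shared.index)
        classified = classified.join(anova)
    else:
        anova = pd.DataFrame(columns=["anova_F", "anova_p", "anova_adj_p"])
    shared_dmr_table = crosscompare.shared_dmrs(dmrs_by_disease)

    # FEM hotspots per disease
    hotspots: dict[str, list] = {}
    if cfg.run_fem:
        edges, _module = simulate.simulate_ppi(cfg.sim, study.truths[cfg.diseases[0]], ann)
        for disease, records in dmps.items():
            stats_df = fem.gene_level_stat(records, chip_ann)
            try:
                graph = fem.weight_network(edges, stats_df["stat"])
            except ValueError:
                hotspots[disease] = []
                continue
            hotspots[disease] = fem.find_hotspots(graph, stats_df["stat"], cfg.fem_cfg)

    # enrichment per disease (hyper and hypo lists separately)
    enrich: dict[str, pd.DataFrame] = {}
    if cfg.run_enrichment:
        sets = simulate.simulate_gene_sets(ann, study.truths[cfg.diseases[0]],
                                           rng_seed=cfg.sim.rng_seed)
        universe = sorted({g for gs in chip_ann["genes"] for g in gs.split(";") if g})
        for disease, sig in significant.items():
            for direction, flag in (("hyper", "HyperM"), ("hypo", "HypoM")):
                sub = sig[sig["flag"] == flag]
                query = sorted(
                    {g for pid in sub.index for g in chip_ann.at[pid, "genes"].split(";") if g}
                )
                if not query:
                    continue
                enrich[f"{disease}_{direction}"] = enrichment.ora(query, sets, universe)

    # summary report
    summary = {
        "per_disease": {
            d: report.summarize_disease(
                significant[d].join(chip_ann[["cgi_relation"]]), dmrs_by_disease[d]
            )
            for d in cfg.diseases
        },
        "cross": report.summarize_cross(
            shared, classified,
            shared_dmrs=shared_dmr_table,
            classified_dmrs=shared_dmr_table if len(shared_dmr_table) else None,
        ),
        "chip": {"n_probes": composition["n_probes"]},
    }

    return PipelineResult(
        study=study, chip_annotation=chip_ann, chip_composition=composition,
        qc_reports=qc_reports, dmps=dmps, significant=significant,
        dmrs=dmrs_by_disease, shared=shared, classified=classified, anova=anova,
        shared_dmr_table=shared_dmr_table, hotspots=hotspots, enrichment=enrich,
        summary=summary,
    )
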
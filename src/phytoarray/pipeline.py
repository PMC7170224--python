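"""End-to-end orchestration: simulate/load -> normalize -> analyze -> write.

Every stage writes its result tables as tab-delimited text with stable
float formatting, so identical seeds and configuration produce
byte-identical output trees.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, coexpression, diffexpr, genesets, io, ordination
from .config import AnalysisConfig
from .design import ArrayDesign, SampleSheet
from .preprocess import ExpressionMatrix, normalize_pipeline
from .simulate import (TruthConfig, default_truth_config, simulate_design,
                       simulate_experiment)

log = logging.getLogger(__name__)


def simulate_stage(outdir: str | Path, seed: int = 0,
                   truth: TruthConfig | None = None,
                   design: ArrayDesign | None = None):
    """Generate the synthetic experiment and write its input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = simulate_design(seed=seed)
    if truth is None:
        truth = default_truth_config(seed=seed)
    intensities, sheet, truth_out = simulate_experiment(design, truth)
    io.write_design(design, outdir / "design.tsv")
    io.write_intensities(intensities, outdir / "intensities.tsv")
    io.write_samples(sheet, outdir / "samples.tsv")
    io.write_matrix(truth_out.effects, outdir / "truth.tsv")
    return design, intensities, sheet, truth_out


def normalize_stage(raw: pd.DataFrame, design: ArrayDesign,
                    cfg: AnalysisConfig, outdir: str | Path
                    ) -> ExpressionMatrix:
    outdir = Path(outdir)
    expr = normalize_pipeline(raw, design, detection_k=cfg.detection_k,
                              normalize_level=cfg.normalize_level)
    io.write_matrix(expr.values, outdir / "expression.tsv")
    io.write_matrix(expr.detected.astype(int), outdir / "detected.tsv")
    return expr


def community_stage(expr: ExpressionMatrix, design: ArrayDesign,
                    sheet: SampleSheet, outdir: str | Path):
    outdir = Path(outdir)
    presence = community.detect_strains(expr.detected, design)
    abundance = community.strain_abundance(expr, design)
    proportions = community.phylogroup_proportions(expr, design, sheet)
    io.write_matrix(presence.present.astype(int),
                    outdir / "strain_presence.tsv")
    io.write_matrix(abundance, outdir / "strain_abundance.tsv")
    io.write_matrix(proportions, outdir / "phylogroup_proportions.tsv")
    return presence, abundance, proportions


def de_stage(expr: ExpressionMatrix, design: ArrayDesign, sheet: SampleSheet,
             cfg: AnalysisConfig, outdir: str | Path
             ) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    results = diffexpr.run_differential_expression(
        expr, sheet, fc_threshold=cfg.fc_threshold,
        alpha_gene=cfg.alpha_gene, moderate=cfg.moderation)
    ann = design.target_annotation()[["gene", "process", "strain_id",
                                      "phylogroup"]]
    for cname, res in results.items():
        table = res.join(ann, how="left")
        io.write_matrix(table, outdir / f"de_{cname}.tsv")
    return results


def geneset_stage(de_results: dict[str, pd.DataFrame], design: ArrayDesign,
                  cfg: AnalysisConfig, outdir: str | Path,
                  scope_mode: str = "phylogroup") -> pd.DataFrame:
    outdir = Path(outdir)
    sets = genesets.build_gene_sets(design, scope_mode=scope_mode)
    results = genesets.test_gene_sets(
        de_results, design, sets, n_perm=cfg.n_perm,
        wilkinson_r=cfg.wilkinson_r, alpha_set=cfg.alpha_set,
        fc_threshold=cfg.fc_threshold, seed=cfg.rng_seed)
    io.write_matrix(results.set_index("set_id"), outdir / "set_results.tsv")
    arrows = genesets.summarize_responses(results)
    io.write_matrix(arrows.set_index("scope"), outdir / "fig2_table.tsv")
    return results


def module_stage(expr: ExpressionMatrix, sheet: SampleSheet,
                 cfg: AnalysisConfig, outdir: str | Path
                 ) -> coexpression.ModuleAssignment:
    outdir = Path(outdir)
    t24 = [s for s, tp in zip(sheet.samples["sample_id"],
                              sheet.samples["timepoint"]) if tp == "T24"]
    frac = expr.detected[t24].mean(axis=1)
    genes = frac.index[frac >= cfg.module_detect_frac]
    log.info("modules: %d of %d genes detected in >=%.0f%% of T24 samples",
             len(genes), len(frac), 100 * cfg.module_detect_frac)
    assignment = coexpression.detect_modules(
        expr.values.loc[genes, t24], min_module_size=cfg.min_module_size,
        target_r2=cfg.soft_power_target_r2,
        cut_height_frac=cfg.cut_height_frac)
    io.write_matrix(assignment.labels.rename("module").to_frame(),
                    outdir / "modules.tsv")
    io.write_matrix(assignment.eigengenes, outdir / "eigengenes.tsv")
    return assignment


def ordination_stage(expr: ExpressionMatrix, sheet: SampleSheet,
                     cfg: AnalysisConfig, outdir: str | Path):
    outdir = Path(outdir)
    d = ordination.euclidean_distances(expr)
    medians = ordination.group_distance_summary(d, sheet)
    order = sheet.samples.set_index("sample_id")
    labels = (order["timepoint"] + "_" + order["treatment"]).loc[d.index]
    col_order = [s for cond in medians.index
                 for s in d.index if labels[s] == cond]
    io.write_matrix(d.loc[col_order, col_order], outdir / "distances.tsv")
    io.write_matrix(medians.rename("median_distance_to_T0").to_frame(),
                    outdir / "median_distances.tsv")
    result = ordination.nmds(d, dim=cfg.nmds_dim,
                             restarts=cfg.nmds_restarts, seed=cfg.rng_seed)
    io.write_matrix(result.coordinates, outdir / "nmds_coords.tsv")
    (outdir / "nmds_stress.txt").write_text(f"{result.stress:.6f}\n")
    return d, medians, result


def run_pipeline(outdir: str | Path, cfg: AnalysisConfig | None = None,
                 design: ArrayDesign | None = None,
                 intensities: pd.DataFrame | None = None,
                 sheet: SampleSheet | None = None,
                 truth: TruthConfig | None = None) -> dict:
    """Run every stage; simulate inputs when none are supplied."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or AnalysisConfig()
    cfg.log_effective()
    cfg.save(outdir / "config.yaml")
    truth_out = None
    if intensities is None:
        design, intensities, sheet, truth_out = simulate_stage(
            outdir, seed=cfg.rng_seed, truth=truth, design=design)
    if design is None or sheet is None:
        raise ValueError("design and sample sheet required with real data")
    expr = normalize_stage(intensities, design, cfg, outdir)
    presence, abundance, proportions = community_stage(
        expr, design, sheet, outdir)
    de_results = de_stage(expr, design, sheet, cfg, outdir)
    set_results = geneset_stage(de_results, design, cfg, outdir)
    modules = module_stage(expr, sheet, cfg, outdir)
    distances, medians, nmds_result = ordination_stage(
        expr, sheet, cfg, outdir)
    return {"design": design, "sheet": sheet, "expr": expr,
            "truth": truth_out, "presence": presence,
            "abundance": abundance, "proportions": proportions,
            "de": de_results, "sets": set_results, "modules": modules,
            "distances": distances, "median_distances": medians,
            "nmds": nmds_result}
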
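"""End-to-end orchestration: network filters -> ePRS -> adversity -> GxE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adversity import AdversityRuleSet, compute_adversity_score
from .eprs import compute_eprs, ld_clump, merge_with_eqtl
from .genotypes import GenotypeMatrix
from .gxe import GxeFitResult, compute_population_pcs, fit_interaction_model, ld_prune
from .network_build import (
    collect_gene_snps,
    filter_coexpressed,
    filter_developmental,
    map_orthologs,
)


@dataclass
class PipelineResult:
    gene_set: pd.DataFrame
    weights: pd.DataFrame
    scores: pd.DataFrame
    adversity: pd.DataFrame
    pcs: pd.DataFrame | None
    fit: GxeFitResult


def build_gene_set(
    coexpression: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    developmental: pd.DataFrame | None,
    coexpr_threshold: float = 0.5,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Co-expression filter, ortholog mapping, developmental filter."""
    genes = filter_coexpressed(coexpression, threshold=coexpr_threshold)
    genes = map_orthologs(genes, ortholog_map)
    return filter_developmental(genes, developmental, fold_threshold=fold_threshold)


def build_eprs(
    genotypes: GenotypeMatrix,
    gene_set: pd.DataFrame,
    annotation: pd.DataFrame,
    eqtl: pd.DataFrame,
    r2_threshold: float = 0.25,
    standardize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP harvest, eQTL merge, LD clump, score.  Returns (weights, scores)."""
    candidates = collect_gene_snps(gene_set, annotation, genotypes.variants)
    merged = merge_with_eqtl(candidates, eqtl, genotypes)
    weights = ld_clump(merged, genotypes, r2_threshold=r2_threshold)
    scores = compute_eprs(genotypes, weights, standardize=standardize)
    return weights, scores


def run_pipeline(
    genotypes: GenotypeMatrix,
    coexpression: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    developmental: pd.DataFrame | None,
    annotation: pd.DataFrame,
    eqtl: pd.DataFrame,
    components: pd.DataFrame,
    ruleset: AdversityRuleSet,
    phenotypes: pd.DataFrame,
    outcome: str = "outcome",
    n_pcs: int = 3,
    r2_clump: float = 0.25,
    standardize: bool = False,
) -> PipelineResult:
    """Run the full analysis on already-QCed genotypes.

    Phenotype, component and score tables are aligned on ``subject``.
    With ``n_pcs=0`` the regression runs without ancestry covariates.
    """
    gene_set = build_gene_set(coexpression, ortholog_map, developmental)
    weights, scores = build_eprs(
        genotypes, gene_set, annotation, eqtl,
        r2_threshold=r2_clump, standardize=standardize,
    )
    adversity = compute_adversity_score(components, ruleset)

    merged = phenotypes.merge(scores, on="subject").merge(
        adversity[["subject", "adversity"]], on="subject"
    )
    pcs = None
    pc_block = None
    if n_pcs > 0:
        pruned = ld_prune(genotypes)
        pcs, _ = compute_population_pcs(genotypes, pruned, n_pcs=n_pcs)
        merged = merged.merge(pcs, on="subject")
        pc_block = merged[[c for c in merged.columns if c.startswith("PC")]]
    score_col = "eprs_z" if standardize else "eprs"
    fit = fit_interaction_model(
        outcome=merged[outcome],
        eprs=merged[score_col],
        adversity=merged["adversity"],
        sex=merged["sex"],
        pcs=pc_block,
    )
    return PipelineResult(
        gene_set=gene_set,
        weights=weights,
        scores=scores,
        adversity=adversity,
        pcs=pcs,
        fit=fit,
    )
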
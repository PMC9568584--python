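"""Assembly of the target gene's co-expression gene set.

The pipeline mirrors how a brain-region co-expression network is turned
into a SNP list: keep genes co-expressed with the target at |r| >= 0.5
(recording the sign of r), map source-species genes to human orthologs,
optionally keep only genes over-expressed in early development
(early/adult fold >= 1.5; the step is skippable when no developmental
atlas covers the region), then harvest every genotyped variant lying
inside a surviving gene's annotated interval.

Gene sets are DataFrames with columns ``gene`` (unique ids), ``sign``
(+1/-1 from the co-expression r) and boolean provenance flags.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def filter_coexpressed(coexpr: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Keep genes with |r| >= threshold (boundary inclusive); record sign(r).

    ``coexpr`` has columns ``gene`` and ``r`` with r in [-1, 1].
    """
    if coexpr["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in co-expression table")
    r = coexpr["r"].to_numpy(dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("co-expression r outside [-1, 1]")
    keep = np.abs(r) >= threshold
    out = coexpr.loc[keep, ["gene"]].copy()
    out["r"] = r[keep]
    out["sign"] = np.where(r[keep] < 0, -1, 1).astype(int)
    out["passed_coexpression"] = True
    return out.reset_index(drop=True)


def map_orthologs(genes: pd.DataFrame, ortholog_map: pd.DataFrame) -> pd.DataFrame:
    """Rename source-species genes to human ids, preserving signs.

    ``ortholog_map`` has columns ``source_gene`` and ``human_gene``.
    Unmapped genes are dropped (and logged).  One-to-many mappings expand
    to every human target; when several source genes collapse onto one
    human gene, the row with the largest |r| wins, with ties broken in
    favor of the positive sign.
    """
    merged = genes.merge(ortholog_map, left_on="gene", right_on="source_gene", how="left")
    dropped = merged.loc[merged["human_gene"].isna(), "gene"].tolist()
    if dropped:
        logger.info("ortholog mapping dropped %d genes: %s", len(dropped), dropped[:10])
    mapped = merged.dropna(subset=["human_gene"]).copy()
    mapped["gene"] = mapped["human_gene"]
    mapped["_abs_r"] = mapped["r"].abs() if "r" in mapped.columns else 0.0
    mapped = (
        mapped.sort_values(["gene", "_abs_r", "sign"], ascending=[True, False, False])
        .drop_duplicates(subset="gene", keep="first")
        .drop(columns="_abs_r")
        .reset_index(drop=True)
    )
    out = mapped[[c for c in genes.columns if c in mapped.columns]].copy()
    out["passed_ortholog"] = True
    return out.reset_index(drop=True)


def filter_developmental(
    genes: pd.DataFrame,
    dev_expr: pd.DataFrame | None,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Keep genes over-expressed early in development.

    ``dev_expr`` has columns ``gene``, ``early_expression`` and
    ``adult_expression`` (both > 0); the gene is kept when
    early/adult >= fold_threshold (boundary inclusive).  Passing
    ``dev_expr=None`` skips the stage (no developmental atlas for the
    region) and returns the gene set unchanged.
    """
    if dev_expr is None:
        out = genes.copy()
        out["passed_developmental"] = True
        return out
    if (dev_expr[["early_expression", "adult_expression"]] <= 0).to_numpy().any():
        raise ValueError("expression levels must be positive")
    fold = dev_expr.set_index("gene").eval("early_expression / adult_expression")
    in_table = genes["gene"].isin(fold.index)
    dropped = genes.loc[~in_table, "gene"].tolist()
    if dropped:
        logger.info("developmental filter: %d genes absent from table: %s",
                    len(dropped), dropped[:10])
    kept = genes[in_table].copy()
    keep = fold.loc[kept["gene"]].to_numpy() >= fold_threshold
    out = kept.loc[keep].copy()
    out["passed_developmental"] = True
    return out.reset_index(drop=True)


def collect_gene_snps(
    genes: pd.DataFrame,
    annotation: pd.DataFrame,
    variants: pd.DataFrame,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """List every variant inside a gene's interval, one row per
    (variant, gene) overlap, carrying the gene's co-expression sign.

    ``annotation`` columns: ``gene, chrom, start, end`` (1-based,
    inclusive); ``variants`` columns: ``id, chrom, pos``.  ``flank_bp``
    widens each interval symmetrically (default 0: gene body only).
    Genes missing from the annotation are dropped and logged.
    """
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("gene annotation with start > end")
    ann = genes.merge(annotation, on="gene", how="left")
    missing = ann.loc[ann["chrom"].isna(), "gene"].tolist()
    if missing:
        logger.info("annotation missing for %d genes: %s", len(missing), missing[:10])
        ann = ann.dropna(subset=["chrom"])
    rows = []
    for _, g in ann.iterrows():
        lo = g["start"] - flank_bp
        hi = g["end"] + flank_bp
        hit = variants[(variants["chrom"] == g["chrom"]) &
                       (variants["pos"] >= lo) & (variants["pos"] <= hi)]
        for _, v in hit.iterrows():
            rows.append({"snp": v["id"], "chrom": v["chrom"], "pos": v["pos"],
                         "gene": g["gene"], "sign": g["sign"]})
    cols = ["snp", "chrom", "pos", "gene", "sign"]
    out = pd.DataFrame(rows, columns=cols).drop_duplicates(subset=["snp", "gene"])
    return out.reset_index(drop=True)
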
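"""Expression-based polygenic risk score construction.

Candidate network SNPs are intersected with a cis-eQTL table and the
genotyped variants, effect alleles are harmonized to the genotype ALT
allele (flipping the slope sign when the eQTL effect allele is the REF
allele, using the dosage identity d_REF = 2 - d_ALT), the list is thinned
by greedy LD clumping at an r-squared threshold (default 0.25), and each
subject's score is the dosage-weighted sum

    score_i = sum_j dosage_ij * slope_j * sign_j

where sign_j is the co-expression sign of the SNP's network gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeInputError, GenotypeMatrix

logger = logging.getLogger(__name__)


def merge_with_eqtl(
    candidates: pd.DataFrame,
    eqtl: pd.DataFrame,
    genotypes: GenotypeMatrix,
    signed: bool = True,
) -> pd.DataFrame:
    """Intersect candidate network SNPs with the eQTL table and the
    genotyped variants; harmonize effect alleles to ALT.

    ``candidates``: columns ``snp, gene, sign`` from the SNP harvest.
    ``eqtl``: columns ``snp, gene, effect_allele, other_allele, slope``.
    A SNP is kept only when an eQTL row exists for one of its network
    genes; if several network genes have eQTL rows for the same SNP, the
    row with the largest |slope| is kept (tie: first gene id), so each
    allele contributes once.  SNPs whose effect allele matches neither
    REF nor ALT are dropped and logged.

    Returns the weighted SNP list: ``snp, chrom, pos, gene, effect_allele,
    slope, sign, weight`` with weight = slope * sign (or plain slope when
    ``signed`` is False).
    """
    merged = candidates.merge(eqtl, on=["snp", "gene"], how="inner")
    var = genotypes.variants.rename(columns={"id": "snp"})
    merged = merged.merge(var[["snp", "chrom", "pos", "ref", "alt"]],
                          on="snp", how="inner", suffixes=("_cand", ""))
    rows = []
    for _, row in merged.iterrows():
        ea, oa = row["effect_allele"], row["other_allele"]
        if ea == row["alt"] and oa == row["ref"]:
            slope = row["slope"]
        elif ea == row["ref"] and oa == row["alt"]:
            slope = -row["slope"]  # flip to ALT orientation
        else:
            logger.info("allele mismatch for %s (%s/%s vs %s/%s); dropped",
                        row["snp"], ea, oa, row["ref"], row["alt"])
            continue
        rows.append({"snp": row["snp"], "chrom": row["chrom"], "pos": row["pos"],
                     "gene": row["gene"], "effect_allele": row["alt"],
                     "slope": slope, "sign": int(row["sign"])})
    out = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "gene",
                                      "effect_allele", "slope", "sign"])
    # one row per SNP: largest |slope| wins, tie broken by gene id
    out["_abs"] = out["slope"].abs()
    out = (out.sort_values(["snp", "_abs", "gene"], ascending=[True, False, True])
              .drop_duplicates(subset="snp", keep="first")
              .drop(columns="_abs"))
    out["weight"] = out["slope"] * out["sign"] if signed else out["slope"]
    return out.reset_index(drop=True)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over
    pairwise-complete subjects; 0.0 when either column is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise GenotypeInputError("fewer than 2 complete pairs for r^2")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _clump_order(weights: pd.DataFrame) -> pd.DataFrame:
    """Deterministic clumping priority: |slope| descending, ties by
    (chrom, pos, snp) ascending."""
    w = weights.copy()
    w["_abs"] = w["slope"].abs()
    w = w.sort_values(["_abs", "chrom", "pos", "snp"],
                      ascending=[False, True, True, True], kind="mergesort")
    return w.drop(columns="_abs")


def ld_clump(
    weights: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.25,
) -> pd.DataFrame:
    """Greedy LD clumping of the weighted SNP list.

    Repeatedly takes the highest-priority unremoved SNP as an index and
    removes every other unselected SNP on the same chromosome whose
    dosage r-squared with it is >= the threshold.  Clumping is per
    chromosome with no distance cap.  Output order follows selection.
    """
    if weights.empty:
        return weights.copy()
    ordered = _clump_order(weights)
    idx_map = genotypes.variant_index(ordered["snp"])
    cols = {snp: genotypes.dosage[:, j] for snp, j in zip(ordered["snp"], idx_map)}
    selected = []
    removed: set[str] = set()
    for _, row in ordered.iterrows():
        if row["snp"] in removed:
            continue
        selected.append(row)
        for _, other in ordered.iterrows():
            o = other["snp"]
            if o == row["snp"] or o in removed or other["chrom"] != row["chrom"]:
                continue
            if any(o == s["snp"] for s in selected):
                continue
            if pairwise_r2(cols[row["snp"]], cols[o]) >= r2_threshold:
                removed.add(o)
    return pd.DataFrame(selected).reset_index(drop=True)


def compute_eprs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    standardize: bool = False,
) -> pd.DataFrame:
    """Per-subject weighted dosage sum over the clumped SNP list.

    Missing dosages are replaced by the variant's mean dosage over
    non-missing subjects.  Returns columns ``subject, eprs`` plus
    ``eprs_z`` (sample-SD z-score) when ``standardize`` is True.
    A weight SNP with no observed genotype at all raises an error.
    """
    if weights.empty:
        score = np.zeros(genotypes.n_subjects)
        out = pd.DataFrame({"subject": genotypes.subjects, "eprs": score})
        if standardize:
            out["eprs_z"] = score
        return out
    idx = genotypes.variant_index(weights["snp"])
    dosage = genotypes.dosage[:, idx].copy()
    all_missing = np.all(np.isnan(dosage), axis=0)
    if all_missing.any():
        bad = weights["snp"].to_numpy()[all_missing]
        raise GenotypeInputError(f"weight SNPs with no observed genotypes: {bad[:5]}")
    col_mean = np.nanmean(dosage, axis=0)
    nan_r, nan_c = np.where(np.isnan(dosage))
    dosage[nan_r, nan_c] = col_mean[nan_c]
    score = dosage @ weights["weight"].to_numpy(dtype=float)
    out = pd.DataFrame({"subject": genotypes.subjects, "eprs": score})
    if standardize:
        sd = score.std(ddof=1)
        out["eprs_z"] = (score - score.mean()) / sd if sd > 0 else 0.0
    return out
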
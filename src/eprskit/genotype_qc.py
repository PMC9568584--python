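"""Variant-level genotype quality control.

Three per-variant filters with strict removal boundaries, as used on array
genotypes before score construction: call rate < 95%, Hardy-Weinberg exact
test p below a floor (default 1e-40), and minor allele frequency < 5%.
A variant sitting exactly at a threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeInputError, GenotypeMatrix


@dataclass
class QcThresholds:
    """Removal thresholds, all strict: a variant fails when its statistic is
    strictly below the threshold (or, for HWE, strictly below the floor)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-40

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def variant_call_rate(dosage: np.ndarray) -> float:
    """Fraction of subjects with a non-missing call for one variant."""
    dosage = np.asarray(dosage, dtype=float)
    if dosage.size == 0:
        raise GenotypeInputError("call rate of an empty dosage column")
    return float(np.sum(~np.isnan(dosage)) / dosage.size)


def minor_allele_frequency(dosage: np.ndarray) -> float:
    """MAF from ALT-dosages: min(f, 1-f) with f = mean(dosage)/2 over
    non-missing entries.  Symmetric under allele relabeling."""
    dosage = np.asarray(dosage, dtype=float)
    obs = dosage[~np.isnan(dosage)]
    if obs.size == 0:
        raise GenotypeInputError("MAF of an all-missing dosage column")
    f = float(obs.mean() / 2.0)
    return min(f, 1.0 - f)


def _hwe_weights(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and relative probabilities of the heterozygote count
    conditional on the minor-allele count.

    ``n`` diploid genotypes, ``n_a`` copies of the rarer allele.  The
    heterozygote count shares the parity of ``n_a`` and ranges up to
    min(n_a, 2n - n_a).  Probabilities are returned normalized.
    """
    n_b = 2 * n - n_a
    lo = n_a % 2
    hi = min(n_a, n_b)
    support = np.arange(lo, hi + 1, 2)
    # Float recurrence outward from the conditional mode for stability.
    mode = int(round(n_a * n_b / (2.0 * n - 1.0)))
    if mode % 2 != lo:
        mode += 1 if mode < hi else -1
    mode = min(max(mode, lo), hi)
    probs = np.zeros(support.size)
    mi = (mode - lo) // 2
    probs[mi] = 1.0
    # P(h+2)/P(h) = (na-h)(nb-h) / ((h+2)(h+1)) with haa=(na-h)/2 etc.
    for k in range(mi, probs.size - 1):
        h = support[k]
        probs[k + 1] = probs[k] * (n_a - h) * (n_b - h) / ((h + 2.0) * (h + 1.0))
    for k in range(mi, 0, -1):
        h = support[k]
        probs[k - 1] = probs[k] * h * (h - 1.0) / ((n_a - h + 2.0) * (n_b - h + 2.0))
    probs /= probs.sum()
    return support, probs


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count.  Returns a p-value in (0, 1].
    """
    counts = (n_aa_hom, n_het, n_bb_hom)
    if any(c < 0 for c in counts):
        raise GenotypeInputError(f"negative genotype counts {counts}")
    n = sum(counts)
    if n < 1:
        raise GenotypeInputError("HWE test needs at least one genotype")
    n_a = 2 * n_aa_hom + n_het
    n_a = min(n_a, 2 * n - n_a)
    support, probs = _hwe_weights(n, n_a)
    p_obs = probs[np.searchsorted(support, n_het)] if n_het in support else None
    if p_obs is None:  # parity guaranteed by construction; defensive
        raise GenotypeInputError(f"inconsistent heterozygote count {n_het}")
    # 1 + 1e-12 guard against float ties just above p_obs
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _hard_call_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    obs = dosage[~np.isnan(dosage)]
    return int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2))


def qc_metrics(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant call rate, MAF and HWE exact p-value."""
    n_var = genotypes.n_variants
    call_rate = np.empty(n_var)
    maf = np.empty(n_var)
    hwe_p = np.empty(n_var)
    for j in range(n_var):
        col = genotypes.dosage[:, j]
        call_rate[j] = variant_call_rate(col)
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            maf[j] = np.nan
            hwe_p[j] = np.nan
            continue
        maf[j] = minor_allele_frequency(col)
        hwe_p[j] = hwe_exact_test(*_hard_call_counts(col))
    return pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants failing any filter (strict inequalities).

    Returns the filtered matrix and a per-variant report with pass/fail
    flags per criterion.  Variants with no observed calls fail call rate
    (rate 0 < any positive threshold) and are flagged on that criterion
    only.  The three filters commute: each is evaluated on the input.
    """
    thresholds = thresholds or QcThresholds()
    report = qc_metrics(genotypes)
    report["call_rate_fail"] = report["call_rate"] < thresholds.min_call_rate
    report["maf_fail"] = report["maf"] < thresholds.min_maf
    report["hwe_fail"] = report["hwe_p"] < thresholds.hwe_p_floor
    report["removed"] = report[["call_rate_fail", "maf_fail", "hwe_fail"]].any(axis=1)
    kept = genotypes.subset_variants(~report["removed"].to_numpy())
    return kept, report


def filter_by_info(
    genotypes: GenotypeMatrix, info: pd.Series | dict, min_info: float = 0.8
) -> GenotypeMatrix:
    """Pass-through imputation-quality filter: keep variants whose INFO
    score is strictly above ``min_info``.  Imputation itself is out of
    scope; the scores must be supplied (variant id -> INFO)."""
    info = pd.Series(info)
    missing = [v for v in genotypes.variants["id"] if v not in info.index]
    if missing:
        raise GenotypeInputError(f"INFO scores missing for variants: {missing[:5]}")
    keep = info.loc[genotypes.variants["id"]].to_numpy() > min_info
    return genotypes.subset_variants(keep)


def qc_summary(report: pd.DataFrame) -> dict:
    return {
        "n_variants": int(len(report)),
        "n_removed": int(report["removed"].sum()),
        "n_call_rate_fail": int(report["call_rate_fail"].sum()),
        "n_maf_fail": int(report["maf_fail"].sum()),
        "n_hwe_fail": int(report["hwe_fail"].sum()),
    }
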
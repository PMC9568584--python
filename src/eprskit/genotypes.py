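"""Genotype dosage matrix with variant metadata.

Dosages count copies of the ALT allele (0, 1, 2); missing calls are NaN.
Variant metadata follows VCF conventions: 1-based positions, string
chromosome labels, single REF/ALT alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class GenotypeInputError(ValueError):
    """Raised for malformed genotype matrices or incompatible inputs."""


@dataclass
class GenotypeMatrix:
    """Subjects x variants ALT-allele dosage matrix.

    Parameters
    ----------
    subjects
        Ordered subject identifiers.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (1-based
        positions), one row per variant, aligned with dosage columns.
    dosage
        Float array of shape ``(n_subjects, n_variants)`` with values in
        {0, 1, 2} or NaN for missing calls.
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise GenotypeInputError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise GenotypeInputError(f"variant table missing columns: {missing_cols}")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise GenotypeInputError(f"duplicate variant ids: {dups[:5]}")
        if (self.variants["pos"] < 0).any():
            raise GenotypeInputError("negative variant positions")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise GenotypeInputError("dosage values must be 0, 1, 2 or NaN")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        """Return a new matrix restricted to the variants selected by a
        boolean mask or an array of integer column indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def variant_index(self, snp_ids) -> np.ndarray:
        """Column indices for the given variant ids (error on absence)."""
        lookup = pd.Series(np.arange(self.n_variants), index=self.variants["id"])
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise GenotypeInputError(f"variants absent from matrix: {missing[:5]}")
        return lookup.loc[list(snp_ids)].to_numpy()
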
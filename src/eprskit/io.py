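"""Reading and writing the on-disk formats: VCF v4.2 genotypes and the
annotation / phenotype TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotypes import GenotypeMatrix

_GT_TO_DOSAGE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF v4.2 with GT calls.

    Missing dosages are written as ``./.``; heterozygotes as ``0/1``.
    """
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(genotypes.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    for subj in genotypes.subjects:
        header.add_sample(str(subj))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, var in genotypes.variants.iterrows():
            rec = vcf.new_record(
                contig=str(var["chrom"]),
                start=int(var["pos"]) - 1,  # pysam start is 0-based
                stop=int(var["pos"]),
                alleles=(str(var["ref"]), str(var["alt"])),
                id=str(var["id"]),
            )
            col = genotypes.dosage[:, j]
            for i, subj in enumerate(genotypes.subjects):
                d = col[i]
                if np.isnan(d):
                    gt = (None, None)
                elif d == 0:
                    gt = (0, 0)
                elif d == 1:
                    gt = (0, 1)
                else:
                    gt = (1, 1)
                rec.samples[str(subj)]["GT"] = gt
            vcf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a :class:`GenotypeMatrix`."""
    rows = []
    dosage_cols = []
    with pysam.VariantFile(str(path)) as vcf:
        subjects = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"variant {rec.id} is not biallelic")
            rows.append(
                {
                    "id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam .pos is 1-based
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                }
            )
            col = np.empty(len(subjects))
            for i, subj in enumerate(subjects):
                gt = rec.samples[subj]["GT"]
                col[i] = _GT_TO_DOSAGE.get(gt, np.nan) if gt is not None else np.nan
            dosage_cols.append(col)
    variants = pd.DataFrame(rows)
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)  # match VCF contig labels
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
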
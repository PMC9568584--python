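"""Synthetic study generator with known ground truth.

Every input the pipeline consumes is generated here: block-LD genotypes
(Gaussian-copula haplotypes with AR(1) within-block latent correlation),
a co-expression table with an exact configured fraction of genes passing
|r| >= 0.5, an ortholog map, a developmental expression table with an
exact fraction at early/adult fold >= 1.5, gene intervals, a signed
cis-eQTL table, binary adversity components, and continuous outcomes from
a linear model with planted main, interaction and sex effects.

The planted per-SNP weights are exactly what the score pipeline recovers
under the default layout (one eQTL SNP per LD block, so clumping at
r^2 < 0.25 removes nothing), which makes end-to-end parameter recovery
exact up to sampling noise.  An optional two-subpopulation mode adds
ancestry confounding: allele frequencies diverge between subpopulations
(Balding-Nichols style), adversity prevalence differs, and the outcome
carries an additive subpopulation shift, so that omitting ancestry PCs
inflates the interaction test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .adversity import AdversityRuleSet, ComponentRule, SubRule
from .eprs import compute_eprs
from .genotypes import GenotypeMatrix


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference study: 2000 subjects, 500 variants in
    a 20-gene network, a planted score x adversity interaction of 0.3 and
    unit residual noise.
    """

    n_subjects: int = 2000
    n_variants: int = 500
    n_genes: int = 20
    ld_block_size: int = 10
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    # network filter fractions (counts are exact after rounding)
    frac_coexpressed: float = 0.6
    frac_negative: float = 0.25
    frac_early_enriched: float = 0.7
    ortholog_coverage: float = 0.9
    # eQTL layout
    eqtl_snps_per_block: int = 1
    eqtl_slope_sd: float = 0.35
    eqtl_flip_frac: float = 0.1
    # adversity components
    n_adversity_components: int = 10
    component_prob: float = 0.3
    adversity_dependence: float = 0.0
    # planted outcome model
    intercept: float = 1.0
    beta_g: float = 0.4
    beta_e: float = 0.3
    beta_gxe: float = 0.3
    beta_sex: float = 0.5
    noise_sd: float = 1.0
    # ancestry confounding (off with n_subpops=1)
    n_subpops: int = 1
    fst: float = 0.0
    subpop_outcome_shift: float = 0.0
    subpop_component_probs: tuple[float, ...] | None = None
    subpop_fractions: tuple[float, ...] | None = None
    align_confounding: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_variants < 1 or self.n_genes < 2:
            raise ConfigurationError("need n_subjects >= 2, n_variants >= 1, n_genes >= 2")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("frac_coexpressed", "frac_negative", "frac_early_enriched",
                     "ortholog_coverage", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_adversity_components < 1:
            raise ConfigurationError("need at least one adversity component")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream validation."""

    true_genes: pd.DataFrame  # gene, sign: passes all three filters
    true_weights: pd.DataFrame  # snp, chrom, pos, gene, effect_allele, slope, sign, weight
    true_score: pd.DataFrame  # subject, eprs: the G used to generate outcomes
    betas: dict = field(default_factory=dict)
    subpop: np.ndarray | None = None


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    coexpression: pd.DataFrame
    ortholog_map: pd.DataFrame
    developmental: pd.DataFrame
    annotation: pd.DataFrame
    eqtl: pd.DataFrame
    phenotypes: pd.DataFrame
    components: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome layout

def _layout(config: SimulationConfig) -> pd.DataFrame:
    """Assign each variant a gene, chromosome, position and LD block.

    Variants split as evenly as possible over genes; genes cycle over up
    to 22 chromosomes; positions are 1 kb apart inside a gene with 100 kb
    gaps between genes on the same chromosome.
    """
    n_chrom = min(config.n_genes, 22)
    per_gene = np.full(config.n_genes, config.n_variants // config.n_genes)
    per_gene[: config.n_variants % config.n_genes] += 1
    cursor = {str(c + 1): 1 for c in range(n_chrom)}
    rows = []
    j = 0
    for g in range(config.n_genes):
        chrom = str(g % n_chrom + 1)
        start = cursor[chrom]
        for k in range(per_gene[g]):
            rows.append({
                "id": f"snp{j:05d}",
                "chrom": chrom,
                "pos": start + 1000 * k,
                "ref": "A",
                "alt": "G",
                "gene": f"GENE{g}",
                "block": k // config.ld_block_size,
            })
            j += 1
        cursor[chrom] = start + 1000 * max(per_gene[g], 1) + 100_000
    return pd.DataFrame(rows)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Block-LD genotypes via a Gaussian copula.

    Within each LD block the latent haplotype variables follow an AR(1)
    process with correlation ``ld_rho``; thresholding at the allele-
    frequency quantile yields two haplotypes summed into dosage.  Returns
    (genotype matrix, variant layout incl. gene/block columns, subpop
    labels, per-subpopulation allele frequencies).
    """
    rng = rng or np.random.default_rng(config.seed)
    layout = _layout(config)
    n, m = config.n_subjects, len(layout)
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=m)

    subpop = np.zeros(n, dtype=int)
    if config.n_subpops > 1:
        fracs = config.subpop_fractions or tuple(
            1.0 / config.n_subpops for _ in range(config.n_subpops)
        )
        counts = np.round(np.asarray(fracs) * n).astype(int)
        counts[-1] = n - counts[:-1].sum()
        subpop = rng.permutation(np.repeat(np.arange(config.n_subpops), counts))
    pop_freq = np.tile(freq, (config.n_subpops, 1))
    if config.n_subpops > 1 and config.fst > 0:
        f = config.fst
        for p in range(config.n_subpops):
            a = freq * (1 - f) / f
            b = (1 - freq) * (1 - f) / f
            pop_freq[p] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)

    dosage = np.zeros((n, m))
    # latent AR(1) per (gene, block), two independent haplotypes
    for (_, _), block in layout.groupby(["gene", "block"], sort=False):
        cols = block.index.to_numpy()
        w = len(cols)
        z = rng.standard_normal((2, n, w))
        for t in range(1, w):
            z[:, :, t] = config.ld_rho * z[:, :, t - 1] + np.sqrt(
                1 - config.ld_rho**2
            ) * z[:, :, t]
        thr = stats.norm.ppf(pop_freq[:, cols])  # (n_subpops, w)
        hap = z < thr[subpop][None, :, :]
        dosage[:, cols] = hap.sum(axis=0)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    subjects = [f"S{i:05d}" for i in range(n)]
    variants = layout[["id", "chrom", "pos", "ref", "alt"]].copy()
    gm = GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)
    return gm, layout, subpop, pop_freq


# ---------------------------------------------------------------------------
# annotation tables

def simulate_annotation_tables(
    config: SimulationConfig,
    layout: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Co-expression, ortholog, developmental, annotation and eQTL tables.

    Counts of genes passing each filter equal the rounded configured
    fractions exactly; r and fold values are placed away from the filter
    boundaries.  Every eQTL SNP lies inside its gene's interval; effect
    alleles are the genotype ALT allele except for a configured fraction
    recorded in REF orientation (with the slope sign flipped accordingly),
    to exercise harmonization.
    """
    n_genes = config.n_genes
    genes = np.array([f"GENE{g}" for g in range(n_genes)])
    mouse = np.array([f"Mgene{g}" for g in range(n_genes)])

    n_co = round(config.frac_coexpressed * n_genes)
    co_pass = rng.choice(n_genes, size=n_co, replace=False)
    n_neg = round(config.frac_negative * n_co)
    neg = set(rng.choice(co_pass, size=n_neg, replace=False)) if n_co else set()
    r = rng.uniform(0.05, 0.45, size=n_genes) * rng.choice([-1, 1], size=n_genes)
    r[co_pass] = rng.uniform(0.55, 0.95, size=n_co)
    for g in neg:
        r[g] = -r[g]
    coexpression = pd.DataFrame({"gene": mouse, "r": r})

    n_orth = round(config.ortholog_coverage * n_genes)
    mapped = np.sort(rng.choice(n_genes, size=n_orth, replace=False))
    ortholog_map = pd.DataFrame({"source_gene": mouse[mapped], "human_gene": genes[mapped]})

    n_dev = round(config.frac_early_enriched * n_genes)
    dev_pass = set(rng.choice(n_genes, size=n_dev, replace=False))
    adult = rng.uniform(1.0, 10.0, size=n_genes)
    fold = np.where(
        np.isin(np.arange(n_genes), list(dev_pass)),
        rng.uniform(1.6, 3.0, size=n_genes),
        rng.uniform(0.5, 1.4, size=n_genes),
    )
    developmental = pd.DataFrame(
        {"gene": genes, "early_expression": adult * fold, "adult_expression": adult}
    )

    span = layout.groupby("gene", sort=False).agg(
        chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max")
    ).reset_index()
    annotation = span.rename(columns={"gene": "gene"})[["gene", "chrom", "start", "end"]]

    eqtl_rows = []
    for gene, gvar in layout.groupby("gene", sort=False):
        for _, block in gvar.groupby("block", sort=False):
            k = min(config.eqtl_snps_per_block, len(block))
            chosen = block.iloc[rng.choice(len(block), size=k, replace=False)]
            for _, v in chosen.iterrows():
                slope = 0.0
                while abs(slope) < 0.05:
                    slope = rng.normal(0.0, config.eqtl_slope_sd)
                if rng.random() < config.eqtl_flip_frac:
                    ea, oa, stored = v["ref"], v["alt"], -slope
                else:
                    ea, oa, stored = v["alt"], v["ref"], slope
                eqtl_rows.append({"snp": v["id"], "gene": gene, "effect_allele": ea,
                                  "other_allele": oa, "slope": stored,
                                  "_alt_slope": slope})
    eqtl = pd.DataFrame(eqtl_rows)
    return coexpression, ortholog_map, developmental, annotation, eqtl


# ---------------------------------------------------------------------------
# cohort

def generic_ruleset(n_components: int) -> AdversityRuleSet:
    """Rule set for the generated binary components comp1..compK."""
    return AdversityRuleSet(
        components=[
            ComponentRule(name=f"comp{k + 1}",
                          rules=[SubRule(column=f"comp{k + 1}", comparison="is_true")])
            for k in range(n_components)
        ]
    )


def simulate_cohort(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adversity components and outcomes for an existing genotype matrix.

    Components are Bernoulli; an optional shared latent factor
    (``adversity_dependence`` in [0, 1)) makes them co-occur.  The outcome
    follows

        y = intercept + beta_g G + beta_e A + beta_gxe G*A + beta_sex sex
            + shift * subpop + Normal(0, noise_sd)

    with G the planted true-weight score and A the component sum.  Sex is
    exactly balanced.  Pass a fresh ``rng`` to draw replicate cohorts on
    the same genotypes.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = genotypes.n_subjects
    if len(truth.true_score) != n:
        raise ValueError("truth score does not match genotype subjects")
    k = config.n_adversity_components
    probs = np.full(n, config.component_prob)
    if config.subpop_component_probs is not None and truth.subpop is not None:
        probs = np.asarray(config.subpop_component_probs)[truth.subpop]
    dep = config.adversity_dependence
    u = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, k))
    latent = stats.norm.cdf(dep * u + np.sqrt(1 - dep**2) * e)
    comps = (latent < probs[:, None]).astype(int)
    components = pd.DataFrame(comps, columns=[f"comp{j + 1}" for j in range(k)])
    components.insert(0, "subject", genotypes.subjects)

    sex = np.zeros(n)
    sex[: n // 2] = 1.0
    sex = rng.permutation(sex)
    g = truth.true_score["eprs"].to_numpy()
    a = comps.sum(axis=1).astype(float)
    y = (
        config.intercept
        + config.beta_g * g
        + config.beta_e * a
        + config.beta_gxe * g * a
        + config.beta_sex * sex
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    if truth.subpop is not None and config.subpop_outcome_shift:
        y = y + config.subpop_outcome_shift * truth.subpop
    phenotypes = pd.DataFrame(
        {"subject": genotypes.subjects, "outcome": y, "sex": sex}
    )
    return phenotypes, components


# ---------------------------------------------------------------------------
# full study

def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes, layout, subpop, pop_freq = simulate_genotypes(config, rng)
    coexpression, ortholog_map, developmental, annotation, eqtl = (
        simulate_annotation_tables(config, layout, rng)
    )

    if config.align_confounding and config.n_subpops > 1:
        # orient every eQTL slope so the ALT-oriented effect points the
        # same way as the allele-frequency divergence; the planted score
        # then shifts between subpopulations deterministically instead of
        # averaging out over random slope signs
        col_of = pd.Series(np.arange(len(layout)), index=layout["id"])
        gene_sign = pd.Series(
            np.where(coexpression["r"].to_numpy() < 0, -1.0, 1.0),
            index=[f"GENE{g}" for g in range(config.n_genes)],
        )
        dfreq = pop_freq[1] - pop_freq[0]
        weight_dir = eqtl["_alt_slope"].to_numpy() * gene_sign[eqtl["gene"]].to_numpy()
        flip = dfreq[col_of[eqtl["snp"]].to_numpy()] * weight_dir < 0
        eqtl.loc[flip, ["slope", "_alt_slope"]] *= -1.0

    # ground-truth gene set: passes co-expression, ortholog and
    # developmental filters simultaneously
    sign = pd.Series(np.where(coexpression["r"] < 0, -1, 1),
                     index=[f"GENE{g}" for g in range(config.n_genes)])
    co_ok = set(f"GENE{g}" for g in np.flatnonzero(np.abs(coexpression["r"]) >= 0.5))
    orth_ok = set(ortholog_map["human_gene"])
    fold = developmental["early_expression"] / developmental["adult_expression"]
    dev_ok = set(developmental.loc[fold >= 1.5, "gene"])
    true_gene_ids = sorted(co_ok & orth_ok & dev_ok)
    true_genes = pd.DataFrame(
        {"gene": true_gene_ids, "sign": [int(sign[g]) for g in true_gene_ids]}
    )

    eq = eqtl[eqtl["gene"].isin(true_gene_ids)].copy()
    var = genotypes.variants.set_index("id")
    true_weights = pd.DataFrame(
        {
            "snp": eq["snp"].to_numpy(),
            "chrom": var.loc[eq["snp"], "chrom"].to_numpy(),
            "pos": var.loc[eq["snp"], "pos"].to_numpy(),
            "gene": eq["gene"].to_numpy(),
            "effect_allele": var.loc[eq["snp"], "alt"].to_numpy(),
            "slope": eq["_alt_slope"].to_numpy(),
            "sign": [int(sign[g]) for g in eq["gene"]],
        }
    )
    true_weights["weight"] = true_weights["slope"] * true_weights["sign"]
    true_score = compute_eprs(genotypes, true_weights)

    truth = GroundTruth(
        true_genes=true_genes,
        true_weights=true_weights,
        true_score=true_score,
        betas={
            "intercept": config.intercept,
            "beta_g": config.beta_g,
            "beta_e": config.beta_e,
            "beta_gxe": config.beta_gxe,
            "beta_sex": config.beta_sex,
        },
        subpop=subpop,
    )
    phenotypes, components = simulate_cohort(genotypes, truth, config, rng)
    eqtl_public = eqtl.drop(columns="_alt_slope")
    return SyntheticStudy(
        config=config,
        genotypes=genotypes,
        coexpression=coexpression,
        ortholog_map=ortholog_map,
        developmental=developmental,
        annotation=annotation,
        eqtl=eqtl_public,
        phenotypes=phenotypes,
        components=components,
        truth=truth,
    )


def confounded_config(seed: int, beta_gxe: float = 0.0, **overrides) -> SimulationConfig:
    """Ancestry-confounded study conditions (positive control).

    Two subpopulations (70/30) with Fst 0.2 allele-frequency divergence
    oriented along the planted weights, adversity prevalence 0.2 vs 0.5,
    and a +1.0 additive outcome shift in the minor subpopulation.  Without
    PC adjustment the score x adversity interaction test is materially
    anti-conservative; including ancestry PCs restores nominal size.
    """
    return SimulationConfig(
        seed=seed,
        beta_gxe=beta_gxe,
        n_subpops=2,
        fst=0.2,
        subpop_outcome_shift=1.0,
        subpop_component_probs=(0.2, 0.5),
        subpop_fractions=(0.7, 0.3),
        align_confounding=True,
        **overrides,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Serialize a study: VCF genotypes, TSV tables, JSON manifest."""
    from pathlib import Path

    from .io import write_manifest, write_table, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(study.genotypes, outdir / "genotypes.vcf")
    write_table(study.coexpression, outdir / "coexpression.tsv")
    write_table(study.ortholog_map, outdir / "ortholog_map.tsv")
    write_table(study.developmental, outdir / "developmental.tsv")
    write_table(study.annotation, outdir / "gene_annotation.tsv")
    write_table(study.eqtl, outdir / "eqtl.tsv")
    write_table(study.phenotypes, outdir / "phenotypes.tsv")
    write_table(study.components, outdir / "adversity_components.tsv")
    write_manifest({"config": asdict(study.config)}, outdir / "manifest.json")
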
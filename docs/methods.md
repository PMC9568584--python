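# Methods

This note documents the models implemented by `eprskit`, the choices made
where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Score construction

**Gene-set filters.** The co-expression filter keeps genes with
|r| ≥ 0.5 and the developmental filter keeps genes with early/adult
expression fold ≥ 1.5; both boundaries are inclusive, matching the
"higher or equal to" wording of the protocol the package implements. The
developmental stage is skippable because no developmental expression
atlas covers every brain region (the hypothalamus pipeline omits it).
Ortholog mapping preserves the co-expression sign; one-to-many mappings
expand to every human target, and many-to-one collisions keep the entry
with the largest |r| (ties resolved toward the positive sign). These
collision rules are not dictated by the protocol — any deterministic rule
would do — and are documented here because they affect gene counts.

**SNP harvest.** Variants are assigned to genes by 1-based inclusive
interval overlap with no flanking window by default: the protocol
harvests "SNPs from these genes", i.e. gene bodies. A `flank_bp` argument
exists for sensitivity analyses.

**eQTL merge and harmonization.** A candidate SNP is retained only if it
is genotyped and has a cis-eQTL row for one of its network genes. Effect
alleles are harmonized to the genotype ALT allele; when the eQTL effect
allele equals REF, the slope sign is flipped (the dosage complement
identity d_REF = 2 − d_ALT makes this exact). A SNP that is an eQTL for
several network genes keeps only the row with the largest |slope| (tie:
first gene id alphabetically) so a single allele is never counted twice.
SNPs whose alleles match neither REF nor ALT are dropped with a log
message rather than failing the run: strand-ambiguous or multi-allelic
leftovers are a routine data artifact.

**LD clumping.** Greedy: SNPs are ranked by |slope| descending (ties by
chromosome, position, id ascending); the top unremoved SNP becomes an
index and removes all unselected same-chromosome SNPs with r² ≥ 0.25
against it. The protocol states only "clumping (r² < 0.25)"; since no
association p-values exist in ePRS construction, |slope| is the only
importance measure available for the ranking, and the tie-break makes the
survivor set independent of input row order. Clumping is per chromosome
with no distance cap; r² is the squared Pearson correlation of unphased
dosages (composite LD) over pairwise-complete subjects.

**Scoring.** score_i = Σ_j d_ij w_j with w_j = slope_j × sign_j. Missing
dosages are mean-imputed per variant at scoring time, keeping the
effective SNP count constant across subjects. Both raw and z-standardized
(sample SD, ddof = 1) scores are available because cohort analyses differ
on this; the interaction *t*-statistic is invariant to the choice.

## Quality control

Call rate, MAF and the Hardy–Weinberg exact test are computed per variant
on hard calls, excluding missing genotypes. Removal is strict — a variant
at exactly 95 % call rate or exactly 5 % MAF survives — because the
thresholds are printed as "<95 %" and "<5 %". The HWE test is the exact
conditional test of the heterozygote count given allele counts: the
p-value sums the probabilities of all heterozygote counts (same parity)
whose conditional probability does not exceed the observed one. It is
implemented with a floating-point recurrence outward from the conditional
mode; the test suite verifies it against a full-enumeration
integer-arithmetic oracle for every configuration with ≤ 200 genotypes
(worst relative error ≈ 2e-15). The HWE floor defaults to 1e-40 but is
required configuration, since array-era pipelines differ on it.

## Adversity score

Each component is a cut-off rule over a phenotype column; composite
components (e.g. maternal mental health) are ORs over sub-rules and still
contribute a single point. Cut-offs live in YAML, not code; two presets
mirror the two cohort designs the protocol describes (10 and 7
components). The source table's row alignment between the two cohort
columns is typographically ambiguous for two items, so the presets follow
the accompanying text about which instruments each cohort lacked.
Missing handling is not described in the protocol; here a missing
component contributes 0 but is tracked, and a subject's total is emitted
only with at least `min_nonmissing` observed components (default: all).
An OR component with one firing observed sub-rule scores 1 even if
another sub-rule value is missing; it is missing only when nothing fires
and at least one value is unobserved.

## Interaction analysis

OLS with terms (intercept, ePRS, adversity, ePRS×adversity, sex,
PC1..PCk), listwise deletion, SEs from the unbiased residual variance and
the inverse normal-equations matrix, two-sided t tests and 95 % CIs on
n − p df. The moderators are not mean-centered by default (a flag
centers them; this changes main-effect terms only). Rank-deficient
designs raise an error naming the collinear columns.

Simple slopes follow the standard moderation algebra: slope(g) = β_adv +
β_int·g at g = ePRS mean ± 1 SD, SE(g) = √(var_adv + g²·var_int +
2g·cov), p two-sided on the fit's residual df. The orientation (slope of
adversity at fixed score levels) matches how such interactions are
reported; the identity slope(+1 SD) − slope(−1 SD) = 2·SD·β_int holds
exactly and is tested. Holm's step-down adjustment is applied per outcome
family (statsmodels' implementation behind the module surface).

**Ancestry PCs.** Variants are LD-pruned (sliding windows of 5 SNPs over
50 kb, removing the lower-MAF SNP of any pair with r² > 0.2, iterated to
stability) and the pruned matrix is centered at 2f and scaled by
√(2f(1−f)) before SVD; missing entries are mean-imputed. Components are
ordered by variance with the sign fixed so the largest-|loading| variant
entry is positive. The number of PCs is configuration (default 3); the
explained-variance fractions are returned for scree inspection.

## Network topology

Degrees count adjacent nodes (in/out reported for directed graphs);
betweenness is the unnormalized shortest-path count ratio, endpoints
excluded, unordered pairs on undirected graphs. Hubs/bottlenecks are
nodes strictly above mean + 1 SD of the respective metric; the SD is the
population SD (ddof = 0) by default — the protocol does not specify the
estimator, and the choice shifts thresholds, so it is exposed as an
argument. Edge weights are ignored for shortest paths (they encode
display thickness in the source networks, not distances).

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 2000 subjects, 500 variants split over 20 genes on
20 chromosomes, LD blocks of 10 variants with AR(1) latent correlation
0.6, allele frequencies uniform on [0.1, 0.5], 2 % missing calls, 60 % of
genes passing the co-expression filter (25 % of those negative), 70 %
passing the developmental filter, 90 % ortholog coverage, one eQTL SNP
per LD block with slope ~ N(0, 0.35²) (10 % stored in REF orientation to
exercise harmonization), 10 independent Bernoulli(0.3) adversity
components, and outcome

    y = 1 + 0.4·G + 0.3·A + 0.3·G·A + 0.5·sex + ε,  ε ~ N(0, 1).

Genotypes come from a Gaussian copula: two independent latent AR(1)
haplotypes per block, thresholded at the allele-frequency quantile and
summed. This gives tunable pairwise r² for testing clumping and pruning
but no recombination-map realism, no phasing, and no imputation
uncertainty. Counts of genes passing each filter are exact by
construction (r and fold values are placed away from the 0.5 and 1.5
boundaries), so the generator is informative about filter logic, not
about boundary behavior of real annotation values — boundary semantics
are tested separately with explicit fixtures.

With one eQTL SNP per LD block, cross-block dosage correlation is
negligible and clumping at r² < 0.25 removes nothing, so the pipeline's
reconstructed weights equal the planted ones exactly and end-to-end
parameter recovery is limited only by sampling noise. Replicate analyses
(bias, coverage, null calibration) redraw the cohort — adversity
components, sex, noise — on fixed genotypes, i.e. they condition on the
design matrix, which is the standard frame for OLS calibration and keeps
500-replicate runs in seconds.

Outcomes are continuous Gaussian. The child-eating-behavior instruments
this emulates produce bounded ordinal domain scores; no distributional
description was available, so normality is a modeling choice here, not a
claim about the instruments.

**Ancestry confounding (positive control).** `confounded_config` draws
two subpopulations (70/30) with Balding–Nichols allele-frequency
divergence (Fst 0.2), adversity prevalence 0.2 vs 0.5, and a +1 additive
outcome shift in the minor subpopulation. Two deliberate design points:

- *Unbalanced subpopulations.* With exactly balanced groups, an additive
  group shift cancels out of the product term (the between-group
  component of G·A residualized on G and A is equal in both groups), so
  the interaction test would not inflate however strong the confounding.
  A 70/30 split breaks the symmetry.
- *Aligned divergence.* The score's between-group shift is a signed sum
  Σ w_j·2Δf_j that can cancel by luck for a given seed. With
  `align_confounding` the eQTL slope signs are oriented along the
  frequency divergence, making the score's ancestry shift deterministic
  (≈1.9 SD) so the positive control is reliable across seeds.

Under these conditions the no-PC interaction test rejects at roughly
0.5–0.7 instead of 0.05, and including 3 PCs restores the nominal rate.

## Known limitations

- The generator's gene intervals never overlap, so the multi-gene SNP
  dedup rule is exercised only by explicit unit fixtures.
- LD pruning is O(window²) per window and intended for array-scale
  panels after QC, not sequencing-scale data.
- No robust/sandwich SEs or mixed models; the moderation model is plain
  OLS as in the protocol.
- Imputation (and INFO-score filtering) is out of scope; the QC module
  only passes through an INFO column filter if one is supplied.
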
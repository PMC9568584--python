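"""Gene-by-environment interaction analysis.

Population structure is summarized by principal components of an
LD-pruned genotype matrix (sliding windows of a fixed SNP count over a
physical span, pruning pairs with r^2 above a threshold).  The moderation
model is ordinary least squares,

    outcome ~ 1 + eprs + adversity + eprs:adversity + sex + PC1..PCk,

with two-sided t tests, 95% confidence intervals, simple slopes of
adversity evaluated with the score fixed at its mean +/- 1 SD, and
Holm step-down adjustment across an outcome family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .eprs import pairwise_r2
from .genotypes import GenotypeInputError, GenotypeMatrix

logger = logging.getLogger(__name__)


def ld_prune(
    genotypes: GenotypeMatrix,
    window_kb: float = 50.0,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Windowed LD pruning for PCA: returns surviving variant ids.

    Variants are walked per chromosome in position order.  Each window
    spans ``window_kb`` kilobases starting at every ``step_snps``-th
    variant; within a window, for every pair with r^2 strictly above the
    threshold the lower-MAF variant is removed.  Passes repeat until no
    removal occurs, so the survivor set has no within-window pair above
    the threshold.
    """
    var = genotypes.variants.copy()
    var["_col"] = np.arange(len(var))
    if not var.groupby("chrom", sort=False)["pos"].apply(
        lambda s: s.is_monotonic_increasing
    ).all():
        logger.info("variants not position-sorted; sorting internally")
    var = var.sort_values(["chrom", "pos"], kind="mergesort")

    from .genotype_qc import minor_allele_frequency

    removed: set[str] = set()
    for _, chrom_var in var.groupby("chrom", sort=False):
        ids = chrom_var["id"].to_numpy()
        pos = chrom_var["pos"].to_numpy(dtype=float)
        cols = {i: genotypes.dosage[:, c] for i, c in zip(ids, chrom_var["_col"])}
        maf = {i: minor_allele_frequency(cols[i]) for i in ids}
        r2_cache: dict[tuple[str, str], float] = {}

        def _r2(a: str, b: str) -> float:
            key = (a, b) if a <= b else (b, a)
            if key not in r2_cache:
                r2_cache[key] = pairwise_r2(cols[a], cols[b])
            return r2_cache[key]

        changed = True
        while changed:
            changed = False
            for start in range(0, len(ids), step_snps):
                in_win = [
                    i for i, p in zip(ids, pos)
                    if pos[start] <= p <= pos[start] + window_kb * 1000.0
                    and i not in removed
                ]
                for a_i in range(len(in_win)):
                    for b_i in range(a_i + 1, len(in_win)):
                        a, b = in_win[a_i], in_win[b_i]
                        if a in removed or b in removed:
                            continue
                        if _r2(a, b) > r2_threshold:
                            drop = a if maf[a] <= maf[b] else b
                            removed.add(drop)
                            changed = True
    return [i for i in genotypes.variants["id"] if i not in removed]


def compute_population_pcs(
    genotypes: GenotypeMatrix,
    pruned_ids: list[str] | None = None,
    n_pcs: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (pruned) genotype matrix.

    Each variant is centered at its mean dosage 2f and scaled by the
    binomial SD sqrt(2 f (1-f)); missing entries are mean-imputed (zero
    after centering).  Components are ordered by decreasing variance with
    the sign fixed so each component's largest-|loading| variant entry is
    positive.  Returns (subject x PC score frame, explained-variance
    fractions of the retained components).
    """
    g = genotypes
    if pruned_ids is not None:
        g = g.subset_variants(g.variant_index(pruned_ids))
    if g.n_variants == 0:
        raise GenotypeInputError("empty pruned variant set")
    if n_pcs == 0:
        return pd.DataFrame({"subject": g.subjects}), np.empty(0)
    if g.n_subjects < n_pcs + 1:
        raise GenotypeInputError("need at least n_pcs + 1 subjects")
    x = g.dosage.copy()
    f = np.nanmean(x, axis=0) / 2.0
    scale = np.sqrt(2.0 * f * (1.0 - f))
    with np.errstate(invalid="ignore"):
        observed_sd = np.nanstd(x, axis=0)
    keep = (scale > 0) & (observed_sd > 0)
    if not keep.any():
        raise GenotypeInputError("all pruned variants are constant")
    x = (x[:, keep] - 2.0 * f[keep]) / scale[keep]
    x[np.isnan(x)] = 0.0
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    k = min(n_pcs, s.size)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    explained = (s**2 / np.sum(s**2))[:k]
    out = pd.DataFrame({"subject": g.subjects})
    for j in range(k):
        out[f"PC{j + 1}"] = scores[:, j]
    return out, explained


@dataclass
class GxeFitResult:
    """OLS fit: tidy coefficient table, coefficient covariance, df."""

    params: pd.DataFrame  # term, beta, se, t, p, ci_low, ci_high
    cov: pd.DataFrame  # term x term covariance of the estimates
    n: int
    df_resid: int

    def beta(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "beta"])


def _fit_ols(design: pd.DataFrame, y: np.ndarray) -> GxeFitResult:
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns not adding rank, in order
        bad = []
        cols: list[str] = []
        for c in design.columns:
            trial = design[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")
    model = sm.OLS(y, design)
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "term": design.columns,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }
    )
    return GxeFitResult(
        params=params,
        cov=pd.DataFrame(fit.cov_params(), index=design.columns, columns=design.columns),
        n=int(fit.nobs),
        df_resid=int(fit.df_resid),
    )


def _assemble(
    outcome: pd.Series | np.ndarray,
    columns: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.DataFrame(columns)
    df["_y"] = np.asarray(outcome, dtype=float)
    df = df.dropna()  # listwise deletion
    y = df.pop("_y").to_numpy()
    df.insert(0, "intercept", 1.0)
    if len(df) < df.shape[1] + 2:
        raise GenotypeInputError(
            f"only {len(df)} complete rows for {df.shape[1]} terms"
        )
    return df, y


def fit_interaction_model(
    outcome,
    eprs,
    adversity,
    sex,
    pcs: pd.DataFrame | None = None,
    center_moderators: bool = False,
) -> GxeFitResult:
    """OLS of outcome on score, adversity, their product, sex and PCs.

    ``pcs`` is a frame whose ``PC*`` columns enter as covariates.  With
    ``center_moderators`` the score and adversity are mean-centered
    before the product is formed (changes main-effect terms only; the
    interaction coefficient is identical either way).
    """
    e = np.asarray(eprs, dtype=float)
    a = np.asarray(adversity, dtype=float)
    if center_moderators:
        e = e - np.nanmean(e)
        a = a - np.nanmean(a)
    cols = {"eprs": e, "adversity": a, "eprs:adversity": e * a,
            "sex": np.asarray(sex, dtype=float)}
    if pcs is not None:
        for c in pcs.columns:
            if c.startswith("PC"):
                cols[c] = pcs[c].to_numpy(dtype=float)
    design, y = _assemble(outcome, cols)
    return _fit_ols(design, y)


def fit_main_effect_model(outcome, eprs, covariates: dict | None = None) -> GxeFitResult:
    """OLS of outcome on the score plus covariates (no interaction)."""
    cols = {"eprs": np.asarray(eprs, dtype=float)}
    for name, v in (covariates or {}).items():
        cols[name] = np.asarray(v, dtype=float)
    design, y = _assemble(outcome, cols)
    return _fit_ols(design, y)


def simple_slopes(
    fit: GxeFitResult,
    moderator_mean: float,
    moderator_sd: float,
    slope_term: str = "adversity",
    interaction_term: str = "eprs:adversity",
) -> pd.DataFrame:
    """Slope of ``slope_term`` with the moderator held at mean -/+ 1 SD.

    slope(g) = beta_slope + beta_int * g with
    SE(g) = sqrt(var_slope + g^2 var_int + 2 g cov); two-sided p on the
    fit's residual df.  Returns one row per level (mean-SD, mean, mean+SD).
    """
    for term in (slope_term, interaction_term):
        if term not in fit.cov.index:
            raise KeyError(f"fit lacks term {term!r} (or its covariance)")
    b_s = fit.beta(slope_term)
    b_i = fit.beta(interaction_term)
    var_s = fit.cov.loc[slope_term, slope_term]
    var_i = fit.cov.loc[interaction_term, interaction_term]
    cov_si = fit.cov.loc[slope_term, interaction_term]
    rows = []
    for label, g in (("mean-sd", moderator_mean - moderator_sd),
                     ("mean", moderator_mean),
                     ("mean+sd", moderator_mean + moderator_sd)):
        slope = b_s + b_i * g
        se = float(np.sqrt(var_s + g * g * var_i + 2.0 * g * cov_si))
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
        rows.append({"level": label, "moderator_value": g, "slope": slope,
                     "se": se, "t": t, "p": p})
    return pd.DataFrame(rows)


def holm_adjust(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Holm step-down adjustment mapped back to input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) p_(j)) over the sorted
    p-values; a hypothesis is rejected while its adjusted p <= alpha.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "p_holm": [], "reject": []})
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return pd.DataFrame({"p": p, "p_holm": p_adj, "reject": reject})
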
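"""Interaction regression, PCs, pruning, simple slopes, Holm adjustment."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from eprskit.genotypes import GenotypeInputError
from eprskit.gxe import (
    compute_population_pcs,
    fit_interaction_model,
    fit_main_effect_model,
    holm_adjust,
    ld_prune,
    simple_slopes,
)
from eprskit.eprs import pairwise_r2
from eprskit.synthetic_data import SimulationConfig, simulate_genotypes

from conftest import make_matrix
from oracles import ols_exact


class TestLdPrune:
    def test_uncorrelated_nothing_pruned(self, rng):
        gm = make_matrix(rng.binomial(2, 0.4, size=(500, 8)).astype(float))
        assert len(ld_prune(gm)) == 8

    def test_perfect_pair_keeps_one(self, rng):
        x = rng.binomial(2, 0.4, size=(200,)).astype(float)
        y = rng.binomial(2, 0.2, size=(200,)).astype(float)
        gm = make_matrix(np.column_stack([x, x, y]), ids=["a", "b", "c"])
        kept = ld_prune(gm)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_block_survivors_pass_all_pairs_check(self):
        cfg = SimulationConfig(n_subjects=800, n_variants=30, n_genes=2,
                               ld_rho=0.8, ld_block_size=10, missing_rate=0.0,
                               seed=13)
        gm, _, _, _ = simulate_genotypes(cfg)
        kept = ld_prune(gm, window_kb=50, step_snps=5, r2_threshold=0.2)
        assert 0 < len(kept) < 30
        idx = {i: j for j, i in enumerate(gm.variants["id"])}
        chrom = dict(zip(gm.variants["id"], gm.variants["chrom"]))
        pos = dict(zip(gm.variants["id"], gm.variants["pos"]))
        for a in kept:
            for b in kept:
                if a >= b or chrom[a] != chrom[b]:
                    continue
                if abs(pos[a] - pos[b]) <= 50_000:
                    r2 = pairwise_r2(gm.dosage[:, idx[a]], gm.dosage[:, idx[b]])
                    assert r2 <= 0.2 + 1e-12


class TestPopulationPcs:
    def test_pc1_separates_subpopulations(self):
        cfg = SimulationConfig(n_subjects=400, n_variants=100, n_genes=5,
                               n_subpops=2, fst=0.3, missing_rate=0.0, seed=17)
        gm, _, subpop, _ = simulate_genotypes(cfg)
        pcs, _ = compute_population_pcs(gm, n_pcs=2)
        r = np.corrcoef(pcs["PC1"], subpop)[0, 1]
        assert abs(r) > 0.9

    def test_zero_pcs_empty_block(self, random_matrix):
        pcs, explained = compute_population_pcs(random_matrix, n_pcs=0)
        assert [c for c in pcs.columns if c.startswith("PC")] == []
        assert explained.size == 0

    def test_explained_variance_monotone(self, random_matrix):
        _, explained = compute_population_pcs(random_matrix, n_pcs=5)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1.0 + 1e-12

    def test_constant_matrix_rejected(self):
        gm = make_matrix(np.ones((10, 3)))
        with pytest.raises(GenotypeInputError):
            compute_population_pcs(gm, n_pcs=1)


class TestInteractionFit:
    def test_zero_noise_exact(self, rng):
        n = 100
        g = rng.normal(size=n)
        a = rng.integers(0, 5, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 1.0 + 0.4 * g + 0.3 * a + 0.25 * g * a + 0.5 * sex
        fit = fit_interaction_model(y, g, a, sex)
        assert fit.beta("eprs:adversity") == pytest.approx(0.25, abs=1e-8)
        assert fit.beta("intercept") == pytest.approx(1.0, abs=1e-8)

    def test_twelve_row_exact_arithmetic_oracle(self):
        g = [2, 0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0]
        a = [0, 1, 2, 3, 4, 5, 0, 1, 2, 3, 4, 5]
        sex = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        y = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8]
        fit = fit_interaction_model(np.array(y, float), np.array(g, float),
                                    np.array(a, float), np.array(sex, float))
        rows = [[1, g[i], a[i], g[i] * a[i], sex[i]] for i in range(12)]
        exact = [float(b) for b in ols_exact(rows, y)]
        np.testing.assert_allclose(fit.params["beta"], exact, atol=1e-10)

    def test_null_interaction_calibrated(self, rng):
        n = 300
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            g = rng.normal(size=n)
            a = rng.binomial(5, 0.4, size=n).astype(float)
            sex = rng.integers(0, 2, size=n).astype(float)
            y = 0.2 * g + 0.3 * a + 0.5 * sex + rng.normal(size=n)
            fit = fit_interaction_model(y, g, a, sex)
            p = fit.params.set_index("term").loc["eprs:adversity", "p"]
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.075

    def test_residuals_orthogonal_to_design(self, rng):
        n = 200
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.3 * g * a + rng.normal(size=n)
        fit = fit_interaction_model(y, g, a, sex)
        design = np.column_stack([np.ones(n), g, a, g * a, sex])
        betas = fit.params["beta"].to_numpy()
        resid = y - design @ betas
        dots = design.T @ resid / n
        assert np.max(np.abs(dots)) < 1e-8

    def test_rank_deficient_design_names_terms(self, rng):
        n = 50
        g = rng.normal(size=n)
        a = g.copy()  # adversity duplicates the score
        with pytest.raises(np.linalg.LinAlgError, match="adversity"):
            fit_interaction_model(rng.normal(size=n), g, a,
                                  rng.integers(0, 2, n).astype(float))

    def test_listwise_deletion(self, rng):
        n = 60
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        y[:5] = np.nan
        fit = fit_interaction_model(y, g, a, sex)
        assert fit.n == 55

    def test_centering_leaves_interaction_unchanged(self, rng):
        n = 150
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.4 * g + 0.3 * a + 0.2 * g * a + rng.normal(size=n)
        f0 = fit_interaction_model(y, g, a, sex)
        f1 = fit_interaction_model(y, g, a, sex, center_moderators=True)
        assert f0.beta("eprs:adversity") == pytest.approx(
            f1.beta("eprs:adversity"), abs=1e-10
        )


class TestMainEffectModel:
    def test_exact_recovery_zero_noise(self, rng):
        n = 80
        g = rng.normal(size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 2.0 + 0.7 * g + 0.5 * sex
        fit = fit_main_effect_model(y, g, {"sex": sex})
        assert fit.beta("eprs") == pytest.approx(0.7, abs=1e-8)

    def test_equals_restricted_interaction_design(self, rng):
        # with the adversity and product columns removed, the main-effect
        # model is the same regression
        n = 120
        g = rng.normal(size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.5 * g + 0.3 * sex + rng.normal(size=n)
        main = fit_main_effect_model(y, g, {"sex": sex})
        import statsmodels.api as sm

        design = pd.DataFrame({"intercept": 1.0, "eprs": g, "sex": sex})
        ref = sm.OLS(y, design).fit()
        np.testing.assert_allclose(main.params["beta"],
                                   ref.params.to_numpy(), atol=1e-12)


class TestSimpleSlopes:
    def fit(self, rng, beta_int=0.2, n=300):
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.4 * g + 0.3 * a + beta_int * g * a + 0.5 * sex + rng.normal(size=n)
        return fit_interaction_model(y, g, a, sex), g

    def test_linear_identity(self, rng):
        fit, g = self.fit(rng)
        ss = simple_slopes(fit, moderator_mean=0.0, moderator_sd=2.0)
        b_adv = fit.beta("adversity")
        b_int = fit.beta("eprs:adversity")
        assert ss.set_index("level").loc["mean+sd", "slope"] == pytest.approx(
            b_adv + 2.0 * b_int
        )
        hi = ss.set_index("level").loc["mean+sd", "slope"]
        lo = ss.set_index("level").loc["mean-sd", "slope"]
        assert hi - lo == pytest.approx(2 * 2.0 * b_int, abs=1e-12)

    def test_reparameterization_equivalence(self, rng):
        # slope at mean+SD equals the adversity coefficient after shifting
        # the moderator by -(mean+SD)
        n = 300
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 0.4 * g + 0.3 * a + 0.2 * g * a + 0.5 * sex + rng.normal(size=n)
        fit = fit_interaction_model(y, g, a, sex)
        m, sd = g.mean(), g.std(ddof=1)
        ss = simple_slopes(fit, m, sd).set_index("level")
        shifted = fit_interaction_model(y, g - (m + sd), a, sex)
        assert ss.loc["mean+sd", "slope"] == pytest.approx(
            shifted.beta("adversity"), abs=1e-10
        )
        assert ss.loc["mean+sd", "se"] == pytest.approx(
            shifted.params.set_index("term").loc["adversity", "se"], abs=1e-10
        )

    def test_null_interaction_equal_slopes(self, rng):
        fit, _ = self.fit(rng)
        # force beta_int to zero by zeroing covariance contribution: use a
        # fit whose interaction is null instead
        n = 300
        g = rng.normal(size=n)
        a = rng.binomial(5, 0.4, size=n).astype(float)
        y = 0.3 * a + rng.normal(size=n)
        f = fit_interaction_model(y, g, a, rng.integers(0, 2, n).astype(float))
        b_int = f.beta("eprs:adversity")
        ss = simple_slopes(f, 0.0, 1.0).set_index("level")
        assert ss.loc["mean+sd", "slope"] - ss.loc["mean-sd", "slope"] == pytest.approx(
            2 * b_int, abs=1e-12
        )

    def test_missing_terms_rejected(self, rng):
        n = 60
        g = rng.normal(size=n)
        fit = fit_main_effect_model(0.5 * g + rng.normal(size=n), g)
        with pytest.raises(KeyError):
            simple_slopes(fit, 0.0, 1.0)


class TestHolm:
    def test_single_p_unchanged(self):
        out = holm_adjust([0.03])
        assert out["p_holm"].iloc[0] == pytest.approx(0.03)

    def test_step_down_hand_example(self):
        # sorted: 0.01, 0.03, 0.04 -> 3*0.01=0.03, 2*0.03=0.06, max(...)=0.06
        out = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(out["p_holm"], [0.03, 0.06, 0.06])

    def test_all_ones(self):
        out = holm_adjust([1.0, 1.0, 1.0])
        assert (out["p_holm"] == 1.0).all()
        assert not out["reject"].any()

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(1e-6, 1, size=20)
        out = holm_adjust(p)
        assert (out["p_holm"] >= out["p"] - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(out["p_holm"].to_numpy()[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])
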
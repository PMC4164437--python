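"""Unit and property tests for the proportional-odds score/LRT engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.testing import assert_allclose

import poassoc as pa
from poassoc.ordinal import GenotypePOModel, POModelParams

from conftest import random_instance


# ---------------------------------------------------------------------------
# null fit
# ---------------------------------------------------------------------------

class TestNullFit:
    def test_proportions_and_weights(self):
        nf = pa.fit_null([0, 0, 1, 2])
        assert nf.proportions == (0.5, 0.25, 0.25)
        assert nf.gamma1 == 0.5 and nf.gamma2 == 0.75
        assert_allclose(nf.weights, (0.5, -0.25, -0.75))

    def test_balanced_marker(self):
        nf = pa.fit_null([0, 0, 1, 1, 2, 2])
        assert_allclose(nf.proportions, (1 / 3, 1 / 3, 1 / 3))
        assert_allclose(nf.weights, (2 / 3, 0.0, -2 / 3), atol=1e-15)
        assert_allclose(nf.wbar, 8 / 27)

    def test_null_loglik_is_trinomial_maximum(self):
        nf = pa.fit_null([0, 0, 1, 1, 2, 2])
        assert_allclose(nf.loglik, 6 * math.log(1 / 3))

    @pytest.mark.parametrize("bad", [[1, 1, 1, 1], [0.0] * 5, [2] * 3])
    def test_monomorphic_raises(self, bad):
        with pytest.raises(pa.DegenerateMarkerError):
            pa.fit_null(bad)

    def test_empty_and_invalid_codes_raise(self):
        with pytest.raises(ValueError):
            pa.fit_null([])
        with pytest.raises(ValueError, match="dosage"):
            pa.fit_null([0, 0.5, 1, 2])

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_weight_sum_is_exactly_zero(self, codes):
        """The score weights have sample mean zero: sum_i c(G_i) = 0."""
        if len(set(codes)) < 2:
            codes = codes + [0, 1]
        nf = pa.fit_null(codes)
        c = np.array(nf.weights)[np.asarray(codes)]
        assert abs(c.sum()) < 1e-10 * max(1, len(codes))


# ---------------------------------------------------------------------------
# score vector / variance / test
# ---------------------------------------------------------------------------

class TestScoreTest:
    def test_score_vector_worked_example(self, worked_example):
        G, y = worked_example
        assert_allclose(pa.score_vector(G, y), [-4 / 3])

    def test_score_vector_constant_phenotype_is_zero(self):
        G = [0, 0, 1, 1, 2, 2]
        assert_allclose(pa.score_vector(G, np.full(6, 3.7)), [0.0], atol=1e-14)

    def test_score_vector_balanced_design_cancels(self):
        U = pa.score_vector([0, 1, 2, 0, 1, 2], [0, 1, 0, 1, 0, 1])
        assert_allclose(U, [0.0], atol=1e-14)

    def test_score_vector_uncentered_equivalence(self, worked_example):
        G, y = worked_example
        assert_allclose(pa.score_vector(G, y), pa.score_vector(G, y + 100.0))

    def test_score_variance_worked_example(self, worked_example):
        G, y = worked_example
        assert_allclose(pa.score_variance(G, y), [[4 / 9]])

    def test_score_variance_quadratic_scaling(self, worked_example):
        G, y = worked_example
        assert_allclose(pa.score_variance(G, 3.0 * y),
                        9.0 * pa.score_variance(G, y))

    def test_collinear_phenotypes_raise(self, worked_example):
        G, y = worked_example
        Y = np.column_stack([y, 2 * y])
        with pytest.raises(pa.CollinearPhenotypesError):
            pa.score_test(G, Y)

    def test_pseudo_inverse_mode_uses_rank_df(self, worked_example):
        G, y = worked_example
        Y = np.column_stack([y, 2 * y])
        res = pa.score_test(G, Y, pseudo_inverse=True)
        assert res.df == 1
        assert_allclose(res.statistic, 4.0)

    def test_worked_example_statistic(self, worked_example):
        G, y = worked_example
        res = pa.score_test(G, y)
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_case_control_table_example(self, cc_table):
        res = pa.score_test_from_table(cc_table)
        nf_expected = (0.375, 0.25, 0.375)
        assert_allclose(res.U, [-6.25])
        assert_allclose(res.V, [[5.859375]])
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        # table path agrees with the expanded-vector path exactly
        G = np.repeat([0, 1, 2, 0, 1, 2], cc_table.ravel().astype(int))
        y = np.repeat([0, 0, 0, 1, 1, 1], cc_table.ravel().astype(int))
        full = pa.score_test(G, y)
        assert_allclose(full.statistic, res.statistic)
        assert full.n_used == res.n_used == 80
        assert pa.fit_null(G).proportions == nf_expected

    def test_monomorphic_marker_flagged_not_raised(self):
        res = pa.score_test([1, 1, 1, 1], [0.0, 1.0, 0.0, 1.0])
        assert res.status == "monomorphic"
        assert res.p_value is None and res.statistic is None

    def test_missing_data_complete_case(self, worked_example):
        G, y = worked_example
        G2 = np.concatenate([G, [np.nan, 2]])
        y2 = np.concatenate([y, [1.0, np.nan]])
        m = GenotypePOModel(G2, y2)
        assert m.n_dropped == 2 and m.nobs == 6
        assert_allclose(m.score_test().statistic, 4.0)

    def test_affine_invariance(self):
        """T is unchanged by any invertible affine map of the phenotypes."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            G, Y = random_instance(rng, q=3)
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            b = rng.normal(size=3)
            t0 = pa.score_test(G, Y).statistic
            t1 = pa.score_test(G, Y @ A.T + b).statistic
            assert t1 == pytest.approx(t0, rel=1e-8)

    def test_allele_flip_invariance(self):
        """Recoding G -> 2-G permutes the weights but leaves T, df, p alone."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            G, Y = random_instance(rng)
            r0, r1 = pa.score_test(G, Y), pa.score_test(2.0 - G, Y)
            assert r1.statistic == pytest.approx(r0.statistic, rel=1e-10)
            assert r1.df == r0.df
            c0 = np.array(pa.fit_null(G).weights)
            c1 = np.array(pa.fit_null(2.0 - G).weights)
            assert_allclose(c1, -c0[::-1], atol=1e-12)

    def test_two_category_reduction_matches_binary_logistic(self):
        """With one genotype class absent the statistic is the binary
        logistic-regression score test on the remaining two classes."""
        rng = np.random.default_rng(13)
        G = rng.integers(0, 2, 150).astype(float)  # classes 0/1 only
        y = rng.normal(size=150) + 0.4 * G
        res = pa.score_test(G, y)
        gbar, ybar = G.mean(), y.mean()
        U = float((G - gbar) @ (y - ybar))
        V = gbar * (1 - gbar) * float(((y - ybar) ** 2).sum())
        assert res.statistic == pytest.approx(U ** 2 / V, rel=1e-10)

    def test_null_calibration_permutation(self, worked_example):
        """Under independent phenotypes T is approximately chi2(q)."""
        rng = np.random.default_rng(14)
        G = rng.integers(0, 3, 400).astype(float)
        stats = np.array([
            pa.score_test(G, rng.normal(size=400)).statistic
            for _ in range(400)
        ])
        assert stats.mean() == pytest.approx(1.0, abs=0.2)  # E chi2_1 = 1
        assert (stats > 3.841).mean() == pytest.approx(0.05, abs=0.04)


# ---------------------------------------------------------------------------
# likelihood, gradient oracle, MLE, LRT
# ---------------------------------------------------------------------------

def _numeric_gradient_beta(G, Y, a1, a2, eps=1e-5):
    q = Y.shape[1]
    grad = np.empty(q)
    for k in range(q):
        step = np.zeros(q)
        step[k] = eps
        up = pa.po_loglik(G, Y, POModelParams(a1, a2, step))
        dn = pa.po_loglik(G, Y, POModelParams(a1, a2, -step))
        grad[k] = (up - dn) / (2 * eps)
    return grad


class TestLikelihood:
    def test_loglik_at_null_mle_is_trinomial(self, worked_example):
        G, y = worked_example
        nf = pa.fit_null(G)
        ll = pa.po_loglik(G, y, POModelParams(*nf.alpha, np.zeros(1)))
        assert ll == pytest.approx(nf.loglik, rel=1e-12)
        assert ll == pytest.approx(6 * math.log(1 / 3), rel=1e-12)

    def test_loglik_outside_support_is_minus_inf(self):
        # alpha1 >= alpha2 is rejected at construction...
        with pytest.raises(ValueError):
            POModelParams(1.0, 0.0, [0.0])
        # ...and a category emptied by saturation yields -inf, not an error
        G = [0, 1, 2]
        ll = pa.po_loglik(G, [0.0, 0.0, 0.0], POModelParams(500.0, 501.0, [0.0]))
        assert ll == -np.inf

    def test_score_vector_is_gradient_of_loglik(self):
        """The closed-form U is the likelihood gradient in beta at the null
        MLE (the anchor pinning the statistic to the model)."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            G, Y = random_instance(rng)
            nf = pa.fit_null(G)
            U = pa.score_vector(G, Y)
            num = _numeric_gradient_beta(G, Y, *nf.alpha)
            assert_allclose(U, num, rtol=1e-6, atol=1e-7)

    def test_analytic_score_and_hessian_match_numeric(self):
        rng = np.random.default_rng(22)
        G, Y = random_instance(rng, n=80, q=2)
        m = GenotypePOModel(G, Y)
        theta = np.array([-0.3, 0.8, 0.2, -0.1])
        eps = 1e-6
        num_grad = np.empty(4)
        for k in range(4):
            e = np.zeros(4); e[k] = eps
            num_grad[k] = (m.loglike(theta + e) - m.loglike(theta - e)) / (2 * eps)
        assert_allclose(m.score(theta), num_grad, rtol=1e-5, atol=1e-6)
        num_hess = np.empty((4, 4))
        for k in range(4):
            e = np.zeros(4); e[k] = eps
            num_hess[k] = (m.score(theta + e) - m.score(theta - e)) / (2 * eps)
        assert_allclose(m.hessian(theta), num_hess, rtol=1e-4, atol=1e-5)


class TestMLE:
    # a fixed 12-observation dataset for the brute-force oracle
    G12 = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 0, 1, 2], dtype=float)
    Y12 = np.array([-1.2, 0.3, -0.5, 0.1, 0.4, 1.1, -0.2, 0.9, 1.5,
                    -0.7, 0.0, 0.6])[:, None]

    def test_null_constrained_fit_closed_form(self):
        nf = pa.fit_null(self.G12)
        m = GenotypePOModel(self.G12, self.Y12)
        ll0 = m.loglike(np.concatenate([nf.alpha, [0.0]]))
        assert ll0 == pytest.approx(nf.loglik, rel=1e-12)

    def test_mle_matches_grid_search_oracle(self):
        """Newton's optimum matches a brute-force profile search to 1e-4."""
        m = GenotypePOModel(self.G12, self.Y12)
        res = m.fit()
        assert res.converged
        # coarse-to-fine grid search, independent of the Newton path
        best = (-np.inf, None)
        lo = np.array([-4.0, -3.0, -4.0])
        hi = np.array([3.0, 4.0, 4.0])
        for _ in range(7):
            a1s = np.linspace(lo[0], hi[0], 11)
            a2s = np.linspace(lo[1], hi[1], 11)
            bs = np.linspace(lo[2], hi[2], 11)
            for a1 in a1s:
                for a2 in a2s:
                    if a1 >= a2:
                        continue
                    for b in bs:
                        ll = m.loglike([a1, a2, b])
                        if ll > best[0]:
                            best = (ll, np.array([a1, a2, b]))
            span = (hi - lo) / 10
            lo, hi = best[1] - span, best[1] + span
        assert res.llf == pytest.approx(best[0], abs=1e-6)
        assert_allclose(res.params, best[1], atol=1e-4)

    def test_mle_matches_statsmodels_ordered_model(self):
        """Independent cross-check: statsmodels' ordinal regression reaches
        the same maximised likelihood."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(31)
        G = rng.integers(0, 3, 300)
        Y = rng.normal(size=(300, 2))
        Y[:, 0] += 0.3 * G
        ours = GenotypePOModel(G, Y).fit()
        sm = OrderedModel(G, Y, distr="logit").fit(method="bfgs", disp=False)
        assert ours.llf == pytest.approx(sm.llf, abs=1e-5)
        # statsmodels models P(G<=j) = F(cut_j - y b): slopes are negated
        assert_allclose(ours.params[2:], -np.asarray(sm.params)[:2], atol=1e-4)

    def test_parameter_recovery_large_n(self):
        """Simulated data with known beta: estimate within 3 SEs."""
        rng = np.random.default_rng(32)
        n = 20000
        beta_true = 0.35
        y = rng.normal(size=n)
        F1 = 1 / (1 + np.exp(-(-0.6 + beta_true * y)))
        F2 = 1 / (1 + np.exp(-(0.7 + beta_true * y)))
        u = rng.uniform(size=n)
        G = np.where(u < F1, 0, np.where(u < F2, 1, 2))
        res = GenotypePOModel(G, y).fit()
        assert res.converged
        se = res.bse[2]
        assert abs(res.params[2] - beta_true) < 3 * se

    def test_empty_heterozygote_class_fits(self):
        """No-heterozygote data reduce to 0-vs-2 binary logistic; the tied
        intercepts still yield a finite, converged fit."""
        rng = np.random.default_rng(33)
        G = rng.choice([0.0, 2.0], size=100)
        y = rng.normal(size=100)
        res = GenotypePOModel(G, y).fit()
        assert res.converged
        assert np.isfinite(res.llf)

    def test_empty_homozygote_class_matches_binary_logistic(self):
        from statsmodels.api import Logit, add_constant

        rng = np.random.default_rng(34)
        G = rng.integers(0, 2, 200).astype(float)
        y = rng.normal(size=200) + 0.3 * G
        res = GenotypePOModel(G, y).fit()
        sm = Logit(G, add_constant(y)).fit(disp=False)
        assert res.converged
        assert res.llf == pytest.approx(sm.llf, abs=1e-6)

    def test_summary_mentions_fit_quality(self):
        rng = np.random.default_rng(35)
        G, Y = random_instance(rng, n=60, q=1)
        text = GenotypePOModel(G, Y, phenotype_names=["bmi"]).fit().summary()
        assert "log-likelihood" in text and "beta[bmi]" in text

    def test_from_dataframe_roundtrip(self, worked_example):
        import pandas as pd

        G, y = worked_example
        df = pd.DataFrame({"geno": G, "trait": y})
        m = GenotypePOModel.from_dataframe(df, "geno")
        assert m.phenotype_names == ["trait"]
        assert_allclose(m.score_test().statistic, 4.0)


class TestLRT:
    def test_statistic_nonnegative_and_chisq_df(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            G, Y = random_instance(rng)
            res = pa.lrt_test(G, Y)
            assert res.converged
            assert res.statistic >= 0.0
            assert res.df == Y.shape[1]

    def test_score_lrt_asymptotic_agreement(self):
        """Score and LRT p-values are nearly identical at large n."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(42)
        p_score, p_lrt = [], []
        for _ in range(150):
            G = rng.integers(0, 3, 2000)
            y = rng.normal(size=2000)
            p_score.append(pa.score_test(G, y).p_value)
            p_lrt.append(pa.lrt_test(G, y).p_value)
        rho = spearmanr(p_score, p_lrt).statistic
        assert rho > 0.99

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(43)
        pvals = []
        for _ in range(200):
            G = rng.integers(0, 3, 300)
            y = rng.normal(size=300)
            pvals.append(pa.lrt_test(G, y).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_table_fast_path_matches_expanded(self, cc_table):
        fast = pa.lrt_test_from_table(cc_table)
        counts = cc_table.ravel().astype(int)
        G = np.repeat([0, 1, 2, 0, 1, 2], counts)
        y = np.repeat([0, 0, 0, 1, 1, 1], counts)
        full = pa.lrt_test(G, y)
        assert fast.statistic == pytest.approx(full.statistic, abs=1e-8)
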
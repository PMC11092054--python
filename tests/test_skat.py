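import numpy as np
import pytest

from ibdpd.skat import (
    DEFAULT_RHO_GRID,
    beta_maf_weights,
    fit_null,
    gene_skat_o,
    genomic_inflation,
    neutral_model_check,
    pvalue_mixture_chisq,
    q_statistic,
    skato_test,
)


@pytest.fixture(scope="module")
def intercept_null():
    rng = np.random.default_rng(0)
    n = 400
    y = (rng.random(n) < 0.3).astype(float)
    return fit_null(y, np.ones((n, 1)))


class TestFitNull:
    def test_intercept_only_fits_case_fraction(self):
        y = np.array([1.0] * 20 + [0.0] * 80)
        null = fit_null(y, np.ones((100, 1)))
        np.testing.assert_allclose(null.mu, 0.2, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
        y = (rng.random(n) < 0.4).astype(float)
        null = fit_null(y, X)
        np.testing.assert_allclose(X.T @ null.resid, 0.0, atol=1e-6)

    def test_matches_grid_oracle_small(self):
        # 10-sample intercept+slope toy vs brute-force likelihood grid
        y = np.array([1, 0, 1, 0, 0, 1, 0, 0, 1, 0], dtype=float)
        x = np.array([2, 2, 1, 1, 1, 0, 0, 0, 2, 0], dtype=float)
        X = np.column_stack([np.ones(10), x])
        null = fit_null(y, X)

        def ll(b0, b1):
            eta = b0 + b1 * x
            return float(y @ eta - np.log1p(np.exp(eta)).sum())

        b0s = np.linspace(-5, 5, 201)
        b1s = np.linspace(-5, 5, 201)
        vals = np.array([[ll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        mu_grid = 1.0 / (1.0 + np.exp(-(b0s[i] + b1s[j] * x)))
        np.testing.assert_allclose(null.mu, mu_grid, atol=0.02)


class TestQStatistic:
    def test_single_variant_rho_invariant(self, intercept_null):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.05, (400, 1)).astype(float)
        w = np.array([1.5])
        qs = [q_statistic(G, w, intercept_null, r) for r in DEFAULT_RHO_GRID]
        np.testing.assert_allclose(qs, qs[0])

    def test_burden_is_squared_weighted_score(self, intercept_null):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.05, (400, 3)).astype(float)
        w = np.array([1.0, 2.0, 0.5])
        q1 = q_statistic(G, w, intercept_null, 1.0)
        s = (G * w).T @ intercept_null.resid
        assert q1 == pytest.approx(s.sum() ** 2)

    def test_matches_dense_matrix_oracle(self, intercept_null):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.08, (400, 4)).astype(float)
        w = rng.uniform(0.5, 2.0, 4)
        rho = 0.3
        R = (1 - rho) * np.eye(4) + rho * np.ones((4, 4))
        K = (G * w) @ R @ (G * w).T
        r = intercept_null.resid
        assert q_statistic(G, w, intercept_null, rho) == pytest.approx(r @ K @ r)


class TestMixtureChisq:
    def test_one_df_upper_tail(self):
        assert pvalue_mixture_chisq(3.841, [1.0]) == pytest.approx(0.05, abs=5e-4)

    def test_two_df_closed_form(self):
        # equal weights: 2-df chi-square, P(X > 2) = exp(-1)
        assert pvalue_mixture_chisq(2.0, [1.0, 1.0]) == pytest.approx(
            np.exp(-1), abs=1e-5
        )

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        draws = 2 * rng.chisquare(1, 10**6) + rng.chisquare(1, 10**6)
        mc = (draws > 5.0).mean()
        se = np.sqrt(mc * (1 - mc) / 10**6)
        assert pvalue_mixture_chisq(5.0, [2.0, 1.0]) == pytest.approx(mc, abs=3 * se)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pvalue_mixture_chisq(-1.0, [1.0])
        with pytest.raises(ValueError):
            pvalue_mixture_chisq(1.0, [0.0, 0.0])


class TestSkatoTest:
    def test_single_variant_all_rho_equal(self, intercept_null):
        rng = np.random.default_rng(6)
        G = rng.binomial(2, 0.1, (400, 1)).astype(float)
        res = skato_test(G, np.ones(1), intercept_null)
        np.testing.assert_allclose(res.p_rho, res.p_rho[0])
        assert res.p_skato == pytest.approx(res.p_rho[0])

    def test_minp_bounds(self, intercept_null):
        rng = np.random.default_rng(7)
        for _ in range(10):
            G = rng.binomial(2, rng.uniform(0.03, 0.15, 4), (400, 4)).astype(float)
            w = beta_maf_weights(np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2))
            res = skato_test(G, w, intercept_null)
            t = min(res.p_rho)
            assert t - 1e-12 <= res.p_skato <= min(1.0, len(res.p_rho) * t) + 1e-12

    def test_power_ordering_unidirectional_vs_mixed(self):
        # one-directional planted effects favour the burden statistic;
        # mixed-sign effects favour SKAT
        rng = np.random.default_rng(8)
        n, m = 600, 6
        burden_wins_uni, burden_wins_mixed = 0, 0
        reps = 30
        for i in range(reps):
            G = rng.binomial(2, 0.04, (n, m)).astype(float)
            w = np.ones(m)
            eta_uni = -1.2 + 0.4 * G.sum(1)
            sign = np.array([1, -1] * (m // 2))
            eta_mix = -1.2 + 0.6 * (G * sign).sum(1)
            for eta, tag in ((eta_uni, "uni"), (eta_mix, "mix")):
                y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
                null = fit_null(y, np.ones((n, 1)))
                res = skato_test(G, w, null)
                if res.p_burden <= res.p_skat:
                    if tag == "uni":
                        burden_wins_uni += 1
                    else:
                        burden_wins_mixed += 1
        assert burden_wins_uni > reps / 2
        assert burden_wins_mixed < reps / 2

    def test_flipped_allele_encoding_invariant(self, intercept_null):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.1, (400, 3)).astype(float)
        maf = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        w = beta_maf_weights(maf)
        res1 = skato_test(G, w, intercept_null)
        G2 = 2.0 - G  # flip ref/alt; folded MAF (hence weights) unchanged
        res2 = skato_test(G2, w, intercept_null)
        assert res1.p_skat == pytest.approx(res2.p_skat, rel=1e-6)


class TestGenomicInflation:
    def test_uniform_p_near_one(self):
        rng = np.random.default_rng(10)
        p = rng.random(2000)
        assert 0.9 < genomic_inflation(p) < 1.1

    def test_constant_half_is_exactly_one(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_halved_p_inflates(self):
        rng = np.random.default_rng(11)
        p = rng.random(2000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            genomic_inflation([0.5] * 10)
        with pytest.raises(ValueError):
            genomic_inflation(np.concatenate([np.full(60, 0.5), [0.0]]))


class TestNeutralModel:
    def test_empty_synonymous_set(self, null_cohort):
        from ibdpd.filtering import QualifyingVariantSet

        _, bundle, _ = null_cohort
        from ibdpd.qc import covariate_table

        cov = covariate_table(bundle)[["sample_id", "sex"]]
        empty = QualifyingVariantSet(model="synonymous")
        report = neutral_model_check(bundle, empty, cov)
        assert report["results"].empty and np.isnan(report["lambda_gc"])

    def test_reports_threshold_and_qq(self, null_cohort):
        from ibdpd.filtering import build_qualifying_sets
        from ibdpd.qc import covariate_table

        _, bundle, _ = null_cohort
        cov = covariate_table(bundle)[["sample_id", "sex"]]
        syn = build_qualifying_sets(bundle, model="synonymous")
        report = neutral_model_check(bundle, syn, cov)
        res = report["results"]
        assert report["threshold"] == pytest.approx(0.05 / len(res))
        assert len(report["qq"]) == len(res)


def test_gene_skat_o_deterministic(causal_cohort):
    from ibdpd.filtering import build_qualifying_sets
    from ibdpd.qc import covariate_table

    _, bundle, _ = causal_cohort
    cov = covariate_table(bundle)[["sample_id", "sex"]]
    qset = build_qualifying_sets(bundle)
    r1 = gene_skat_o(bundle, qset, cov, seed=5)
    r2 = gene_skat_o(bundle, qset, cov, seed=5)
    assert r1.equals(r2)
    assert (r1["p_bonferroni"] >= r1["p_skato"] - 1e-15).all()
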
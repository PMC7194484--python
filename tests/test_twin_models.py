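"""Univariate twin variance decomposition: ML fits, correlations, LRTs."""

import numpy as np
import pytest
from scipy import stats

from latertwin.exceptions import ConvergenceError, DegenerateDataError
from latertwin.twin import (
    TwinPairTable,
    UnivariateTwinModel,
    compare_models,
    falconer_estimates,
    pair_correlation,
)

from conftest import make_cohort


@pytest.mark.parametrize(
    "r_mz, r_dz, expected",
    [
        (0.5, 0.25, (0.5, 0.0, 0.5)),  # textbook additive case
        (0.0, 0.0, (0.0, 0.0, 1.0)),  # pure-chance trait
        (0.18, 0.13, (0.10, 0.08, 0.82)),  # EHI-like correlations
    ],
)
def test_falconer_arithmetic(r_mz, r_dz, expected):
    a2, c2, e2 = falconer_estimates(r_mz, r_dz)
    assert (a2, c2, e2) == pytest.approx(expected)
    assert a2 + c2 + e2 == pytest.approx(1.0)


def test_falconer_clipped_variant_labelled():
    a2, c2, e2 = falconer_estimates(0.09, -0.09, clip=True)
    assert min(a2, c2, e2) >= 0 and a2 + c2 + e2 == pytest.approx(1.0)
    raw = falconer_estimates(0.09, -0.09)
    assert raw[1] < 0  # unclipped version keeps the negative c2


class TestPairCorrelation:
    def test_identical_twins_give_r_one(self):
        x = np.linspace(-2, 2, 20)
        res = pair_correlation(np.column_stack([x, x]))
        assert res.r == pytest.approx(1.0, abs=1e-3)

    def test_ml_icc_recovers_truth(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((2000, 2))
        r = 0.5
        xy = np.column_stack([z[:, 0], r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]])
        res = pair_correlation(xy)
        assert res.r == pytest.approx(0.5, abs=0.03)
        assert res.ci_low < 0.5 < res.ci_high
        # the labelled double-entry variants travel alongside
        assert res.pearson_double_entry == pytest.approx(res.r, abs=0.02)

    def test_zero_variance_signalled(self):
        with pytest.raises(DegenerateDataError):
            pair_correlation(np.ones((10, 2)))


class TestUnivariateFit:
    def test_parameter_recovery(self, ae_cohort):
        table, truth = ae_cohort
        fit = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        assert fit.a2 == pytest.approx(truth.a2, abs=0.05)
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-8)

    def test_no_familial_covariance_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        mz = rng.standard_normal((400, 2))
        dz = rng.standard_normal((400, 2))
        fit = UnivariateTwinModel(mz, dz, "AE").fit()
        assert fit.a2 == pytest.approx(0.0, abs=0.06)  # within sampling noise

    def test_negative_sample_correlation_hits_exact_zero_boundary(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((300, 2))
        mz = np.column_stack([z[:, 0], -0.2 * z[:, 0] + z[:, 1]])
        dz = rng.standard_normal((300, 2))
        fit = UnivariateTwinModel(mz, dz, "AE").fit()
        assert fit.a2 == 0.0  # boundary estimates reported as exact zero

    def test_loglik_matches_bruteforce_bivariate_normal(self):
        """On tiny instances the model log-likelihood equals the summed
        bivariate-normal log-density evaluated pair by pair."""
        rng = np.random.default_rng(12)
        mz = rng.normal(1.0, 2.0, (6, 2))
        dz = rng.normal(1.0, 2.0, (4, 2))
        model = UnivariateTwinModel(mz, dz, "ACE")
        mu, v, a2, c2 = 0.8, 3.5, 0.3, 0.2
        expected = 0.0
        for xy, k in ((mz, 1.0), (dz, 0.5)):
            r = k * a2 + c2
            cov = v * np.array([[1, r], [r, 1]])
            expected += stats.multivariate_normal.logpdf(xy, [mu, mu], cov).sum()
        assert model.loglike_components(mu, v, a2, c2) == pytest.approx(
            expected, abs=1e-9
        )

    def test_order_invariance(self, ae_cohort):
        table, _ = ae_cohort
        mz = table.values("pheno", "MZ")
        dz = table.values("pheno", "DZ")
        fit1 = UnivariateTwinModel(mz, dz, "AE").fit()
        # swap twin order in an arbitrary subset of pairs
        mz2, dz2 = mz.copy(), dz.copy()
        mz2[::3] = mz2[::3, ::-1]
        dz2[1::4] = dz2[1::4, ::-1]
        fit2 = UnivariateTwinModel(mz2, dz2, "AE").fit()
        assert fit2.a2 == pytest.approx(fit1.a2, abs=1e-8)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)

    def test_implied_correlations_identity(self, ae_cohort):
        table, _ = ae_cohort
        for model in ("ACE", "AE", "CE"):
            fit = UnivariateTwinModel.from_table(table, "pheno", model).fit()
            assert fit.implied_r_mz == pytest.approx(fit.a2 + fit.c2)
            assert fit.implied_r_dz == pytest.approx(0.5 * fit.a2 + fit.c2)

    def test_shared_environment_scenario_prefers_ce(self):
        """When twin similarity is zygosity-independent (c2 > 0, a2 = 0),
        the CE model fits at least as well as AE — the blood-flow pattern."""
        table, _ = make_cohort(500, 500, a2=0.0, c2=0.35, seed=21)
        mz = table.values("pheno", "MZ")
        dz = table.values("pheno", "DZ")
        ce = UnivariateTwinModel(mz, dz, "CE").fit()
        ae = UnivariateTwinModel(mz, dz, "AE").fit()
        assert ce.loglik > ae.loglik
        assert ce.c2 == pytest.approx(0.35, abs=0.07)


class TestModelComparison:
    def test_identical_fits_give_null_lrt(self):
        """When the full model's extra component lands on the zero
        boundary, full and reduced fits coincide: chi-square 0, p = 1."""
        rng = np.random.default_rng(4)
        z = rng.standard_normal((300, 2))
        mz = np.column_stack([z[:, 0], -0.2 * z[:, 0] + z[:, 1]])
        dz = rng.standard_normal((300, 2))
        ae = UnivariateTwinModel(mz, dz, "AE").fit()
        e = UnivariateTwinModel(mz, dz, "E").fit()
        assert ae.a2 == 0.0
        stat, df, p = compare_models(ae, e)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_genetic_term_detected(self, ae_cohort):
        table, _ = ae_cohort
        ae = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        e = UnivariateTwinModel.from_table(table, "pheno", "E").fit()
        stat, df, p = compare_models(ae, e)
        assert df == 1 and stat > 50 and p < 1e-10

    def test_mixture_reference_halves_p(self, ae_cohort):
        table, _ = ae_cohort
        ae = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        e = UnivariateTwinModel.from_table(table, "pheno", "E").fit()
        stat, _, p_std = compare_models(ae, e)
        _, _, p_mix = compare_models(ae, e, mixture=True)
        assert p_mix == pytest.approx(0.5 * p_std, rel=1e-9)

    def test_lrt_null_distribution_matches_boundary_mixture(self):
        """Under a2 = 0 the AE-vs-E LRT follows the 50:50 chi2(0):chi2(1)
        mixture; the rejection rate at the chi2(1) 0.95 quantile is ~2.5%."""
        from latertwin.power import _simulated_lrt

        rng = np.random.default_rng(88)
        crit = stats.chi2.ppf(0.95, 1)
        stats_ = [_simulated_lrt(rng, 100, 100, 0.0) for _ in range(400)]
        rate = np.mean(np.asarray(stats_) > crit)
        assert rate == pytest.approx(0.025, abs=0.025)
        assert np.mean(np.asarray(stats_) < 1e-6) == pytest.approx(0.5, abs=0.08)


class TestProfileCI:
    def test_fixed_component_signalled(self, ae_cohort):
        table, _ = ae_cohort
        fit = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        with pytest.raises(DegenerateDataError):
            fit.profile_ci("c2")

    def test_interval_brackets_estimate(self, ae_cohort):
        table, _ = ae_cohort
        fit = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        low, high = fit.profile_ci("a2")
        assert 0 <= low < fit.a2 < high <= 1

    def test_boundary_estimate_gives_zero_lower_bound(self):
        table, _ = make_cohort(65, 76, a2=0.0, c2=0.0, seed=5)
        fit = UnivariateTwinModel.from_table(table, "pheno", "AE").fit()
        low, high = fit.profile_ci("a2")
        assert low == 0.0
        assert high < 0.5

    def test_coverage_at_study_sample_sizes(self):
        """The 95% profile interval for a2 covers the generating value in
        roughly 95% of replicates at the study's handedness sample size."""
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            table, _ = make_cohort(96, 98, a2=0.25, c2=0.0, seed=10_000 + rep)
            fit = UnivariateTwinModel.from_table(table, "pheno", "AE").fit(restarts=2)
            low, high = fit.profile_ci("a2")
            hits += low <= 0.25 <= high
        coverage = hits / n_rep
        assert coverage == pytest.approx(0.95, abs=0.04)


def test_double_entry_round_trip(tmp_path):
    table, _ = make_cohort(20, 25, a2=0.5, c2=0.0, seed=9)
    path = tmp_path / "pairs.csv"
    table.to_csv(path)
    back = TwinPairTable.from_csv(path)
    np.testing.assert_allclose(
        back.values("pheno", "MZ"), table.values("pheno", "MZ"), rtol=1e-6
    )
    assert back.pairs["zygosity"].tolist() == table.pairs["zygosity"].tolist()
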
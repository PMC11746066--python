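"""PSA: distribution fitting, Monte Carlo, CEAC, acceptability, ellipse."""

import numpy as np
import pandas as pd
import pytest

import tkicea as t
from tkicea.psa import (
    PsaSample,
    Z95,
    ceac,
    confidence_ellipse,
    default_wtp_grid,
    fit_distributions,
    pairwise_acceptability,
)


class TestFits:
    def test_beta_closed_form_example(self):
        # a symmetric 95% range of width 2*1.96*0.1 around 0.5 gives a=b=12
        f = t.fit_beta(0.5, 0.30401, 0.69599)
        assert f.args[0] == pytest.approx(12.0, rel=1e-3)
        assert f.args[1] == pytest.approx(f.args[0])
        assert f.mean() == pytest.approx(0.5, abs=1e-9)

    def test_beta_mean_recovery_contract(self):
        f = t.fit_beta(0.67, 0.60, 0.81)
        assert not f.clamped
        assert f.mean() == pytest.approx(0.67, abs=1e-9)
        assert f.sd() == pytest.approx((0.81 - 0.60) / (2 * Z95), abs=1e-9)

    def test_beta_infeasible_variance_clamped(self):
        # the (0, 1) transplant-receipt range implies sd^2 >= mean(1-mean)
        f = t.fit_beta(0.038, 0.0, 1.0)
        assert f.clamped
        assert f.args == (0.5, 0.5)

    def test_beta_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            t.fit_beta(1.5, 0.1, 0.9)
        with pytest.raises(ValueError):
            t.fit_beta(0.5, 0.9, 0.1)

    def test_gamma_closed_form(self):
        f = t.fit_gamma(100.0, 100 - Z95 * 50, 100 + Z95 * 50)
        assert f.args[0] == pytest.approx(4.0, rel=1e-12)
        assert f.args[1] == pytest.approx(25.0, rel=1e-12)
        assert f.mean() == pytest.approx(100.0, rel=1e-12)

    def test_gamma_published_drug_cost(self):
        f = t.fit_gamma(4634.40, 2317.20, 6951.60)
        assert f.sd() == pytest.approx(1182.26, abs=0.01)
        assert f.args[0] == pytest.approx(15.366, abs=1e-3)
        assert f.mean() == pytest.approx(4634.40, abs=1e-9)

    def test_fit_distributions_cover_all_ranges(self, basecase):
        fits = fit_distributions(basecase)
        assert [f.parameter for f in fits] == [r.parameter for r in basecase.ranges]
        for f, r in zip(fits, basecase.ranges):
            if not f.clamped:
                assert f.mean() == pytest.approx(basecase.get(r.parameter),
                                                 abs=1e-9)

    def test_uniform_interpretation_flag(self, basecase):
        spec = basecase.clone()
        spec.econ.conventions.range_interpretation = "uniform"
        fits = {f.parameter: f for f in fit_distributions(spec)}
        f = fits["costs.monitoring"]
        assert f.family == "uniform"
        assert f.args == (403.12, 1209.38)


@pytest.fixture(scope="module")
def small_sample():
    spec = t.builtin_basecase()
    return spec, t.run_psa(spec, 200, seed=42)


class TestRunPsa:
    def test_seed_determinism(self, small_sample):
        spec, sample = small_sample
        again = t.run_psa(spec, 200, seed=42)
        pd.testing.assert_frame_equal(sample.draws, again.draws)
        np.testing.assert_array_equal(sample.costs, again.costs)
        np.testing.assert_array_equal(sample.qalys, again.qalys)

    def test_different_seed_differs(self, small_sample):
        spec, sample = small_sample
        other = t.run_psa(spec, 200, seed=43)
        assert not np.array_equal(sample.costs, other.costs)

    def test_degenerate_ranges_reproduce_base_case(self, basecase,
                                                   basecase_results):
        spec = basecase.clone()
        for r in spec.ranges:
            r.family = "fixed"
        sample = t.run_psa(spec, 5, seed=0)
        for j, name in enumerate(sample.strategies):
            np.testing.assert_allclose(sample.costs[:, j],
                                       basecase_results[name].total_cost)
            np.testing.assert_allclose(sample.qalys[:, j],
                                       basecase_results[name].total_qalys)

    def test_draw_means_match_distribution_means(self, small_sample):
        spec, sample = small_sample
        n = sample.n_iterations
        for f in sample.fits:
            if f.family == "fixed":
                continue
            se = f.sd() / np.sqrt(n)
            assert abs(sample.draws[f.parameter].mean() - f.mean()) <= 3 * se

    def test_draw_supports(self, small_sample):
        _, sample = small_sample
        for f in sample.fits:
            col = sample.draws[f.parameter]
            assert (col >= 0).all()
            if f.family == "beta":
                assert (col <= 1).all()


class TestCeac:
    def test_probabilities_sum_to_one(self, small_sample):
        _, sample = small_sample
        curve = ceac(sample, default_wtp_grid())
        probs = curve.frame[sample.strategies].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_grid_includes_threshold_exactly(self):
        grid = default_wtp_grid(18760.0)
        assert 18760.0 in grid

    def test_zero_wtp_prefers_cheapest(self, small_sample):
        _, sample = small_sample
        curve = ceac(sample, [0.0])
        cheapest = np.argmin(sample.costs, axis=1)
        for j, s in enumerate(sample.strategies):
            assert curve.at(0.0, s) == pytest.approx(np.mean(cheapest == j),
                                                     abs=1e-12)

    def test_dominating_strategy_has_probability_one(self):
        costs = np.array([[10.0, 20.0]] * 50)
        qalys = np.array([[2.0, 1.0]] * 50)
        sample = PsaSample(["a", "b"], costs, qalys, pd.DataFrame(), 0)
        curve = ceac(sample, [0.0, 1e4, 1e5])
        assert (curve.frame["a"] == 1.0).all()

    def test_empty_grid_rejected(self, small_sample):
        _, sample = small_sample
        with pytest.raises(ValueError):
            ceac(sample, [])


class TestPairwiseAcceptability:
    def _sample(self, de, dc):
        n = len(de)
        costs = np.column_stack([np.zeros(n), dc])
        qalys = np.column_stack([np.zeros(n), de])
        return PsaSample(["ref", "cmp"], costs, qalys, pd.DataFrame(), 0)

    def test_all_dominant_points(self):
        s = self._sample(np.ones(10), -np.ones(10))
        assert pairwise_acceptability(s, "ref", "cmp", 18760.0) == 1.0

    def test_zero_wtp_counts_cost_savings(self):
        s = self._sample(np.array([1.0, 1.0, -1.0]), np.array([-5.0, 5.0, -5.0]))
        assert pairwise_acceptability(s, "ref", "cmp", 0.0) == pytest.approx(2 / 3)

    def test_unknown_strategy_rejected(self):
        s = self._sample(np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            pairwise_acceptability(s, "ref", "nope", 0.0)


class TestConfidenceEllipse:
    def _normal_sample(self, n, cov, seed=7):
        rng = np.random.default_rng(seed)
        pts = rng.multivariate_normal([1.0, 100.0], cov, size=n)
        costs = np.column_stack([np.zeros(n), pts[:, 1]])
        qalys = np.column_stack([np.zeros(n), pts[:, 0]])
        return PsaSample(["ref", "cmp"], costs, qalys, pd.DataFrame(), 0)

    def test_identical_points_degenerate(self):
        costs = np.array([[0.0, 5.0]] * 10)
        qalys = np.array([[0.0, 1.0]] * 10)
        s = PsaSample(["ref", "cmp"], costs, qalys, pd.DataFrame(), 0)
        ell = confidence_ellipse(s, "ref", "cmp")
        assert ell.degenerate
        assert ell.axes == (0.0, 0.0)

    def test_isotropic_cloud_near_circular(self):
        s = self._normal_sample(20000, np.eye(2))
        ell = confidence_ellipse(s, "ref", "cmp")
        major, minor = ell.axes
        assert major / minor == pytest.approx(1.0, abs=0.05)

    def test_coverage_near_95_percent(self):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        s = self._normal_sample(20000, cov)
        ell = confidence_ellipse(s, "ref", "cmp")
        de, dc = s.deltas("ref", "cmp")
        assert np.mean(ell.contains(de, dc)) == pytest.approx(0.95, abs=0.01)

    def test_needs_three_iterations(self):
        costs = np.array([[0.0, 1.0], [0.0, 2.0]])
        s = PsaSample(["ref", "cmp"], costs, costs, pd.DataFrame(), 0)
        with pytest.raises(ValueError):
            confidence_ellipse(s, "ref", "cmp")
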
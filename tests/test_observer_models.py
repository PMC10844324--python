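"""Unit and property tests for the generative observer models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronobind import (
    FreeParams,
    MODELS,
    ObserverParams,
    PerceptPair,
    conditional_estimates,
    get_model,
    joint_posterior_ratio,
    marginal_causal_posterior,
    respond,
    sample_percepts,
)


def posterior_oracle(tau_A, tau_O, params, p_causal, mu_AO):
    """Independent scalar evaluation of the marginal causal posterior:
    unnormalized scenario masses (Gaussian over the percept discrepancy vs.
    flat over the normalization square), then normalize."""
    sigma_tot = np.sqrt(params.sigma_tot_sq)
    d = tau_O - tau_A - mu_AO
    mass_causal = (
        p_causal
        / (np.sqrt(2 * np.pi) * params.T * sigma_tot)
        * np.exp(-(d**2) / (2 * sigma_tot**2))
    )
    mass_acausal = (1.0 - p_causal) / params.T**2
    return mass_causal / (mass_causal + mass_acausal)


class TestSamplePercepts:
    def test_noiseless_limit(self):
        params = ObserverParams(b_A=-10.0, sigma_A=1e-9, b_O=5.0, sigma_O=1e-9)
        pp = sample_percepts(params, t_AO=250.0, n=50, seed=0)
        np.testing.assert_allclose(pp.tau_A, -10.0, atol=1e-6)
        np.testing.assert_allclose(pp.tau_O, 255.0, atol=1e-6)

    def test_law_of_large_numbers(self, default_params):
        n = 100_000
        pp = sample_percepts(default_params, t_AO=0.0, n=n, seed=7)
        se = default_params.sigma_A / np.sqrt(n)
        assert abs(pp.tau_A.mean() - default_params.b_A) < 3 * se
        se_O = default_params.sigma_O / np.sqrt(n)
        assert abs(pp.tau_O.mean() - default_params.b_O) < 3 * se_O
        # independence across the pair: sample correlation near zero
        assert abs(np.corrcoef(pp.tau_A, pp.tau_O)[0, 1]) < 4 / np.sqrt(n)

    def test_reproducible_given_seed(self, default_params):
        a = sample_percepts(default_params, 250.0, 100, seed=3)
        b = sample_percepts(default_params, 250.0, 100, seed=3)
        np.testing.assert_array_equal(a.tau_A, b.tau_A)
        np.testing.assert_array_equal(a.tau_O, b.tau_O)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(ValueError):
            ObserverParams(b_A=0, sigma_A=bad, b_O=0, sigma_O=50.0)

    def test_n_zero_rejected(self, default_params):
        with pytest.raises(ValueError):
            sample_percepts(default_params, 0.0, 0, seed=0)


class TestConditionalEstimates:
    def test_hand_computed_shift(self):
        # sigma_tot^2 = 2500 + 3600 + 100 = 6200
        params = ObserverParams(b_A=0, sigma_A=50.0, b_O=0, sigma_O=60.0)
        est = conditional_estimates(PerceptPair(0.0, 250.0), params, mu_AO=0.0)
        assert est.t_hat_A_causal == pytest.approx(250.0 * 2500 / 6200)
        assert est.t_hat_O_causal == pytest.approx(250.0 - 250.0 * 3600 / 6200)
        assert est.t_hat_A_acausal == 0.0
        assert est.t_hat_O_acausal == 250.0

    def test_zero_discrepancy_means_zero_shift(self, default_params):
        pp = PerceptPair(10.0, 10.0 + 120.0)
        est = conditional_estimates(pp, default_params, mu_AO=120.0)
        assert est.t_hat_A_causal == pytest.approx(pp.tau_A)
        assert est.t_hat_O_causal == pytest.approx(pp.tau_O)

    def test_shrinkage_identity_bulk(self, default_params, rng):
        # t_hat_O - t_hat_A - mu == (sigma_AO^2/sigma_tot^2)(tau_O - tau_A - mu)
        n = 10_000
        pp = PerceptPair(rng.normal(0, 200, n), rng.normal(250, 200, n))
        mu = 80.0
        est = conditional_estimates(pp, default_params, mu)
        d = pp.tau_O - pp.tau_A - mu
        expected = mu + default_params.sigma_AO**2 / default_params.sigma_tot_sq * d
        np.testing.assert_allclose(
            est.t_hat_O_causal - est.t_hat_A_causal, expected, rtol=1e-9
        )
        # shrinkage: the causal interval is never further from the prior
        assert np.all(
            np.abs(est.t_hat_O_causal - est.t_hat_A_causal - mu) <= np.abs(d) + 1e-12
        )

    @given(
        tau_A=st.floats(-500, 500),
        tau_O=st.floats(-500, 1000),
        mu=st.floats(0, 500),
        sigma_A=st.floats(5, 150),
        sigma_O=st.floats(5, 150),
    )
    @settings(max_examples=100, derandomize=True)
    def test_shrinkage_identity_property(self, tau_A, tau_O, mu, sigma_A, sigma_O):
        params = ObserverParams(b_A=0, sigma_A=sigma_A, b_O=0, sigma_O=sigma_O)
        est = conditional_estimates(PerceptPair(tau_A, tau_O), params, mu)
        d = tau_O - tau_A - mu
        got = est.t_hat_O_causal - est.t_hat_A_causal - mu
        expected = params.sigma_AO**2 / params.sigma_tot_sq * d
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_compression_direction_unity_prior(self, default_params):
        # with mu=0 and tau_O > tau_A the estimates move toward each other
        pp = PerceptPair(0.0, 300.0)
        est = conditional_estimates(pp, default_params, mu_AO=0.0)
        assert est.t_hat_A_causal > pp.tau_A
        assert est.t_hat_O_causal < pp.tau_O

    def test_repulsion_when_interval_below_prior(self, default_params):
        # coupling prior larger than the perceived interval reverses the shift
        pp = PerceptPair(0.0, 100.0)
        est = conditional_estimates(pp, default_params, mu_AO=400.0)
        assert est.t_hat_A_causal < pp.tau_A
        assert est.t_hat_O_causal > pp.tau_O


class TestMarginalPosterior:
    def test_degenerate_priors(self, default_params):
        pp = PerceptPair(0.0, 250.0)
        assert marginal_causal_posterior(pp, default_params, 0.0, 0.0) == 0.0
        assert marginal_causal_posterior(pp, default_params, 1.0, 0.0) == 1.0

    def test_matches_scalar_oracle(self, rng):
        params = ObserverParams(b_A=0, sigma_A=50.0, b_O=0, sigma_O=60.0)
        # frozen hand value: large discrepancy makes the causal case unlikely
        got = marginal_causal_posterior(PerceptPair(0.0, 250.0), params, 0.5, 0.0)
        assert got == pytest.approx(0.008131, abs=1e-5)
        for _ in range(50):
            tau_A = rng.uniform(-300, 300)
            tau_O = rng.uniform(-300, 800)
            p = rng.uniform(0.01, 0.99)
            mu = rng.uniform(0, 500)
            expected = posterior_oracle(tau_A, tau_O, params, p, mu)
            got = marginal_causal_posterior(PerceptPair(tau_A, tau_O), params, p, mu)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_normalization_to_machine_precision(self, default_params, rng):
        d_grid = rng.uniform(-800, 800, 200)
        pp = PerceptPair(np.zeros(200), d_grid)
        post = marginal_causal_posterior(pp, default_params, 0.37, 90.0)
        comp = marginal_causal_posterior(
            pp, default_params, 0.37, 90.0
        )  # complement via the same kernel
        np.testing.assert_allclose(post + (1.0 - comp), 1.0, rtol=0, atol=1e-15)
        assert np.all((post >= 0) & (post <= 1))

    def test_strictly_decreasing_in_discrepancy(self, default_params):
        mu = 50.0
        d = np.linspace(0.0, 600.0, 400)
        pp = PerceptPair(np.zeros_like(d), d + mu)
        post = marginal_causal_posterior(pp, default_params, 0.6, mu)
        assert np.all(np.diff(post) < 0)


class TestJointPosteriorRatio:
    def test_boundary_priors(self, default_params):
        pp = PerceptPair(0.0, 250.0)
        assert joint_posterior_ratio(pp, default_params, 0.0, 0.0) == 0.0
        assert np.isinf(joint_posterior_ratio(pp, default_params, 1.0, 0.0))

    def test_maximized_at_prior_interval(self, default_params):
        d = np.linspace(-400, 900, 1001)
        pp = PerceptPair(np.zeros_like(d), d)
        r = joint_posterior_ratio(pp, default_params, 0.5, 250.0)
        assert d[np.argmax(r)] == pytest.approx(250.0, abs=2.0)

    def test_causal_region_is_contiguous(self, default_params):
        d = np.linspace(-600, 1100, 4001)
        pp = PerceptPair(np.zeros_like(d), d)
        r = joint_posterior_ratio(pp, default_params, 0.7, 250.0)
        causal = r > 1.0
        # at most one off->on and one on->off transition along the axis
        assert np.abs(np.diff(causal.astype(int))).sum() <= 2
        assert causal.any()


def grid_peak_log_ratio(tau_A, tau_O, params, p_causal, mu_AO, step=1.0):
    """Brute-force oracle: log ratio of the joint-posterior peaks found by
    maximizing the unnormalized joint density over a 2-D grid of candidate
    event times (causal case) against the analytic acausal peak."""
    # pad the grid by the discrepancy so it always contains the causal
    # peak, which shifts away from the percepts by a fraction of it
    pad = abs(tau_O - tau_A - mu_AO)
    span_A = 4 * params.sigma_A + pad
    span_O = 4 * params.sigma_O + pad
    t_A = np.arange(tau_A - span_A, tau_A + span_A + step, step)
    t_O = np.arange(tau_O - span_O, tau_O + span_O + step, step)
    TA, TO = np.meshgrid(t_A, t_O, indexing="ij")
    log_like = (
        -((tau_A - TA) ** 2) / (2 * params.sigma_A**2)
        - ((tau_O - TO) ** 2) / (2 * params.sigma_O**2)
    )
    log_prior_causal = -((TO - TA - mu_AO) ** 2) / (2 * params.sigma_AO**2) - np.log(
        np.sqrt(2 * np.pi) * params.sigma_AO * params.T
    )
    log_peak_causal = np.log(p_causal) + np.max(log_like + log_prior_causal)
    # acausal peak is exactly at (tau_A, tau_O) with flat prior 1/T^2
    log_peak_acausal = np.log1p(-p_causal) - 2 * np.log(params.T)
    return log_peak_causal - log_peak_acausal


class TestJointDecisionOracle:
    def test_ratio_matches_grid_peak(self, rng):
        for _ in range(15):
            params = ObserverParams(
                b_A=0, sigma_A=rng.uniform(30, 90), b_O=0, sigma_O=rng.uniform(30, 90)
            )
            tau_A = rng.uniform(-150, 150)
            tau_O = rng.uniform(-150, 650)
            p = rng.uniform(0.05, 0.95)
            mu = rng.uniform(0, 500)
            oracle = grid_peak_log_ratio(tau_A, tau_O, params, p, mu, step=0.5)
            got = np.log(
                joint_posterior_ratio(PerceptPair(tau_A, tau_O), params, p, mu)
            )
            assert got == pytest.approx(oracle, abs=5e-3)


class TestRespond:
    @pytest.mark.parametrize(
        "phi, expect_action, expect_outcome",
        [(200.0, 70.0, 70.0), (100.0, -10.0, 150.0)],
    )
    def test_fixed_criterion(self, default_params, phi, expect_action, expect_outcome):
        pp = PerceptPair(-10.0, 150.0)
        free = FreeParams(phi=phi)
        assert respond("FC", free, pp, default_params, "action", 0.5) == expect_action
        assert respond("FC", free, pp, default_params, "outcome", 0.5) == expect_outcome

    def test_fixed_criterion_boundary_is_inclusive(self, default_params):
        pp = PerceptPair(0.0, 160.0)
        free = FreeParams(phi=160.0)
        assert respond("FC", free, pp, default_params, "action", 0.5) == 80.0

    def test_false_report_degenerate(self, default_params, rng):
        pp = PerceptPair(rng.normal(0, 50, 100), rng.normal(250, 50, 100))
        u = rng.uniform(size=100)
        never = respond("FR", FreeParams(p_fr=0.0), pp, default_params, "action", u)
        np.testing.assert_array_equal(never, pp.tau_A)
        always = respond("FR", FreeParams(p_fr=1.0), pp, default_params, "action", u)
        np.testing.assert_array_equal(always, pp.tau_O)
        swapped = respond("FR", FreeParams(p_fr=1.0), pp, default_params, "outcome", u)
        np.testing.assert_array_equal(swapped, pp.tau_A)

    def test_null_returns_raw_percept(self, default_params):
        pp = PerceptPair(12.5, 300.0)
        assert respond("NULL", FreeParams(), pp, default_params, "outcome", 0.1) == 300.0

    def test_model_averaging_is_convex_combination(self, default_params, rng):
        n = 2_000
        pp = PerceptPair(rng.normal(0, 100, n), rng.normal(250, 100, n))
        free = FreeParams(p_causal=0.6, mu_AO=120.0)
        for target in ("action", "outcome"):
            report = respond("MAcp", free, pp, default_params, target, 0.5)
            est = conditional_estimates(pp, default_params, 120.0)
            causal = est.t_hat_A_causal if target == "action" else est.t_hat_O_causal
            acausal = pp.tau_A if target == "action" else pp.tau_O
            lo = np.minimum(causal, acausal) - 1e-9
            hi = np.maximum(causal, acausal) + 1e-9
            assert np.all((report >= lo) & (report <= hi))

    def test_probability_matching_frequency(self, default_params):
        pp = PerceptPair(0.0, 150.0)
        post = float(marginal_causal_posterior(pp, default_params, 0.6, 0.0))
        n = 100_000
        u = np.random.default_rng(5).uniform(size=n)
        ppn = PerceptPair(np.zeros(n), np.full(n, 150.0))
        reports = respond("PMup", FreeParams(p_causal=0.6), ppn, default_params, "action", u)
        est = conditional_estimates(pp, default_params, 0.0)
        frac_causal = np.mean(np.isclose(reports, est.t_hat_A_causal))
        se = np.sqrt(post * (1 - post) / n)
        assert abs(frac_causal - post) < 4 * se

    @pytest.mark.parametrize("p_causal", [0.0, 1.0])
    def test_ms_and_pm_coincide_at_degenerate_posterior(self, default_params, p_causal):
        n = 500
        r = np.random.default_rng(9)
        pp = PerceptPair(r.normal(0, 60, n), r.normal(250, 60, n))
        u = r.uniform(size=n)
        free = FreeParams(p_causal=p_causal)
        ms = respond("MSup", free, pp, default_params, "outcome", u)
        pm = respond("PMup", free, pp, default_params, "outcome", u)
        np.testing.assert_array_equal(ms, pm)

    def test_mandatory_ignores_percept_gap(self, default_params):
        # MI always integrates: report equals the causal MAP for any gap
        pp = PerceptPair(0.0, 900.0)
        est = conditional_estimates(pp, default_params, 0.0)
        got = respond("MIup", FreeParams(), pp, default_params, "action", 0.0)
        assert got == pytest.approx(est.t_hat_A_causal)

    def test_missing_required_parameter_raises(self, default_params):
        with pytest.raises(ValueError, match="requires free parameter"):
            respond("FC", FreeParams(p_causal=0.5), PerceptPair(0.0, 1.0),
                    default_params, "action", 0.5)

    def test_bad_target_rejected(self, default_params):
        with pytest.raises(ValueError, match="target"):
            respond("NULL", FreeParams(), PerceptPair(0.0, 1.0),
                    default_params, "tone", 0.5)


class TestRegistry:
    def test_model_inventory(self):
        assert len(MODELS) == 13
        assert sum(m.id != "NULL" for m in MODELS.values()) == 12
        assert MODELS["NULL"].n_free == 0
        assert MODELS["MIup"].n_free == 0
        assert MODELS["MIcp"].free_param_names == ("mu_AO",)
        for mid in ("JPup", "MSup", "MAup", "PMup"):
            assert MODELS[mid].free_param_names == ("p_causal",)
        for mid in ("JPcp", "MScp", "MAcp", "PMcp"):
            assert MODELS[mid].free_param_names == ("p_causal", "mu_AO")

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            get_model("XXcp")

    def test_free_param_range_enforced(self):
        with pytest.raises(ValueError):
            FreeParams(p_causal=1.5)
        with pytest.raises(ValueError):
            FreeParams(mu_AO=-1.0)
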
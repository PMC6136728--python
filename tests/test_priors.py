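"""Tests for the likelihood, priors and posterior evaluation."""

import math

import numpy as np
import pytest
from scipy import stats

from itcfit import (
    ParameterState,
    PriorConfig,
    log_likelihood,
    log_posterior,
    log_prior,
    model_heats,
)
from itcfit.priors import lognormal_params, make_log_posterior


def _state(**kw):
    base = dict(dG=-10.0, dH=-5.0, dH0=0.3e-6, Ls=1e-3, R0=1e-4, sigma=1e-6)
    base.update(kw)
    return ParameterState(**base)


class TestLogLikelihood:
    def test_zero_residuals_closed_form(self, design):
        state = _state()
        q = model_heats(state, design)
        n = len(q)
        expected = -0.5 * n * math.log(2 * math.pi) - n * math.log(state.sigma)
        assert log_likelihood(state, q, design) == pytest.approx(expected, rel=1e-12)

    def test_hand_computed_two_point_example(self, design):
        # two injections, residuals (1, 2) ucal at sigma = 1 ucal:
        # -ln(2 pi) - 2 ln(1e-6) - 2.5, summed by independent arithmetic
        from itcfit import ExperimentDesign

        des2 = ExperimentDesign(
            cell_volume=design.cell_volume,
            injection_volumes=design.injection_volumes[:2],
            temperature=design.temperature,
            stated_titrand=1e-4,
            stated_titrant=1e-3,
        )
        state = _state()
        qstar = model_heats(state, des2)
        q = qstar + np.array([1e-6, 2e-6])
        expected = -math.log(2 * math.pi) - 2 * math.log(1e-6) - 2.5
        assert log_likelihood(state, q, des2) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scaling_of_residuals(self, design):
        state = _state()
        qstar = model_heats(state, design)
        r = 1e-6 * np.linspace(-1, 1, len(qstar))
        base = log_likelihood(state, qstar, design)
        l1 = log_likelihood(state, qstar + r, design)
        l2 = log_likelihood(state, qstar + 2 * r, design)
        # doubling residuals quadruples the quadratic penalty
        assert (base - l2) == pytest.approx(4 * (base - l1), rel=1e-9)

    def test_sigma_mle_is_root_mean_square_residual(self, design):
        state = _state()
        qstar = model_heats(state, design)
        rng = np.random.default_rng(3)
        q = qstar + 1e-6 * rng.standard_normal(len(qstar))
        msr = float(np.mean((q - qstar) ** 2))
        sig_hat = math.sqrt(msr)
        best = log_likelihood(_state(sigma=sig_hat), q, design)
        for f in (0.8, 0.9, 1.1, 1.25):
            assert log_likelihood(_state(sigma=f * sig_hat), q, design) < best


class TestLogPrior:
    @pytest.fixture()
    def heats(self, design, noisy_curve):
        return noisy_curve[0]

    def test_free_energy_outside_box_is_impossible(self, design, heats):
        lp = log_prior(_state(dG=-50.0), PriorConfig(), heats, design)
        assert lp == -math.inf

    def test_titrant_term_matches_scipy_lognormal(self, design, heats):
        cfg = PriorConfig("general")
        mu, s = lognormal_params(design.stated_titrant, 0.1)
        dist = stats.lognorm(s=s, scale=math.exp(mu))
        a = log_prior(_state(Ls=1e-3), cfg, heats, design)
        b = log_prior(_state(Ls=1.1e-3), cfg, heats, design)
        expected = dist.logpdf(1e-3) - dist.logpdf(1.1e-3)
        assert (a - b) == pytest.approx(expected, rel=1e-10)

    def test_comparison_model_flat_in_titrand(self, design, heats):
        cfg = PriorConfig("comparison")
        a = log_prior(_state(R0=0.3e-4), cfg, heats, design)
        b = log_prior(_state(R0=3e-4), cfg, heats, design)
        assert a == b and math.isfinite(a)

    def test_flat_titrand_bounds_enforced(self, design, heats):
        cfg = PriorConfig("flat-r0")
        assert log_prior(_state(R0=1e-6), cfg, heats, design) == -math.inf
        assert log_prior(_state(R0=2e-3), cfg, heats, design) == -math.inf

    def test_offset_box_follows_heat_range(self, design, heats):
        cfg = PriorConfig()
        qmin, qmax = float(np.min(heats)), float(np.max(heats))
        dq = qmax - qmin
        inside = _state(dH0=qmax + 0.5 * dq)
        outside = _state(dH0=qmax + 1.5 * dq)
        assert math.isfinite(log_prior(inside, cfg, heats, design))
        assert log_prior(outside, cfg, heats, design) == -math.inf


class TestLogPosterior:
    def test_additivity(self, design, noisy_curve):
        q = noisy_curve[0]
        cfg = PriorConfig()
        st_ = _state()
        total = log_posterior(st_, cfg, q, design)
        parts = log_prior(st_, cfg, q, design) + log_likelihood(st_, q, design)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_out_of_support_propagates(self, design, noisy_curve):
        q = noisy_curve[0]
        assert log_posterior(_state(dH=200.0), PriorConfig(), q, design) == -math.inf

    def test_ratio_equals_likelihood_ratio_under_equal_priors(
        self, design, noisy_curve
    ):
        # comparison model: R0 flat, so two states differing only in R0
        # (and the energies) have identical priors
        q = noisy_curve[0]
        cfg = PriorConfig("comparison")
        s1 = _state(dG=-10.0, R0=0.9e-4)
        s2 = _state(dG=-9.5, R0=0.9e-4)
        post = log_posterior(s1, cfg, q, design) - log_posterior(s2, cfg, q, design)
        lik = log_likelihood(s1, q, design) - log_likelihood(s2, q, design)
        assert post == pytest.approx(lik, rel=1e-10)

    def test_compiled_path_matches_reference_path(self, design, noisy_curve):
        q = noisy_curve[0]
        for name in ("general", "flat-r0", "comparison"):
            cfg = PriorConfig(name)
            f = make_log_posterior(q, design, cfg)
            rng = np.random.default_rng(11)
            for _ in range(50):
                st_ = _state(
                    dG=rng.uniform(-14, -6),
                    dH=rng.uniform(-10, 2),
                    dH0=rng.uniform(-2e-6, 2e-6),
                    Ls=1e-3 * rng.uniform(0.7, 1.3),
                    R0=1e-4 * rng.uniform(0.7, 1.3),
                    sigma=10 ** rng.uniform(-6.5, -5),
                )
                slow = log_posterior(st_, cfg, q, design)
                fast = f(st_.as_array())
                assert fast == pytest.approx(slow, rel=1e-12)


class TestLognormalConvention:
    def test_mean_and_cv_are_as_declared(self):
        mu, s = lognormal_params(1e-3, 0.1)
        rng = np.random.default_rng(0)
        draws = rng.lognormal(mu, s, size=100_000)
        assert np.mean(draws) == pytest.approx(1e-3, rel=0.01)
        assert np.std(draws) / np.mean(draws) == pytest.approx(0.1, rel=0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lognormal_params(-1.0, 0.1)
        with pytest.raises(ValueError):
            lognormal_params(1.0, -0.1)


def test_flat_prior_posterior_mode_matches_least_squares(design):
    """On a noiseless curve the comparison-model posterior mode and the NLS
    optimum identify the same thermodynamics."""
    from itcfit import ITCLeastSquares, SimulationSpec, simulate_experiment
    from itcfit.sampler import posterior_mode

    spec = SimulationSpec(concentration_cv=0.0, noise_sd=0.0, seed=0)
    q, truth = simulate_experiment(spec, design)
    mode = posterior_mode(q, design, PriorConfig("comparison"))
    nls = ITCLeastSquares(q, design).fit().fit_result
    assert mode.dG == pytest.approx(nls.dG, rel=1e-3)
    assert mode.dH == pytest.approx(nls.dH, rel=1e-3)
    assert mode.dG == pytest.approx(truth.dG, rel=1e-3)
    assert nls.n_stoich == pytest.approx(1.0, abs=1e-3)
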
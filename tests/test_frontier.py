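import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ltsseff import (
    ConfigurationError,
    DomainError,
    FitOptions,
    FrontierFit,
    FrontierParams,
    FrontierSpec,
    FrontierTruth,
    PanelDataset,
    SyntheticConfig,
    build_design,
    decay_factor,
    fit_frontier,
    generate_panel,
    loglik,
    predict_scores,
)
from ltsseff.frontier import FrontierData, _mills_ratio, _state_posterior

from conftest import make_frame


# ---------------------------------------------------------------------------
# Independent oracles: 1-D adaptive quadrature of the composed-error density.


def _integrate_positive(f, su, mu, eps_scale):
    """Accurate integral of a peaked density over [0, inf).

    ``f`` must map an array of u values to an array of densities.  Locates
    the peak on a grid, rescales by its height, and splits the adaptive
    quadrature there so narrow peaks away from zero are not missed.
    Returns (value, log_scale) with value * exp(log_scale) the integral.
    """
    upper = 10.0 * (su + abs(mu) + eps_scale) + 5.0
    grid = np.linspace(0.0, upper, 2001)
    heights = f(grid)
    peak_idx = int(np.argmax(heights))
    peak, height = grid[peak_idx], heights[peak_idx]
    if height <= 0:
        raise AssertionError("oracle integrand vanished on the whole grid")
    g = lambda u: float(f(np.array([u]))[0] / height)
    kwargs = dict(limit=200, epsabs=1e-12, epsrel=1e-10)
    left, _ = integrate.quad(g, 0.0, peak, **kwargs) if peak > 0 else (0.0, 0.0)
    mid, _ = integrate.quad(g, peak, upper, **kwargs)
    tail, _ = integrate.quad(g, upper, np.inf, **kwargs)
    return left + mid + tail, np.log(height)


def _gauss_product(e, h, sv):
    """Vector-in, vector-out product of observation densities at each u."""

    def f(u):
        z = (e[:, None] - h[:, None] * np.asarray(u)[None, :]) / sv
        return np.prod(stats.norm.pdf(z) / sv, axis=0)

    return f


def quadrature_loglik(params, fdata):
    """Integrate the state-level truncated-normal u out numerically."""
    sv, su, mu, eta = params.sigma_v, params.sigma_u, params.mu, params.eta
    eps = fdata.y - fdata.X @ params.beta
    total = 0.0
    for s in range(fdata.n_states):
        mask = fdata.state_idx == s
        e, h = eps[mask], np.exp(-eta * fdata.tmT[mask])
        gauss = _gauss_product(e, h, sv)

        def integrand(u):
            prior = stats.norm.pdf((np.asarray(u) - mu) / su) / (su * stats.norm.cdf(mu / su))
            return gauss(u) * prior

        value, log_scale = _integrate_positive(integrand, su, mu, np.abs(e).max())
        total += np.log(value) + log_scale
    return total


def quadrature_posterior_mean(params, fdata, state):
    sv, su, mu, eta = params.sigma_v, params.sigma_u, params.mu, params.eta
    eps = fdata.y - fdata.X @ params.beta
    mask = fdata.state_idx == state
    e, h = eps[mask], np.exp(-eta * fdata.tmT[mask])
    gauss = _gauss_product(e, h, sv)

    def joint(u):
        return gauss(u) * stats.norm.pdf((np.asarray(u) - mu) / su)

    scale = np.abs(e).max()
    den, log_den = _integrate_positive(joint, su, mu, scale)
    num, log_num = _integrate_positive(lambda u: np.asarray(u) * joint(u), su, mu, scale)
    return num / den * np.exp(log_num - log_den)


def toy_fdata(rng, n_states=2, n_years=3, k=1):
    n = n_states * n_years
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(k - 1)])
    y = rng.normal(size=n)
    years = np.tile(np.arange(2000, 2000 + n_years), n_states)
    return FrontierData(
        y=y, X=X, columns=[f"c{i}" for i in range(k)],
        state_codes=[f"S{i}" for i in range(n_states)],
        state_idx=np.repeat(np.arange(n_states), n_years),
        years=years,
        tmT=(years - (2000 + n_years - 1)).astype(float),
    )


class TestDecayFactor:
    def test_anchor_year(self):
        assert decay_factor(2007, 2007, 0.3) == 1.0

    def test_eta_zero(self):
        np.testing.assert_array_equal(decay_factor(np.arange(1999, 2008), 2007, 0.0), 1.0)

    def test_direct_evaluation(self):
        assert decay_factor(1999, 2007, 0.011) == pytest.approx(np.exp(0.088))
        assert float(decay_factor(1999, 2007, 0.011)) == pytest.approx(1.09199, abs=5e-6)


class TestBuildDesign:
    def test_nine_years_base_2007_gives_eight_dummies(self, full_grid):
        fdata = build_design(full_grid, FrontierSpec(base_year=2007))
        dummies = [c for c in fdata.columns if c.startswith("year_")]
        assert len(dummies) == 8
        assert "year_2007" not in dummies

    def test_single_year_panel_no_dummies(self):
        data = PanelDataset(make_frame([("CA", 2005), ("NY", 2005)]))
        fdata = build_design(data, FrontierSpec(base_year=2007))
        assert fdata.columns == ["const", "log_q_hcbs", "log_q_inst"]

    def test_toy_record_values(self):
        data = PanelDataset(
            make_frame([("CA", 2005), ("CA", 2006)], total_cost=1000.0, q_hcbs=10.0, q_inst=5.0)
        )
        fdata = build_design(data, FrontierSpec(base_year=2006))
        np.testing.assert_allclose(fdata.y, np.log(1000.0))
        np.testing.assert_allclose(fdata.X[0, :3], [1.0, np.log(10.0), np.log(5.0)])
        assert fdata.columns == ["const", "log_q_hcbs", "log_q_inst", "year_2005"]

    def test_squares_and_interaction(self, toy_dataset):
        fdata = build_design(
            toy_dataset, FrontierSpec(output_terms="with_squares_and_interaction")
        )
        assert {"log_q_hcbs_sq", "log_q_inst_sq", "log_q_hcbs_x_inst"} <= set(fdata.columns)

    def test_zero_count_is_domain_error(self):
        data = PanelDataset(make_frame([("CA", 2005), ("CA", 2006)], q_inst=0.0))
        with pytest.raises(DomainError, match="CA"):
            build_design(data, FrontierSpec())

    def test_offset_allows_zero_counts(self):
        data = PanelDataset(make_frame([("CA", 2005), ("CA", 2006)], q_inst=0.0))
        fdata = build_design(data, FrontierSpec(), offset=1.0)
        np.testing.assert_allclose(fdata.X[:, 2], 0.0)

    def test_tmT_per_state_last_year(self):
        frame = make_frame([("CA", 2000), ("CA", 2001), ("NY", 2000)])
        fdata = build_design(PanelDataset(frame), FrontierSpec(base_year=2001))
        # CA last year 2001, NY last year 2000
        np.testing.assert_array_equal(fdata.tmT, [-1.0, 0.0, 0.0])


class TestSpecValidation:
    def test_exponential_requires_time_invariant(self):
        with pytest.raises(ConfigurationError):
            FrontierSpec(distribution="exponential", time_varying=True)

    def test_unknown_distribution(self):
        with pytest.raises(ConfigurationError):
            FrontierSpec(distribution="gamma")


class TestLoglik:
    def test_matches_quadrature_on_toy_panel(self, rng):
        fdata = toy_fdata(rng)
        params = FrontierParams(beta=np.array([0.1]), sigma_sq=1.0, gamma=0.5, mu=0.2, eta=0.1)
        closed = loglik(params, FrontierSpec(), fdata)
        assert closed == pytest.approx(quadrature_loglik(params, fdata), abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_quadrature_property_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        fdata = toy_fdata(rng, n_states=int(rng.integers(2, 5)), n_years=int(rng.integers(2, 5)))
        params = FrontierParams(
            beta=np.array([rng.normal()]),
            sigma_sq=float(rng.uniform(0.2, 2.0)),
            gamma=float(rng.uniform(0.05, 0.95)),
            mu=float(rng.normal(0, 0.5)),
            eta=float(rng.normal(0, 0.1)),
        )
        closed = loglik(params, FrontierSpec(), fdata)
        assert closed == pytest.approx(quadrature_loglik(params, fdata), abs=1e-6)

    def test_gamma_to_zero_limit_is_gaussian(self, rng):
        fdata = toy_fdata(rng)
        sigma_sq = 0.8
        params = FrontierParams(beta=np.array([0.0]), sigma_sq=sigma_sq, gamma=1e-12, mu=0.0, eta=0.0)
        closed = loglik(params, FrontierSpec(), fdata)
        gaussian = float(np.sum(stats.norm.logpdf(fdata.y, scale=np.sqrt(sigma_sq))))
        assert closed == pytest.approx(gaussian, abs=1e-5)

    def test_hnormal_equals_tnormal_with_mu_zero(self, rng):
        fdata = toy_fdata(rng)
        base = dict(beta=np.array([0.2]), sigma_sq=1.3, gamma=0.6, eta=0.05)
        ll_h = loglik(FrontierParams(mu=99.0, **base), FrontierSpec(distribution="hnormal"), fdata)
        ll_t = loglik(FrontierParams(mu=0.0, **base), FrontierSpec(distribution="tnormal"), fdata)
        assert ll_h == ll_t

    def test_invariant_to_state_ordering(self, rng):
        fdata = toy_fdata(rng, n_states=3)
        params = FrontierParams(beta=np.array([0.0]), sigma_sq=1.0, gamma=0.4, mu=0.1, eta=0.02)
        perm = np.array([2, 0, 1])
        order = np.argsort(perm[fdata.state_idx], kind="stable")
        shuffled = FrontierData(
            y=fdata.y[order], X=fdata.X[order], columns=fdata.columns,
            state_codes=["S2", "S0", "S1"],
            state_idx=perm[fdata.state_idx][order],
            years=fdata.years[order], tmT=fdata.tmT[order],
        )
        spec = FrontierSpec()
        assert loglik(params, spec, fdata) == pytest.approx(loglik(params, spec, shuffled), rel=1e-12)

    def test_invariant_to_year_relabeling_preserving_tmT(self, rng):
        fdata = toy_fdata(rng)
        shifted = FrontierData(
            y=fdata.y, X=fdata.X, columns=fdata.columns,
            state_codes=fdata.state_codes, state_idx=fdata.state_idx,
            years=fdata.years + 50, tmT=fdata.tmT,
        )
        params = FrontierParams(beta=np.array([0.0]), sigma_sq=1.0, gamma=0.4, mu=0.1, eta=0.02)
        spec = FrontierSpec()
        assert loglik(params, spec, fdata) == loglik(params, spec, shifted)

    def test_exponential_closed_form_matches_observationwise_quadrature(self, rng):
        fdata = toy_fdata(rng)
        params = FrontierParams(beta=np.array([0.1]), sigma_sq=1.0, gamma=0.5)
        spec = FrontierSpec(distribution="exponential", time_varying=False)
        closed = loglik(params, spec, fdata)
        sv, su = params.sigma_v, params.sigma_u
        eps = fdata.y - fdata.X @ params.beta
        total = 0.0
        for e in eps:
            val, _ = integrate.quad(
                lambda u: stats.norm.pdf((e - u) / sv) / sv * np.exp(-u / su) / su,
                0, np.inf, limit=200,
            )
            total += np.log(val)
        assert closed == pytest.approx(total, abs=1e-8)


class TestPredictScores:
    def make_fit(self, fdata, params, spec=FrontierSpec()):
        return FrontierFit(
            spec=spec, params=params, loglik=0.0, converged=True, n_iter=1,
            grad_norm=0.0, se={}, n_obs=fdata.n_obs, n_states=fdata.n_states,
            columns=fdata.columns, state_codes=fdata.state_codes,
        )

    def test_posterior_mean_matches_quadrature(self, rng):
        # 1 state beyond the minimum so the fit is well posed; check both
        fdata = toy_fdata(rng, n_states=2, n_years=2)
        params = FrontierParams(beta=np.array([0.05]), sigma_sq=0.7, gamma=0.6, mu=0.15, eta=0.08)
        eps = fdata.y - fdata.X @ params.beta
        mstar, sstar, sums = _state_posterior(params, fdata, eps)
        for s in range(fdata.n_states):
            closed = mstar[s] + sstar[s] * _mills_ratio(np.array([mstar[s] / sstar[s]]))[0]
            assert closed == pytest.approx(quadrature_posterior_mean(params, fdata, s), abs=1e-8)

    def test_small_gamma_scores_near_zero(self):
        config = SyntheticConfig(n_states=10, years=(2000, 2004), seed=3,
                                 frontier=FrontierTruth(sigma_u=0.0, mu=0.0, eta=0.0))
        data, _ = generate_panel(config)
        fdata = build_design(data, FrontierSpec(base_year=2004))
        beta, *_ = np.linalg.lstsq(fdata.X, fdata.y, rcond=None)
        params = FrontierParams(beta=beta, sigma_sq=0.01, gamma=1e-8, mu=0.0, eta=0.0)
        fit = self.make_fit(fdata, params, FrontierSpec(base_year=2004))
        scores = predict_scores(fit, data)
        assert scores.frame["score"].max() < 0.2
        assert scores.frame["ce"].min() > 0.998

    def test_positive_eta_scores_strictly_decreasing(self):
        config = SyntheticConfig(n_states=12, years=(1999, 2007), seed=5)
        data, _ = generate_panel(config)
        fit = fit_frontier(data, FrontierSpec(), FitOptions(gamma_starts=(0.7,), compute_se=False))
        assert fit.params.eta > 0
        scores = predict_scores(fit, data)
        for _, group in scores.frame.sort_values("year").groupby("state"):
            assert (np.diff(group["score"]) < 0).all()

    def test_unknown_state_raises(self, toy_dataset):
        fdata = build_design(toy_dataset, FrontierSpec(base_year=2001))
        params = FrontierParams(beta=np.zeros(fdata.X.shape[1]), sigma_sq=1.0, gamma=0.5)
        fit = self.make_fit(fdata, params, FrontierSpec(base_year=2001))
        other = PanelDataset(make_frame([("TX", 1999), ("TX", 2000)]))
        with pytest.raises(KeyError, match="TX"):
            predict_scores(fit, other)

    def test_ce_score_identity(self):
        config = SyntheticConfig(n_states=8, years=(2000, 2004), seed=1)
        data, _ = generate_panel(config)
        fit = fit_frontier(data, FrontierSpec(base_year=2004),
                           FitOptions(gamma_starts=(0.7,), compute_se=False))
        scores = predict_scores(fit, data)
        np.testing.assert_allclose(scores.frame["ce"], np.exp(-scores.frame["score"] / 100.0))
        assert (scores.frame["score"] >= 0).all()
        assert ((scores.frame["ce"] > 0) & (scores.frame["ce"] <= 1)).all()


class TestFitFrontier:
    def test_no_inefficiency_collapses_to_ols(self):
        config = SyntheticConfig(n_states=30, years=(1999, 2007), seed=21,
                                 frontier=FrontierTruth(sigma_u=0.0, mu=0.0, eta=0.0))
        data, _ = generate_panel(config)
        fit = fit_frontier(data, FrontierSpec(), FitOptions(gamma_starts=(0.1, 0.5), compute_se=False))
        fdata = build_design(data, FrontierSpec())
        beta_ols, *_ = np.linalg.lstsq(fdata.X, fdata.y, rcond=None)
        resid = fdata.y - fdata.X @ beta_ols
        cov = np.linalg.inv(fdata.X.T @ fdata.X) * (resid @ resid) / (fdata.n_obs - fdata.X.shape[1])
        se_ols = np.sqrt(np.diag(cov))
        assert fit.params.gamma < 0.2
        np.testing.assert_array_less(np.abs(fit.params.beta - beta_ols), 2 * se_ols + 1e-8)

    def test_refit_deterministic(self):
        config = SyntheticConfig(n_states=10, years=(2000, 2004), seed=8)
        data, _ = generate_panel(config)
        opts = FitOptions(gamma_starts=(0.5, 0.9), compute_se=False)
        a = fit_frontier(data, FrontierSpec(base_year=2004), opts)
        b = fit_frontier(data, FrontierSpec(base_year=2004), opts)
        np.testing.assert_array_equal(a.params.beta, b.params.beta)
        assert a.loglik == b.loglik

    def test_hnormal_nested_in_tnormal(self):
        config = SyntheticConfig(n_states=15, years=(2000, 2005), seed=4)
        data, _ = generate_panel(config)
        opts = FitOptions(gamma_starts=(0.5, 0.9), compute_se=False)
        ll_h = fit_frontier(data, FrontierSpec(distribution="hnormal", base_year=2005), opts).loglik
        ll_t = fit_frontier(data, FrontierSpec(distribution="tnormal", base_year=2005), opts).loglik
        assert ll_h <= ll_t + 1e-4

    def test_exponential_pooled_fit_runs(self):
        config = SyntheticConfig(n_states=15, years=(2000, 2005), seed=4)
        data, _ = generate_panel(config)
        spec = FrontierSpec(distribution="exponential", time_varying=False, base_year=2005)
        fit = fit_frontier(data, spec, FitOptions(gamma_starts=(0.5,), compute_se=False))
        assert np.isfinite(fit.loglik)
        assert fit.params.eta == 0.0

    def test_parameter_recovery_smoke(self):
        config = SyntheticConfig(n_states=50, years=(1999, 2007), seed=17)
        data, _ = generate_panel(config)
        fit = fit_frontier(data, FrontierSpec(), FitOptions(gamma_starts=(0.5, 0.9)))
        assert fit.converged
        coef = dict(zip(fit.columns, fit.params.beta))
        assert coef["log_q_hcbs"] == pytest.approx(0.22, abs=0.08)
        assert coef["log_q_inst"] == pytest.approx(0.17, abs=0.08)
        assert fit.params.eta == pytest.approx(0.011, abs=0.02)
        assert fit.se.get("log_q_hcbs", np.nan) > 0

    def test_serialization(self):
        config = SyntheticConfig(n_states=8, years=(2000, 2003), seed=2)
        data, _ = generate_panel(config)
        fit = fit_frontier(data, FrontierSpec(base_year=2003),
                           FitOptions(gamma_starts=(0.7,), compute_se=False))
        payload = fit.to_dict()
        assert payload["spec"]["distribution"] == "tnormal"
        assert set(payload["params"]["beta"]) == set(fit.columns)
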
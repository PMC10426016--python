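"""State-space models: specs, filtering likelihoods, MLE, comparison."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import revoquant as rq
from revoquant.exceptions import SpecError
from revoquant.pomp import ProductionDynamicsResults


def _fake_result(label, loglik, k, n_obs):
    model = SimpleNamespace(spec=rq.ModelSpec(
        label=label,
        **{f: True for f in _LABEL_FLAGS[label]},
    ))
    return ProductionDynamicsResults(model=model, params=rq.ParamVector(),
                                     loglik=loglik, k=k, n_obs=n_obs,
                                     method="exact", seed=0, converged=True)


_LABEL_FLAGS = {"A": (), "B": ("h2_autoreg",), "C": ("h2_autoreg", "h3_gdp"),
                "D": ("h2_autoreg", "h5_diff")}


def _panel_from_process(n_countries=2, n_steps=30, seed=0, with_gdp=True,
                        params=None, spec=None):
    cfg = rq.GeneratorConfig(
        n_countries=n_countries, time_start=1300,
        time_end=1300 + 10 * (n_steps - 1), time_step=10, seed=seed)
    spec = spec or (rq.model_from_label("C") if with_gdp else rq.model_from_label("B"))
    params = params or rq.ParamVector(
        mu=0.4, rho=0.6, beta_gdp=0.3 if spec.h3_gdp else 0.0,
        sigma_proc=0.3, tau_obs=0.4)
    panel, _ = rq.simulate_panel(cfg, params=params, spec=spec)
    return panel


class TestModelSpec:
    @pytest.mark.parametrize("label,k", [("A", 3), ("B", 4), ("C", 5),
                                         ("D", 5), ("E", 6), ("K", 9)])
    def test_free_parameter_counts(self, label, k):
        assert rq.model_from_label(label).k == k

    def test_interaction_requires_gdp_and_diffusion(self):
        with pytest.raises(SpecError):
            rq.ModelSpec(h2_autoreg=True, h7_interaction=True)
        with pytest.raises(SpecError):
            rq.ModelSpec(h3_gdp=True, h7_interaction=True)

    def test_inactive_parameter_pinned_to_zero(self):
        p = rq.ParamVector(beta_gdp=0.5)
        with pytest.raises(SpecError):
            p.validate(rq.model_from_label("B"))

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(SpecError):
            rq.ParamVector(mu=math.inf).validate(rq.model_from_label("A"))


class TestLikelihood:
    def test_degenerate_filter_matches_closed_form(self):
        """With sigma_proc = 0 and x0 pinned, the latent path is
        deterministic and the likelihood is a sum of Normal densities."""
        panel = _panel_from_process(n_countries=1, n_steps=6, seed=3)
        spec = rq.model_from_label("B")
        model = rq.ProductionDynamics(panel, spec)
        params = rq.ParamVector(mu=0.2, rho=0.5, sigma_proc=0.0, tau_obs=0.4)
        ystar = model.ystar[0]
        x = ystar[0]
        expected = 0.0
        for t in range(1, len(ystar)):
            x = 0.2 + 0.5 * x
            expected += stats.norm.logpdf(ystar[t], loc=x, scale=0.4)
        assert model.kalman_loglik(params) == pytest.approx(expected)
        pf = model.particle_loglik(params, n_particles=50, seed=0)
        assert pf == pytest.approx(expected)

    def test_kalman_matches_independent_oracle(self):
        """Cross-check the vectorized Kalman recursion against a naive
        scalar filter written directly from the state-space equations."""
        panel = _panel_from_process(n_countries=3, n_steps=25, seed=8)
        spec = rq.model_from_label("C")
        model = rq.ProductionDynamics(panel, spec)
        params = rq.ParamVector(mu=0.3, rho=0.55, beta_gdp=0.25,
                                sigma_proc=0.35, tau_obs=0.3)

        total = 0.0
        for c, country in enumerate(model.countries):
            ystar = model.ystar[c]
            zg = model._Z["gdp_z"][c]
            m, P = ystar[0], 0.0
            for t in range(1, len(ystar)):
                m_pred = 0.3 + 0.55 * m + 0.25 * zg[t]
                P_pred = 0.55**2 * P + 0.35**2
                S = P_pred + 0.3**2
                total += stats.norm.logpdf(ystar[t], loc=m_pred, scale=math.sqrt(S))
                K = P_pred / S
                m = m_pred + K * (ystar[t] - m_pred)
                P = (1 - K) * P_pred
        assert model.kalman_loglik(params) == pytest.approx(total)

    def test_particle_filter_agrees_with_kalman(self):
        panel = _panel_from_process(n_countries=1, n_steps=30, seed=5)
        model = rq.ProductionDynamics(panel, rq.model_from_label("C"))
        params = rq.ParamVector(mu=0.4, rho=0.6, beta_gdp=0.3,
                                sigma_proc=0.3, tau_obs=0.4)
        exact = model.kalman_loglik(params)
        pf, se = model.particle_loglik(params, n_particles=2000, seed=11,
                                       return_se=True)
        assert abs(pf - exact) <= 3 * se

    def test_duplicated_country_doubles_loglik(self):
        panel = _panel_from_process(n_countries=1, n_steps=15, seed=6)
        twin = panel.assign(country="twin")
        both = pd.concat([panel, twin], ignore_index=True)
        spec = rq.model_from_label("C")
        params = rq.ParamVector(mu=0.4, rho=0.6, beta_gdp=0.3,
                                sigma_proc=0.3, tau_obs=0.4)
        single = rq.ProductionDynamics(panel, spec).kalman_loglik(params)
        # recompute the z-scored covariates on the doubled panel so both
        # copies carry identical columns
        double = rq.ProductionDynamics(both, spec).kalman_loglik(params)
        assert double == pytest.approx(2 * single)

    def test_pf_variance_shrinks_with_particle_count(self):
        panel = _panel_from_process(n_countries=1, n_steps=20, seed=7)
        model = rq.ProductionDynamics(panel, rq.model_from_label("B"))
        params = rq.ParamVector(mu=0.4, rho=0.6, sigma_proc=0.3, tau_obs=0.4)
        variances = []
        for n in (50, 200, 800):
            lls = [model.particle_loglik(params, n_particles=n, seed=s)
                   for s in range(12)]
            variances.append(np.var(lls))
        assert variances[2] < variances[0]

    def test_pf_deterministic_in_seed(self):
        panel = _panel_from_process(n_countries=2, n_steps=10, seed=1)
        model = rq.ProductionDynamics(panel, rq.model_from_label("B"))
        params = rq.ParamVector(mu=0.4, rho=0.6, sigma_proc=0.3, tau_obs=0.4)
        a = model.particle_loglik(params, n_particles=100, seed=42)
        b = model.particle_loglik(params, n_particles=100, seed=42)
        assert a == b


class TestFit:
    def test_nested_model_never_beats_full(self):
        panel = _panel_from_process(n_countries=4, n_steps=30, seed=12)
        fit_b = rq.ProductionDynamics(panel, rq.model_from_label("B")).fit()
        fit_c = rq.ProductionDynamics(panel, rq.model_from_label("C")).fit(
            starts=[fit_b.params, rq.ParamVector(mu=0.3, rho=0.3,
                                                 sigma_proc=0.3, tau_obs=0.3)])
        assert fit_c.loglik >= fit_b.loglik - 1e-6

    def test_fit_deterministic_under_crn(self):
        panel = _panel_from_process(n_countries=2, n_steps=12, seed=2)
        model = rq.ProductionDynamics(panel, rq.model_from_label("B"))
        start = [rq.ParamVector(mu=0.3, rho=0.4, sigma_proc=0.3, tau_obs=0.3)]
        a = model.fit(starts=start, method="pf", n_particles=100, seed=9)
        b = model.fit(starts=start, method="pf", n_particles=100, seed=9)
        assert a.loglik == b.loglik
        assert a.params.to_free_array(a.spec).tolist() == \
            b.params.to_free_array(b.spec).tolist()

    def test_standard_errors_finite_at_optimum(self):
        panel = _panel_from_process(n_countries=4, n_steps=30, seed=13)
        res = rq.ProductionDynamics(panel, rq.model_from_label("C")).fit()
        se = res.bse()
        assert all(np.isfinite(v) and v > 0 for v in se.values())


class TestComparison:
    def test_information_criteria_formulas(self):
        res = _fake_result("A", loglik=-100.0, k=3, n_obs=55)
        assert res.aic == pytest.approx(206.0)
        assert res.bic == pytest.approx(3 * math.log(55) + 200, abs=1e-6)
        assert res.bic == pytest.approx(212.02, abs=0.01)

    def test_compare_table_sorted_by_aic(self):
        fits = [_fake_result("A", -105.0, 3, 55), _fake_result("B", -100.0, 4, 55)]
        table = rq.compare_models(fits)
        assert list(table["model"]) == ["B", "A"]
        assert table.loc[0, "delta_aic"] == 0.0

    def test_useless_parameter_raises_aic(self):
        base = _fake_result("B", -100.0, 4, 55)
        extra = _fake_result("C", -99.5, 5, 55)  # gain below one loglik unit
        assert extra.aic > base.aic

    def test_mismatched_nobs_rejected(self):
        with pytest.raises(ValueError):
            rq.compare_models([_fake_result("A", -10, 3, 50),
                               _fake_result("B", -9, 4, 55)])


class TestLRT:
    def test_zero_deviance_p_one(self):
        a = _fake_result("A", -100.0, 3, 55)
        b = _fake_result("B", -100.0, 4, 55)
        out = rq.lrt(a, b)
        assert out.deviance == 0.0 and out.p == pytest.approx(1.0)

    @pytest.mark.parametrize("dev,p", [(3.841, 0.050), (2.706, 0.100)])
    def test_chi2_upper_tail(self, dev, p):
        a = _fake_result("A", -100.0, 3, 55)
        b = _fake_result("B", -100.0 + dev / 2, 4, 55)
        assert rq.lrt(a, b).p == pytest.approx(p, abs=5e-4)

    def test_negative_deviance_clipped_with_warning(self):
        a = _fake_result("A", -99.0, 3, 55)
        b = _fake_result("B", -100.0, 4, 55)
        with pytest.warns(UserWarning):
            out = rq.lrt(a, b)
        assert out.deviance == 0.0

    def test_non_nested_pair_rejected(self):
        c = _fake_result("C", -100.0, 5, 55)
        d = _fake_result("D", -99.0, 5, 55)
        with pytest.raises(SpecError):
            rq.lrt(c, d)
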
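import numpy as np
import pytest

import fertimap as fm
from fertimap.mcmc import MCMCConfig, PosteriorDraws


def _rr_draws(beta1, delta, periods=("P1", "P2", "P3")):
    """PosteriorDraws carrying only the regression coefficients."""
    beta1 = np.asarray(beta1, dtype=float)[None, :]  # one chain
    delta = np.asarray(delta, dtype=float)[None, :, :]
    params = {
        "beta1": beta1,
        "delta": delta,
        "alpha": np.zeros((*beta1.shape, delta.shape[2])),
        "tau_u": np.ones(beta1.shape),
        "tau_v": np.ones(beta1.shape),
    }
    cfg = MCMCConfig(seed=0, n_chains=1, n_iter=beta1.shape[1], burn_in=0, thin=1)
    return PosteriorDraws(params=params, periods=periods, config=cfg)


class TestRelativeRisk:
    def test_null_effect(self):
        d = _rr_draws(np.zeros(50), np.zeros((50, 3)))
        rr = fm.relative_risk(d, (-1.6, 1.7))
        assert np.allclose(rr.rr, 1.0)
        assert not rr.sig_12 and not rr.sig_23

    def test_closed_form_doubling(self):
        span = 3.3
        d = _rr_draws(np.full(50, np.log(2) / span), np.zeros((50, 3)))
        rr = fm.relative_risk(d, (0.0, span))
        assert np.allclose(rr.rr, 2.0)

    def test_lognormal_summaries(self):
        """beta1 ~ N(mu, sigma^2): RR quantiles follow the lognormal closed form."""
        mu, sigma, span = 0.12, 0.03, 3.0
        rng = np.random.default_rng(5)
        b = mu + sigma * rng.standard_normal(100_000)
        d = _rr_draws(b, np.zeros((100_000, 3)))
        rr = fm.relative_risk(d, (0.0, span))
        assert rr.rr[0] == pytest.approx(np.exp(mu * span), rel=0.005)
        assert rr.lo95[0] == pytest.approx(np.exp((mu - 1.96 * sigma) * span), rel=0.01)
        assert rr.hi95[0] == pytest.approx(np.exp((mu + 1.96 * sigma) * span), rel=0.01)

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(6)
        b = 0.05 * rng.standard_normal(2000)
        delta = 0.02 * rng.standard_normal((2000, 3))
        lo = fm.relative_risk(_rr_draws(b, delta), (0.0, 3.0))
        hi = fm.relative_risk(_rr_draws(b + 0.1, delta), (0.0, 3.0))
        assert (hi.rr > lo.rr).all()
        assert (hi.lo95 > lo.lo95).all() and (hi.hi95 > lo.hi95).all()

    def test_change_rule_reparameterization_invariant(self):
        """Testing delta3 - delta2 is the same as testing beta3 - beta2."""
        rng = np.random.default_rng(7)
        b = rng.standard_normal(5000) * 0.1
        delta = rng.standard_normal((5000, 3)) * 0.05
        delta[:, 0] = 0.0
        rr = fm.relative_risk(_rr_draws(b, delta), (0.0, 3.0))
        beta_p = b[:, None] + delta
        contrast = beta_p[:, 2] - beta_p[:, 1]
        lo, hi = np.percentile(contrast, [2.5, 97.5])
        assert rr.sig_23 == bool(lo > 0 or hi < 0)

    def test_invalid_span(self):
        d = _rr_draws(np.zeros(10), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            fm.relative_risk(d, (1.0, 1.0))


class TestFitEcoregression:
    def test_missing_period_rejected(self, small_city):
        sub = small_city.counts.query(
            "age_group == '25-34' and nationality == 'Spanish' and period != 'P2'"
        )
        cfg = MCMCConfig(seed=0, n_iter=10, burn_in=0, thin=1)
        with pytest.raises(ValueError, match="P2"):
            fm.fit_ecoregression(sub, small_city.index, small_city.graph, cfg)

    def test_row_order_irrelevant(self, small_city):
        """Shuffling the counts rows cannot change the fit: alignment is by id."""
        sub = small_city.counts.query("age_group == '25-34' and nationality == 'LIC'")
        cfg = MCMCConfig(seed=14, n_chains=2, n_iter=80, burn_in=60, thin=1)
        d1 = fm.fit_ecoregression(sub, small_city.index, small_city.graph, cfg)
        shuffled = sub.sample(frac=1.0, random_state=3)
        d2 = fm.fit_ecoregression(shuffled, small_city.index, small_city.graph, cfg)
        for k in ("beta1", "delta", "alpha"):
            assert np.array_equal(d1.params[k], d2.params[k])

    def test_recovers_strong_effect_direction(self):
        """A strong positive deprivation effect yields RR > 1 with CI above 1."""
        city = fm.simulate_city(8, 8, seed=31, rr_targets=(2.5, 2.5, 2.5))
        sub = city.counts.query("age_group == '25-34' and nationality == 'LIC'")
        cfg = MCMCConfig(seed=15, n_chains=2, n_iter=800, burn_in=500, thin=1)
        d = fm.fit_ecoregression(sub, city.index, city.graph, cfg)
        rr = fm.relative_risk(d, (city.index.q5, city.index.q95))
        assert (rr.lo95 > 1.0).all()
        assert rr.rr == pytest.approx([2.5, 2.5, 2.5], rel=0.35)


class TestRunStratifiedAnalysis:
    def test_table_shape_and_flags(self, small_city):
        cfg = MCMCConfig(seed=5, n_chains=2, n_iter=60, burn_in=40, thin=1)
        table = fm.run_stratified_analysis(
            small_city.counts, small_city.index, small_city.graph, cfg
        )
        # 5 age rows x 2 nationality panels x 3 period columns
        assert len(table) == 5 * 2 * 3
        assert set(table.columns) >= {"rr", "lo95", "hi95", "sig_12", "sig_23", "sparse"}
        assert (table.rr > 0).all()
        assert (table.lo95 <= table.rr).all() and (table.rr <= table.hi95).all()
        assert not table["sparse"].any()

    def test_empty_period_names_stratum(self, small_city):
        counts = small_city.counts.copy()
        mask = (
            (counts.age_group == "35-49") & (counts.nationality == "LIC") & (counts.period == "P3")
        )
        counts.loc[mask, ["births", "women"]] = 0
        cfg = MCMCConfig(seed=5, n_iter=10, burn_in=0, thin=1)
        with pytest.raises(ValueError, match="35-49.*LIC"):
            fm.run_stratified_analysis(counts, small_city.index, small_city.graph, cfg)
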
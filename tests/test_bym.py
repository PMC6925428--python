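import numpy as np
import pytest

import fertimap as fm
from fertimap.mcmc import MCMCConfig, PosteriorDraws


def _draws(alpha, u=None, v=None, periods=("P1",)):
    """Hand-built degenerate posterior for summary-level tests."""
    params = {"alpha": np.asarray(alpha, dtype=float)}
    if u is not None:
        params["u"] = np.asarray(u, dtype=float)
    if v is not None:
        params["v"] = np.asarray(v, dtype=float)
    params["tau_u"] = np.ones(params["alpha"].shape[:2])
    params["tau_v"] = np.ones(params["alpha"].shape[:2])
    cfg = MCMCConfig(seed=0, n_chains=params["alpha"].shape[0], n_iter=params["alpha"].shape[1], burn_in=0, thin=1)
    return PosteriorDraws(params=params, periods=periods, config=cfg)


class TestBYMModelValidation:
    def test_size_mismatch(self, lattice_4x5):
        _, g = lattice_4x5
        with pytest.raises(ValueError):
            fm.BYMModel(graph=g, O=np.zeros(3), N=np.ones(3))

    def test_all_zero_denominators(self, lattice_4x5):
        _, g = lattice_4x5
        with pytest.raises(ValueError, match="positive denominator"):
            fm.BYMModel(graph=g, O=np.zeros(g.n), N=np.zeros(g.n))


class TestFitBym:
    def test_conjugate_limit_small(self, lattice_4x5):
        """Fields off: rate posterior equals the Poisson-Gamma closed form."""
        _, g = lattice_4x5
        rng = np.random.default_rng(1)
        N = np.full(g.n, 2000.0)
        O = rng.poisson(0.05 * N)
        a, b = 2.0, 10.0
        model = fm.BYMModel(graph=g, O=O, N=N, alpha_prior=(a, b), spatial=False, heterogeneous=False)
        cfg = MCMCConfig(seed=5, n_chains=2, n_iter=2000, burn_in=500, thin=1)
        d = fm.fit_bym(model, cfg)
        lam = np.exp(d.stacked("alpha")[:, 0])
        pa, pb = a + O.sum(), b + N.sum()
        # generous Monte-Carlo band for the short unit-test chains
        assert lam.mean() == pytest.approx(pa / pb, rel=0.02)
        assert lam.var() == pytest.approx(pa / pb**2, rel=0.4)

    def test_determinism(self, lattice_4x5):
        _, g = lattice_4x5
        rng = np.random.default_rng(2)
        N = np.full(g.n, 500.0)
        O = rng.poisson(0.03 * N)
        model = fm.BYMModel(graph=g, O=O, N=N)
        cfg = MCMCConfig(seed=9, n_chains=2, n_iter=100, burn_in=80, thin=1)
        r1 = fm.smoothed_rates(fm.fit_bym(model, cfg), model)
        r2 = fm.smoothed_rates(fm.fit_bym(model, cfg), model)
        assert np.array_equal(r1.mean, r2.mean)
        assert np.array_equal(r1.lo95, r2.lo95)


class TestSmoothedRates:
    def test_degenerate_draws(self):
        tracts, g = fm.generate_lattice(1, 3)
        alpha = np.full((1, 5, 1), np.log(0.04))
        d = _draws(alpha)
        model = fm.BYMModel(graph=g, O=np.array([1, 2, 3]), N=np.array([100, 100, 100.0]),
                            spatial=False, heterogeneous=False)
        sm = fm.smoothed_rates(d, model)
        assert np.allclose(sm.mean, 40.0)
        assert np.allclose(sm.hi95 - sm.lo95, 0.0)

    def test_large_population_tract_tracks_crude_rate(self):
        """Likelihood dominance: N = 1e6 pins the smoothed rate to the crude."""
        tracts, g = fm.generate_lattice(3, 3)
        rng = np.random.default_rng(3)
        N = np.full(g.n, 500.0)
        N[4] = 1e6
        O = rng.poisson(0.05 * N).astype(float)
        model = fm.BYMModel(graph=g, O=O, N=N)
        cfg = MCMCConfig(seed=11, n_chains=2, n_iter=1500, burn_in=700, thin=1)
        sm = fm.smoothed_rates(fm.fit_bym(model, cfg), model)
        crude = 1000.0 * O[4] / N[4]
        assert abs(sm.mean[4] - crude) < 0.01 * crude

    def test_empty_tract_flagged(self):
        tracts, g = fm.generate_lattice(1, 4)
        N = np.array([0.0, 300, 300, 300])
        O = np.array([0.0, 9, 12, 15])
        model = fm.BYMModel(graph=g, O=O, N=N)
        cfg = MCMCConfig(seed=2, n_chains=2, n_iter=200, burn_in=150, thin=1)
        sm = fm.smoothed_rates(fm.fit_bym(model, cfg), model)
        assert sm.flagged_empty.tolist() == [True, False, False, False]
        assert np.isfinite(sm.mean).all()

    def test_shrinkage_reduces_variance(self, small_city):
        """Across-tract variance of smoothed means <= variance of crude rates."""
        sub = small_city.counts.query(
            "age_group == '15-49' and nationality == 'Spanish' and period == 'P1'"
        )
        agg = sub.groupby("tract_id", sort=False)[["births", "women"]].sum()
        agg = agg.reindex(list(small_city.tracts.tract_id), fill_value=0)
        model = fm.BYMModel(graph=small_city.graph, O=agg.births.to_numpy(), N=agg.women.to_numpy())
        cfg = MCMCConfig(seed=8, n_chains=2, n_iter=600, burn_in=400, thin=1)
        sm = fm.smoothed_rates(fm.fit_bym(model, cfg), model)
        crude = 1000.0 * agg.births / agg.women
        assert sm.mean.var() <= crude.var()
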
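import numpy as np
import pytest
from scipy import stats

import fertimap as fm
from fertimap import mcmc
from fertimap.mcmc import ConvergenceWarning, MCMCConfig, sample_poisson_bym

from conftest import random_connected_graph


class TestIcarLogKernel:
    def test_zero_field(self, lattice_4x5):
        _, graph = lattice_4x5
        tau = 3.0
        val = fm.icar_log_kernel(np.zeros(graph.n), graph, tau)
        assert val == pytest.approx(0.5 * (graph.n - 1) * np.log(tau))

    def test_two_node_pair(self):
        """u = (1, -1), tau = 1: quadratic term is -(1/2) * (2)^2 = -2."""
        g = fm.AdjacencyGraph(n=2, edges=np.array([[0, 1]]))
        assert fm.icar_log_kernel(np.array([1.0, -1.0]), g, 1.0) == pytest.approx(-2.0)

    def test_matches_laplacian_quadratic_form(self, rng):
        """Brute-force oracle: -(tau/2) u' L u on random small graphs."""
        for _ in range(50):
            g = random_connected_graph(rng)
            u = rng.standard_normal(g.n)
            tau = float(rng.uniform(0.1, 5.0))
            expected = -0.5 * tau * u @ g.laplacian() @ u + 0.5 * (g.n - 1) * np.log(tau)
            assert fm.icar_log_kernel(u, g, tau) == pytest.approx(expected, abs=1e-10)

    def test_length_mismatch(self, lattice_4x5):
        with pytest.raises(ValueError):
            fm.icar_log_kernel(np.zeros(3), lattice_4x5[1], 1.0)


class TestTauConditional:
    def test_gibbs_conditional_matches_brute_force_density(self):
        """tau_u | u is Gamma(a + (n-1)/2, b + SS/2); checked on a grid.

        The unnormalized conditional is exp(icar_log_kernel) times the Gamma
        prior; normalizing it numerically must reproduce the closed-form
        Gamma density used by the sampler's Gibbs step.
        """
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng)
        u = rng.standard_normal(g.n)
        u -= u.mean()
        a, b = 0.5, 0.0005
        e = g.edges
        ss = np.sum((u[e[:, 0]] - u[e[:, 1]]) ** 2)
        grid = np.linspace(1e-3, 30, 4000)
        log_dens = np.array([fm.icar_log_kernel(u, g, t) for t in grid])
        log_dens += (a - 1) * np.log(grid) - b * grid
        dens = np.exp(log_dens - log_dens.max())
        dens /= np.trapezoid(dens, grid)
        expected = stats.gamma.pdf(grid, a + (g.n - 1) / 2, scale=1 / (b + ss / 2))
        # tolerance limited by the trapezoid normalization of the brute force
        assert np.abs(dens - expected).max() < 1e-3 * expected.max()


class TestSampler:
    def test_same_seed_identical_draws(self, small_city):
        sub = small_city.counts.query("age_group == '15-49' and nationality == 'Spanish' and period == 'P1'")
        agg = sub.groupby("tract_id", sort=False)[["births", "women"]].sum()
        agg = agg.reindex(list(small_city.tracts.tract_id), fill_value=0)
        cfg = MCMCConfig(seed=21, n_chains=2, n_iter=150, burn_in=100, thin=1)
        kw = dict(spatial=True, heterogeneous=True)
        d1 = sample_poisson_bym(agg.births.to_numpy(), agg.women.to_numpy(), small_city.graph, cfg, **kw)
        d2 = sample_poisson_bym(agg.births.to_numpy(), agg.women.to_numpy(), small_city.graph, cfg, **kw)
        for k in d1.params:
            assert np.array_equal(d1.params[k], d2.params[k])

    def test_u_draws_sum_to_zero(self, small_city):
        sub = small_city.counts.query("age_group == '15-49' and nationality == 'LIC' and period == 'P2'")
        agg = sub.groupby("tract_id", sort=False)[["births", "women"]].sum()
        agg = agg.reindex(list(small_city.tracts.tract_id), fill_value=0)
        cfg = MCMCConfig(seed=4, n_chains=2, n_iter=100, burn_in=50, thin=1)
        d = sample_poisson_bym(agg.births.to_numpy(), agg.women.to_numpy(), small_city.graph, cfg)
        u = d.params["u"]  # (chains, draws, n, 1)
        assert np.abs(u.sum(axis=2)).max() < 1e-8
        assert (d.params["tau_u"] > 0).all() and (d.params["tau_v"] > 0).all()

    def test_births_without_women_rejected(self, lattice_4x5):
        _, g = lattice_4x5
        O = np.zeros(g.n); O[0] = 3
        N = np.zeros(g.n); N[1] = 10
        cfg = MCMCConfig(seed=0, n_iter=10, burn_in=0, thin=1)
        with pytest.raises(ValueError, match="zero woman-years"):
            sample_poisson_bym(O, N, g, cfg)

    def test_nonconvergence_warns_and_records(self, lattice_4x5, monkeypatch):
        _, g = lattice_4x5
        rng = np.random.default_rng(0)
        N = np.full(g.n, 100.0)
        O = rng.poisson(0.05 * N)
        monkeypatch.setattr(mcmc, "gelman_rubin", lambda d: {"alpha[P1]": 3.0})
        cfg = MCMCConfig(seed=1, n_chains=2, n_iter=20, burn_in=10, thin=1)
        with pytest.warns(ConvergenceWarning):
            d = sample_poisson_bym(O, N, g, cfg)
        assert d.warnings and "R-hat" in d.warnings[0]


class TestGelmanRubin:
    def test_identical_constant_chains_report_one(self):
        a = np.ones((2, 100))
        assert fm.gelman_rubin({"p": a})["p"] == 1.0

    def test_stationary_normal_chains_near_one(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((2, 10_000))
        assert fm.gelman_rubin({"p": a})["p"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(9)
        a = np.stack([rng.standard_normal(500), 10 + rng.standard_normal(500)])
        assert fm.gelman_rubin({"p": a})["p"] > 3

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            fm.gelman_rubin({"p": np.zeros((1, 100))})

    def test_agrees_with_arviz(self):
        """Independent cross-check of split R-hat against arviz."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(10)
        # AR(1) chains with different means: moderate, comparable R-hat
        eps = rng.standard_normal((2, 2000))
        a = np.empty_like(eps)
        a[:, 0] = eps[:, 0]
        for t in range(1, eps.shape[1]):
            a[:, t] = 0.7 * a[:, t - 1] + eps[:, t]
        a[1] += 0.3
        ours = fm.gelman_rubin({"p": a})["p"]
        theirs = float(az.rhat(az.convert_to_dataset(a))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.05)
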
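import numpy as np
import pytest

import fertimap as fm
from fertimap.deprivation import INDICATOR_COLUMNS
from fertimap.graph import DisconnectedGraphError
from fertimap.synthetic import sample_populations


class TestIcarField:
    def test_sums_to_zero(self, lattice_4x5):
        _, graph = lattice_4x5
        u = fm.sample_icar_field(graph, tau_u=3.0, seed=0, size=50)
        assert np.abs(u.sum(axis=1)).max() < 1e-10

    def test_two_tract_marginal_variance(self):
        """On 2 tracts, u = (z, -z) with z ~ N(0, 1/(4 tau))."""
        g = fm.AdjacencyGraph(n=2, edges=np.array([[0, 1]]))
        u = fm.sample_icar_field(g, tau_u=1.0, seed=7, size=10_000)
        assert np.allclose(u[:, 0], -u[:, 1])
        var = u[:, 0].var()
        se = 0.25 * np.sqrt(2 / 10_000)  # sd of a chi2-based variance estimate
        assert abs(var - 0.25) < 4 * se

    def test_covariance_matches_laplacian_pseudoinverse(self):
        """Empirical covariance equals pinv(tau * L) on a small graph."""
        g = fm.AdjacencyGraph(n=5, edges=np.array([[0, 1], [1, 2], [2, 3], [3, 4], [0, 4], [1, 3]]))
        tau = 2.5
        u = fm.sample_icar_field(g, tau_u=tau, seed=11, size=40_000)
        emp = np.cov(u.T)
        expected = np.linalg.pinv(tau * g.laplacian())
        assert np.abs(emp - expected).max() < 0.02

    def test_high_precision_limit(self, lattice_4x5):
        _, graph = lattice_4x5
        u = fm.sample_icar_field(graph, tau_u=1e6, seed=0)
        assert np.abs(u).max() < 0.05

    def test_disconnected_rejected(self):
        g = fm.AdjacencyGraph(n=4, edges=np.array([[0, 1], [2, 3]]))
        with pytest.raises(DisconnectedGraphError):
            fm.sample_icar_field(g, tau_u=1.0, seed=0)

    def test_bad_precision_rejected(self, lattice_4x5):
        with pytest.raises(ValueError):
            fm.sample_icar_field(lattice_4x5[1], tau_u=0.0, seed=0)


class TestIndicators:
    def test_zero_noise_columns_identical_up_to_shift(self, lattice_4x5):
        tracts, graph = lattice_4x5
        ind = fm.generate_indicators(tracts, graph, loadings=(1, 1, 1, 1, 1), noise_sd=0.0, seed=4)
        cols = [ind[c].to_numpy() for c in INDICATOR_COLUMNS]
        for c in cols[1:]:
            diff = c - cols[0]
            assert np.ptp(diff) < 1e-12  # constant shift only

    def test_single_factor_dominates(self):
        tracts, graph = fm.generate_lattice(20, 20)
        ind = fm.generate_indicators(tracts, graph, noise_sd=0.1, seed=9)
        mat = ind[list(INDICATOR_COLUMNS)].to_numpy()
        z = (mat - mat.mean(0)) / mat.std(0)
        eigvals = np.linalg.eigvalsh(np.corrcoef(z.T))
        assert eigvals[-1] / 5 > 0.75  # first PC explains > 75% of variance

    def test_deterministic_under_seed(self, lattice_4x5):
        tracts, graph = lattice_4x5
        a = fm.generate_indicators(tracts, graph, seed=33)
        b = fm.generate_indicators(tracts, graph, seed=33)
        assert a.equals(b)

    def test_negative_noise_rejected(self, lattice_4x5):
        with pytest.raises(ValueError):
            fm.generate_indicators(*lattice_4x5, noise_sd=-1.0, seed=0)


class TestSimulateCounts:
    @staticmethod
    def _truth(n, alpha=np.log(0.05), beta=0.0):
        return fm.GroundTruth(
            alpha=[alpha], beta=[beta], tau_u=1.0, tau_v=1.0,
            u=np.zeros(n), v=np.zeros(n), seed=0,
        )

    def test_zero_population_gives_zero_births(self, lattice_4x5):
        tracts, graph = lattice_4x5
        n = tracts.n_tracts
        N = np.zeros(n)
        df = fm.simulate_counts(tracts, graph, np.zeros(n), self._truth(n), N, seed=1,
                                periods=("P1",))
        assert (df["births"] == 0).all()

    def test_poisson_mean(self):
        """alpha = log(0.05), N = 1000 -> mean count 50 within 3 SE of 1000 replicates."""
        tracts, graph = fm.generate_lattice(1, 2)
        truth = self._truth(2)
        rng = np.random.default_rng(77)
        means = [
            fm.simulate_counts(tracts, graph, np.zeros(2), truth, np.full(2, 1000.0),
                               seed=rng, periods=("P1",))["births"].mean()
            for _ in range(1000)
        ]
        se = np.sqrt(50.0 / (1000 * 2))  # Poisson var = mean, 2 tracts per rep
        assert abs(np.mean(means) - 50.0) < 3 * se

    def test_doubling_population_doubles_expected_births(self):
        tracts, graph = fm.generate_lattice(1, 2)
        truth = self._truth(2)
        reps = 400
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(6)
        tot1 = sum(fm.simulate_counts(tracts, graph, np.zeros(2), truth, np.full(2, 1000.0),
                                      seed=rng1, periods=("P1",))["births"].sum() for _ in range(reps))
        tot2 = sum(fm.simulate_counts(tracts, graph, np.zeros(2), truth, np.full(2, 2000.0),
                                      seed=rng2, periods=("P1",))["births"].sum() for _ in range(reps))
        ratio = tot2 / tot1
        assert abs(ratio - 2.0) < 0.1

    def test_overflow_guard(self, lattice_4x5):
        tracts, graph = lattice_4x5
        n = tracts.n_tracts
        truth = self._truth(n, alpha=800.0)
        with pytest.raises(ValueError, match="rescale"):
            fm.simulate_counts(tracts, graph, np.zeros(n), truth, np.full(n, 10.0), seed=0,
                               periods=("P1",))


class TestSimulateCity:
    def test_deterministic_under_seed(self):
        a = fm.simulate_city(4, 4, seed=99)
        b = fm.simulate_city(4, 4, seed=99)
        assert a.counts.equals(b.counts)
        assert a.indicators.equals(b.indicators)
        assert np.array_equal(a.index.x, b.index.x)

    def test_age_all_cells_are_sums(self, small_city):
        c = small_city.counts
        narrow = c[c["age_group"] != "15-49"].groupby(
            ["tract_id", "period", "nationality"])[["births", "women"]].sum()
        wide = c[c["age_group"] == "15-49"].set_index(
            ["tract_id", "period", "nationality"])[["births", "women"]]
        assert narrow.sort_index().equals(wide.sort_index())

    def test_rr_targets_fix_true_slopes(self):
        city = fm.simulate_city(5, 5, seed=1, rr_targets=(1.0, 1.5, 2.0))
        truth = next(iter(city.truths.values()))
        rr = np.exp(truth.beta * city.index.span)
        assert np.allclose(rr, [1.0, 1.5, 2.0])

    def test_populations_lognormal_scale(self):
        women = sample_populations(5000, median_women=500.0, log_sd=0.25, seed=3)
        med = np.median(women)
        assert 450 < med < 550
        assert (women >= 1).all()
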
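import math

import numpy as np
import pytest

from idpchar import ensemble as ens
from idpchar.saxs import SAXSCurve


def naive_debye(coords, s_grid):
    """Reference double-loop Debye sum, independent of the fast path."""
    n = len(coords)
    out = np.zeros(len(s_grid))
    for k, s in enumerate(s_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                r = math.dist(coords[i], coords[j])
                x = s * r
                total += 1.0 if x == 0 else math.sin(x) / x
        out[k] = total
    return out


class TestChainGeneration:
    def test_two_point_chain_rg(self):
        rng = np.random.default_rng(0)
        chain = ens.generate_chain(2, rng)
        assert chain.rg == pytest.approx(1.9)

    def test_bond_lengths_and_clashes(self):
        rng = np.random.default_rng(1)
        chain = ens.generate_chain(80, rng)
        bonds = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 3.8, atol=0.01)
        # no non-adjacent pair inside the clash radius
        from scipy.spatial.distance import squareform, pdist
        d = squareform(pdist(chain.coords))
        n = len(chain.coords)
        ii, jj = np.triu_indices(n, k=3)
        assert d[ii, jj].min() >= 4.0 - 1e-9

    def test_pool_determinism(self):
        a = ens.generate_pool(40, 5, seed=7)
        b = ens.generate_pool(40, 5, seed=7)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.coords, cb.coords)

    def test_different_seeds_differ(self):
        a = ens.generate_pool(40, 2, seed=1)
        b = ens.generate_pool(40, 2, seed=2)
        assert not np.allclose(a.chains[0].coords, b.chains[0].coords)

    def test_impossible_geometry_errors(self):
        # clash radius beyond the maximal 3-bond span (3 * 3.8 = 11.4 A)
        # makes the i, i-3 constraint unsatisfiable
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError):
            ens.generate_chain(60, rng, clash_radius=12.0, max_step_retries=5,
                               max_restarts=3)

    def test_rg_grows_with_chain_length(self):
        r50 = ens.generate_pool(50, 15, seed=3).rgs.mean()
        r150 = ens.generate_pool(150, 15, seed=3).rgs.mean()
        assert r150 > r50


class TestDebyeEngine:
    def test_forward_scattering_is_n_squared(self, small_pool):
        i = ens.debye_intensity(small_pool.chains[0].coords, np.array([0.0]))
        assert i[0] == pytest.approx(60**2)

    def test_two_point_closed_form(self):
        d = 5.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        s = np.array([0.1, 0.5, math.pi / d])
        expected = 2.0 * (1.0 + np.sin(s * d) / (s * d))
        np.testing.assert_allclose(ens.debye_intensity(coords, s), expected,
                                   rtol=1e-12)
        assert ens.debye_intensity(coords, s)[2] == pytest.approx(2.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(4)
        chain = ens.generate_chain(15, rng)
        s = np.linspace(0.0, 0.4, 9)
        fast = ens.debye_intensity(chain.coords, s)
        slow = naive_debye(chain.coords, s)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        chain = ens.generate_chain(20, rng)
        s = np.linspace(0.01, 0.3, 10)
        base = ens.debye_intensity(chain.coords, s)
        # rotate about z by 40 degrees and translate
        t = math.radians(40.0)
        rot = np.array([[math.cos(t), -math.sin(t), 0],
                        [math.sin(t), math.cos(t), 0], [0, 0, 1]])
        moved = chain.coords @ rot.T + np.array([5.0, -3.0, 11.0])
        np.testing.assert_allclose(ens.debye_intensity(moved, s), base,
                                   rtol=1e-10)


class TestGASelection:
    @pytest.fixture(scope="class")
    def pool_with_intensities(self, small_pool):
        s = np.geomspace(0.005, 0.35, 40)
        small_pool.compute_intensities(s)
        return small_pool, s

    def test_planted_single_conformer_recovered(self, pool_with_intensities):
        pool, s = pool_with_intensities
        target_i = pool.intensities[123] * 3.5
        target = SAXSCurve(s=s, intensity=target_i, sigma=0.01 * target_i)
        fit = ens.ga_select(pool, target, ensemble_size=1, population=60,
                            generations=60, seed=5)
        assert set(fit.indices) == {123}
        assert fit.chi2 < 1e-12
        assert fit.scale == pytest.approx(3.5)

    def test_chi2_history_non_increasing(self, pool_with_intensities):
        pool, s = pool_with_intensities
        target_i = pool.intensities[:10].mean(axis=0)
        target = SAXSCurve(s=s, intensity=target_i, sigma=0.01 * target_i)
        fit = ens.ga_select(pool, target, ensemble_size=5, population=40,
                            generations=30, seed=9)
        hist = np.array(fit.chi2_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_zero_generations_returns_best_random(self, pool_with_intensities):
        pool, s = pool_with_intensities
        target_i = pool.intensities[7]
        target = SAXSCurve(s=s, intensity=target_i, sigma=0.01 * target_i)
        fit = ens.ga_select(pool, target, ensemble_size=3, population=30,
                            generations=0, seed=2)
        assert len(fit.chi2_history) == 1
        assert fit.chi2 == fit.chi2_history[0]

    def test_ga_beats_best_single_and_random(self, pool_with_intensities):
        # chi2(GA) <= chi2(best single conformer) <= mean chi2(random picks)
        pool, s = pool_with_intensities
        rng = np.random.default_rng(0)
        planted = rng.choice(len(pool), 8, replace=False)
        target_i = pool.intensities[planted].mean(axis=0)
        sigma = 0.01 * target_i
        target = SAXSCurve(s=s, intensity=target_i + rng.normal(0, sigma),
                           sigma=sigma)
        fit = ens.ga_select(pool, target, ensemble_size=8, population=60,
                            generations=60, seed=1)

        def chi2_of(indices):
            model = pool.intensities[np.asarray(indices)].mean(axis=0)
            return ens._chi2(model, target.intensity, sigma)[0]

        best_single = min(chi2_of([i]) for i in range(len(pool)))
        random_mean = np.mean([
            chi2_of(rng.integers(0, len(pool), 8)) for _ in range(50)])
        assert fit.chi2 <= best_single + 1e-12
        assert best_single <= random_mean

    def test_sigma_surrogate_warns(self, pool_with_intensities):
        pool, s = pool_with_intensities
        target = SAXSCurve(s=s, intensity=pool.intensities[0])
        with pytest.warns(UserWarning):
            ens.ga_select(pool, target, ensemble_size=1, population=10,
                          generations=2, seed=0)

    def test_determinism(self, pool_with_intensities):
        pool, s = pool_with_intensities
        target_i = pool.intensities[:5].mean(axis=0)
        target = SAXSCurve(s=s, intensity=target_i, sigma=0.01 * target_i)
        kw = dict(ensemble_size=4, population=30, generations=20, seed=11)
        a = ens.ga_select(pool, target, **kw)
        b = ens.ga_select(pool, target, **kw)
        assert a.indices == b.indices
        assert a.chi2 == b.chi2

    def test_compact_target_shifts_selection_compact(self, pool_with_intensities):
        # fitting a compact target must select conformers with lower mean
        # Rg than the pool average (directional sanity)
        pool, s = pool_with_intensities
        order = np.argsort(pool.rgs)
        compact = order[:10]
        target_i = pool.intensities[compact].mean(axis=0)
        target = SAXSCurve(s=s, intensity=target_i, sigma=0.01 * target_i)
        fit = ens.ga_select(pool, target, ensemble_size=10, population=60,
                            generations=60, seed=3)
        assert fit.rgs.mean() < pool.rgs.mean()


class TestRgReport:
    def make_fit(self, pool, indices):
        indices = tuple(int(i) for i in indices)
        uniq, counts = np.unique(indices, return_counts=True)
        return ens.EnsembleFit(
            indices=indices,
            weights={int(i): c / len(indices) for i, c in zip(uniq, counts)},
            intensity=np.zeros(3), chi2=0.0, scale=1.0, chi2_history=(0.0,),
            rgs=pool.rgs[list(indices)], settings={})

    def test_whole_pool_selection_has_zero_shift(self, small_pool):
        fit = self.make_fit(small_pool, range(len(small_pool)))
        rep = ens.rg_report(small_pool, fit)
        assert rep["shift"] == 0.0
        np.testing.assert_allclose(rep["density_pool"],
                                   rep["density_selection"])

    def test_planted_bimodal_selection_two_modes(self, small_pool):
        order = np.argsort(small_pool.rgs)
        sel = np.concatenate([order[:10], order[-10:]])
        rep = ens.rg_report(small_pool, self.make_fit(small_pool, sel))
        assert rep["n_modes_selection"] == 2

    def test_single_conformer_full_contribution(self, small_pool):
        rep = ens.rg_report(small_pool, self.make_fit(small_pool, [5]))
        assert rep["contribution_percent"] == {5: 100.0}
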
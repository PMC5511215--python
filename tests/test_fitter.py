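"""Chi-square statistic and the (R_D, Ar, K_D) grid inversion."""

import numpy as np
import pytest

import mcfret as m


def _decay(counts, window=50.0):
    t = (np.arange(len(counts)) + 0.5) * (window / len(counts))
    return m.DecayHistogram(t, np.asarray(counts, dtype=float))


class TestChiSquared:
    def test_perfect_model_gives_zero(self):
        d = _decay(np.exp(-np.linspace(0, 5, 200)) * 1e4)
        chi2, s = m.chi_squared(d, d)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0)

    def test_poisson_data_gives_unit_reduced_chi2(self, rng):
        model = _decay(np.exp(-np.linspace(0, 5, 1024)) * 2e4)
        data = m.DecayHistogram(model.time, rng.poisson(model.counts).astype(float))
        chi2, _ = m.chi_squared(model, data)
        assert abs(chi2 - 1.0) < 4 / np.sqrt(2 * 1024)

    def test_intensity_scale_is_absorbed(self, rng):
        model = _decay(np.exp(-np.linspace(0, 5, 256)) * 1e4)
        data = m.DecayHistogram(model.time, rng.poisson(model.counts).astype(float))
        c1, s1 = m.chi_squared(model, data)
        doubled = m.DecayHistogram(model.time, model.counts * 2)
        c2, s2 = m.chi_squared(doubled, data)
        assert c2 == pytest.approx(c1, rel=1e-10)
        assert s2 == pytest.approx(s1 / 2, rel=1e-10)

    def test_rejects_empty_or_mismatched(self):
        d = _decay(np.ones(10))
        with pytest.raises(ValueError):
            m.chi_squared(d, _decay(np.zeros(10)))
        with pytest.raises(ValueError):
            m.chi_squared(_decay(np.ones(20)), d)


SMALL_GRID = {
    "domain_radius": np.array([6.0, 8.0, 10.0]),
    "area_fraction": np.array([0.0, 0.35, 0.45, 0.55]),
    "k_d": np.array([1.0, 10.0, 20.0]),
}


def _synthetic_data(photo, rd, ar, kd, seed, bins=256):
    scene = m.SceneSpec(domain_radius=rd if ar else 8.0, area_fraction=ar,
                        partition=m.PartitionCoefficients(kd, kd))
    surv = m.simulate_ensemble_survival(scene, photo, n_scenes=48, n_donors=128,
                                        window=50, bins=bins, seed=seed)
    return m.compose_decay(surv, photo, total_counts=1e6, poisson=True, seed=seed + 1)


class TestGridFit:
    def test_recovers_truth_on_small_grid(self, photo):
        data = _synthetic_data(photo, 8.0, 0.45, 20.0, seed=50)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=800,
                         n_donors=64, seed=51, refine=False)
        best = res.best
        assert best["domain_radius"] == 8.0
        assert best["area_fraction"] == 0.45
        assert best["k_d"] == 20.0

    def test_refinement_tightens_the_estimate(self, photo):
        data = _synthetic_data(photo, 9.0, 0.45, 20.0, seed=60)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=800,
                         n_donors=64, seed=61)
        assert res.refined is not None
        assert abs(res.best["domain_radius"] - 9.0) <= 1.0

    def test_homogeneous_data_flagged_degenerate(self, photo):
        data = _synthetic_data(photo, 8.0, 0.0, 1.0, seed=70)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=400,
                         n_donors=48, seed=71)
        assert res.degenerate
        assert any("homogeneous" in w for w in res.warnings)
        assert res.refined is None
        # the whole K=1 plane and Ar=0 plane are exactly tied
        assert np.ptp(res.chi2[:, :, 0]) == 0.0

    def test_deterministic_given_seed(self, photo):
        data = _synthetic_data(photo, 8.0, 0.45, 10.0, seed=80)
        kw = dict(grids=SMALL_GRID, n_events=400, n_donors=48, seed=81, refine=False)
        a = m.grid_fit(data, photo, **kw)
        b = m.grid_fit(data, photo, **kw)
        np.testing.assert_array_equal(a.chi2, b.chi2)
        assert a.minima == b.minima

    def test_minima_ranked_ascending(self, photo):
        data = _synthetic_data(photo, 8.0, 0.35, 10.0, seed=90)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=400,
                         n_donors=48, seed=91, refine=False, delta_chi2=0.5)
        assert len(res.minima) >= 1
        chis = [mm["chi2_red"] for mm in res.minima]
        assert chis == sorted(chis)

    def test_grid_bounds_enforced(self, photo):
        data = _synthetic_data(photo, 8.0, 0.0, 1.0, seed=95)
        with pytest.raises(ValueError):
            m.grid_fit(data, photo, grids={"domain_radius": np.array([1.0, 8.0])})
        with pytest.raises(ValueError):
            m.grid_fit(data, photo, grids={"area_fraction": np.array([0.0, 0.7])})


class TestProfileUncertainty:
    def test_zero_threshold_collapses_to_point(self, photo):
        data = _synthetic_data(photo, 8.0, 0.45, 20.0, seed=100)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=400,
                         n_donors=48, seed=101, refine=False)
        iv = m.profile_uncertainty(res, delta_chi2=0.0)
        for name in ("domain_radius", "area_fraction", "k_d"):
            assert iv[name]["low"] == iv[name]["high"] == res.best[name]

    def test_flat_surface_flags_unbounded(self, photo):
        data = _synthetic_data(photo, 8.0, 0.0, 1.0, seed=110)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=400,
                         n_donors=48, seed=111)
        iv = m.profile_uncertainty(res, delta_chi2=0.05)
        assert all(iv[name]["unbounded"] for name in iv)

    def test_intervals_contain_point_estimate(self, photo):
        data = _synthetic_data(photo, 8.0, 0.45, 20.0, seed=120)
        res = m.grid_fit(data, photo, grids=SMALL_GRID, n_events=800,
                         n_donors=64, seed=121)
        for name in ("domain_radius", "area_fraction", "k_d"):
            assert res.intervals[name]["low"] <= res.best[name] <= res.intervals[name]["high"]
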
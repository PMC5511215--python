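"""Förster transfer rates, survival sampling, decay composition, efficiencies."""

import numpy as np
import pytest

import mcfret as m
from mcfret.fretmc import _all_donor_rates


def _photo(r0=5.0, tau=1.0, ca=0.0):
    return m.Photophysics(forster_radius=r0, intrinsic_decay=((1.0, tau),),
                          acceptor_density=ca)


def _field_with_acceptors(acceptor_xy, box=1000.0, leaflets=None, h=4.0):
    """One donor at the origin plus explicitly placed acceptors."""
    acceptor_xy = np.atleast_2d(np.asarray(acceptor_xy, dtype=float))
    n = len(acceptor_xy)
    leaflets = np.zeros(n, dtype=int) if leaflets is None else np.asarray(leaflets)
    return m.ProbeField(
        donor_xy=np.zeros((1, 2)),
        donor_leaflet=np.zeros(1, dtype=int),
        donor_inside=np.zeros(1, dtype=bool),
        acceptor_xy=acceptor_xy,
        acceptor_leaflet=leaflets,
        acceptor_inside=np.zeros(n, dtype=bool),
        leaflet_separation=h,
        box_side=box,
    )


class TestPairwiseRate:
    def test_rate_is_unity_at_forster_radius(self):
        assert m.pairwise_rate(5.0, _photo()) == pytest.approx(1.0)

    def test_sixth_power_distance_law(self):
        assert m.pairwise_rate(10.0, _photo()) == pytest.approx(1 / 64)

    def test_general_value(self):
        photo = m.Photophysics(5.0, ((1.0, 3.0),))
        assert m.pairwise_rate(4.0, photo) == pytest.approx(1.27157, abs=1e-5)

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            m.pairwise_rate(0.0, _photo())


class TestDonorTotalRate:
    def test_no_acceptors_means_no_transfer(self):
        field = _field_with_acceptors(np.empty((0, 2)))
        assert m.donor_total_rate(0, field, _photo()) == 0.0

    def test_single_acceptor_at_r0(self):
        field = _field_with_acceptors([[5.0, 0.0]])
        assert m.donor_total_rate(0, field, _photo()) == pytest.approx(1.0)

    def test_rates_add_over_acceptors(self):
        field = _field_with_acceptors([[5.0, 0.0], [0.0, 10.0]])
        assert m.donor_total_rate(0, field, _photo()) == pytest.approx(1.015625)

    def test_cross_leaflet_distance(self):
        # acceptor straight across the bilayer: r = h
        field = _field_with_acceptors([[0.0, 0.0]], leaflets=[1], h=5.0)
        assert m.donor_total_rate(0, field, _photo()) == pytest.approx(1.0)

    def test_minimum_image_convention(self):
        # acceptor across the periodic boundary is effectively 5 nm away
        field = _field_with_acceptors([[95.0, 0.0]], box=100.0)
        assert m.donor_total_rate(0, field, _photo()) == pytest.approx(1.0)

    def test_contact_clamp_bounds_rate(self):
        field = _field_with_acceptors([[1e-9, 0.0]])
        clamped = m.pairwise_rate(0.5, _photo())
        assert m.donor_total_rate(0, field, _photo()) == pytest.approx(clamped)


class TestSampleTransferTime:
    def test_inverse_transform_value(self):
        assert m.sample_transfer_time(2.0, np.exp(-1.0)) == pytest.approx(0.5)

    def test_gamma_near_one_is_instant(self):
        assert m.sample_transfer_time(2.0, 1.0) == 0.0

    def test_zero_rate_censors_event(self):
        assert m.sample_transfer_time(0.0, 0.5) == np.inf

    def test_mean_is_inverse_rate(self, rng):
        gamma = 1.0 - rng.random(100_000)
        dt = m.sample_transfer_time(np.full(100_000, 0.4), gamma)
        assert abs(dt.mean() - 2.5) < 3 * 2.5 / np.sqrt(100_000)

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            m.sample_transfer_time(1.0, 0.0)


class TestSimulateSurvival:
    def test_fixed_rate_matches_exponential(self, rng):
        # single donor-acceptor pair at r = R0: Omega = 1, G(t) = exp(-t)
        gamma = 1.0 - rng.random(50_000)
        dt = np.sort(m.sample_transfer_time(np.ones(50_000), gamma))
        t = np.linspace(0.05, 5, 40)
        g_emp = 1.0 - np.searchsorted(dt, t) / 50_000
        g_true = np.exp(-t)
        bound = 4 * np.sqrt(g_true * (1 - g_true) / 50_000)
        assert np.all(np.abs(g_emp - g_true) < bound)

    def test_histogram_matches_conditional_expectation(self, photo):
        """Event-sampled G equals <exp(-Omega t)> over the same configurations."""
        scene = m.SceneSpec(domain_radius=8.0, area_fraction=0.4,
                            partition=m.PartitionCoefficients(10.0, 10.0))
        surv = m.simulate_survival(scene, photo, n_events=60_000, window=50,
                                   bins=512, seed=21, return_event_rates=True)
        omega = surv.meta["event_rates"]
        oracle = np.exp(-np.outer(np.where(np.isfinite(omega), omega, 0.0), surv.time)).mean(0)
        bound = 4 * np.sqrt(np.maximum(oracle * (1 - oracle), 1e-12) / 60_000)
        assert np.all(np.abs(surv.values - oracle) <= bound + 1e-9)

    def test_survival_invariants(self, photo):
        scene = m.SceneSpec(area_fraction=0.0)
        for method in ("events", "expectation"):
            surv = m.simulate_survival(scene, photo, n_events=10_000, window=50,
                                       bins=256, seed=2, method=method)
            assert np.all(np.diff(surv.values) <= 1e-12)
            assert surv.values[0] <= 1.0 and surv.values[-1] >= 0.0

    def test_domain_blind_when_no_preference(self, photo):
        """K_D = 1 decays are statistically independent of (R_D, Ar)."""
        from mcfret._model import homogeneous_survival

        scene = m.SceneSpec(domain_radius=8.0, area_fraction=0.4,
                            partition=m.PartitionCoefficients(1.0, 1.0))
        surv = m.simulate_survival(scene, photo, n_events=60_000, window=50,
                                   bins=256, seed=31)
        g_ref = homogeneous_survival(surv.time, photo.forster_radius,
                                     photo.mean_lifetime, photo.contact_radius,
                                     photo.acceptor_density, 4.0)
        # 5 sigma: configuration reuse mildly clusters the event noise
        bound = 5 * np.sqrt(np.maximum(g_ref * (1 - g_ref), 1e-12) / 60_000)
        assert np.all(np.abs(surv.values - g_ref) < bound + 5e-3)

    def test_probe_redistribution_changes_decay_in_expected_direction(self, photo):
        """Donor/acceptor segregation slows the decay; co-enrichment speeds it."""
        kw = dict(n_events=40_000, window=50, bins=256)
        homog = m.simulate_survival(m.SceneSpec(area_fraction=0.0), photo, seed=41, **kw)
        apart = m.simulate_survival(
            m.SceneSpec(domain_radius=8.0, area_fraction=0.45,
                        partition=m.PartitionCoefficients(10.0, 0.1)),
            photo, seed=42, **kw)
        together = m.simulate_survival(
            m.SceneSpec(domain_radius=8.0, area_fraction=0.45,
                        partition=m.PartitionCoefficients(20.0, 20.0)),
            photo, seed=43, **kw)
        assert apart.values.sum() > homog.values.sum() > together.values.sum()

    def test_rejects_bad_inputs(self, photo):
        with pytest.raises(ValueError):
            m.simulate_survival(m.SceneSpec(), photo, n_events=10, reuse=100)
        with pytest.raises(ValueError):
            m.simulate_survival(m.SceneSpec(n_donors=0), photo)
        with pytest.raises(ValueError):
            m.simulate_survival(m.SceneSpec(), photo, window=1.0)


class TestComposeDecay:
    def test_pure_intrinsic_shape(self):
        photo = m.Photophysics(5.0, ((1.0, 3.0),))
        t = np.linspace(0.05, 30, 300)
        surv = m.SurvivalCurve(t, np.ones_like(t))
        decay = m.compose_decay(surv, photo, total_counts=1e6)
        expected = np.exp(-t / 3)
        np.testing.assert_allclose(decay.counts / decay.counts[0],
                                   expected / expected[0], rtol=1e-10)

    def test_noiseless_is_deterministic(self, photo):
        t = np.linspace(0.05, 30, 100)
        surv = m.SurvivalCurve(t, np.exp(-t / 5))
        a = m.compose_decay(surv, photo, total_counts=1e5)
        b = m.compose_decay(surv, photo, total_counts=1e5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_poisson_counts_track_expectation(self, photo):
        t = np.linspace(0.05, 30, 200)
        surv = m.SurvivalCurve(t, np.exp(-t / 5))
        clean = m.compose_decay(surv, photo, total_counts=1e6)
        noisy = m.compose_decay(surv, photo, total_counts=1e6, poisson=True, seed=9)
        sigma = np.sqrt(np.maximum(clean.counts, 1.0))
        assert np.all(np.abs(noisy.counts - clean.counts) < 5 * sigma + 1)

    def test_irf_grid_mismatch_rejected(self, photo):
        t = np.linspace(0.05, 30, 100)
        surv = m.SurvivalCurve(t, np.exp(-t / 5))
        irf = m.DecayHistogram(np.linspace(0.05, 30, 50), np.ones(50))
        with pytest.raises(ValueError):
            m.compose_decay(surv, photo, irf=irf)


class TestFretEfficiency:
    def test_identical_decays_give_zero(self):
        t = np.linspace(0.05, 50, 500)
        d = m.DecayHistogram(t, np.exp(-t / 3) * 1e5)
        assert m.fret_efficiency(d, d) == pytest.approx(0.0, abs=1e-12)
        assert m.relative_efficiency(0.5, 0.5) == pytest.approx(1.0)

    def test_uniform_extra_rate_halves_lifetime(self):
        # tau = 3 quenched by extra rate 1/3: E = 1 - 1.5/3 = 0.5
        t = np.linspace(0.01, 200, 20000)
        donor = m.DecayHistogram(t, np.exp(-t / 3))
        quenched = m.DecayHistogram(t, np.exp(-2 * t / 3))
        assert m.fret_efficiency(quenched, donor) == pytest.approx(0.5, abs=1e-3)

    def test_scale_invariance(self):
        t = np.linspace(0.05, 50, 500)
        donor = m.DecayHistogram(t, np.exp(-t / 3) * 1e6)
        quenched = m.DecayHistogram(t, np.exp(-t / 2) * 3e4)
        e1 = m.fret_efficiency(quenched, donor)
        quenched2 = m.DecayHistogram(t, quenched.counts * 7.3)
        assert m.fret_efficiency(quenched2, donor) == pytest.approx(e1, rel=1e-12)

    def test_rejects_empty_donor(self):
        t = np.linspace(0.05, 50, 10)
        with pytest.raises(ValueError):
            m.fret_efficiency(m.DecayHistogram(t, np.ones(10)),
                              m.DecayHistogram(t, np.zeros(10)))
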
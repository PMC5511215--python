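"""Scene construction: domain packing and partition-driven probe placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mcfret as m
from mcfret.membrane import PackingError


class TestPlaceDomains:
    def test_domain_count_and_achieved_fraction(self):
        layout = m.place_domains(200.0, 8.0, 0.37, seed=5)
        assert layout.n_domains == 74  # round(0.37 * 200^2 / (pi * 64))
        assert layout.achieved_area_fraction == pytest.approx(0.3720, abs=5e-4)

    def test_zero_area_fraction_gives_empty_layout(self):
        layout = m.place_domains(200.0, 8.0, 0.0, seed=5)
        assert layout.n_domains == 0
        assert layout.achieved_area_fraction == 0.0

    @pytest.mark.parametrize("area_fraction", [0.1, 0.37, 0.45, 0.55, 0.6])
    def test_hard_disk_non_overlap(self, area_fraction):
        layout = m.place_domains(100.0, 8.0, area_fraction, seed=7)
        assert layout.min_center_distance() >= 2 * layout.domain_radius - 1e-9
        # achieved within one domain's area of the target (rounding)
        one = np.pi * 64 / 100.0**2
        assert abs(layout.achieved_area_fraction - area_fraction) <= one

    def test_same_seed_bit_identical(self):
        a = m.place_domains(100.0, 8.0, 0.4, seed=42)
        b = m.place_domains(100.0, 8.0, 0.4, seed=42)
        np.testing.assert_array_equal(a.centers, b.centers)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(box_side=100.0, domain_radius=1.0, area_fraction=0.3),
            dict(box_side=100.0, domain_radius=60.0, area_fraction=0.3),
            dict(box_side=100.0, domain_radius=8.0, area_fraction=0.7),
            dict(box_side=50.0, domain_radius=8.0, area_fraction=0.3),
        ],
    )
    def test_preconditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            m.place_domains(seed=0, **kwargs)

    def test_json_round_trip(self):
        layout = m.place_domains(100.0, 8.0, 0.3, seed=3)
        again = m.DomainLayout.from_json(layout.to_json())
        np.testing.assert_allclose(again.centers, layout.centers)
        assert again.domain_radius == layout.domain_radius


class TestPartitionProbability:
    @pytest.mark.parametrize(
        "k_d, ar, expected",
        [(1.0, 0.37, 0.37), (10.0, 0.37, 0.854503), (20.0, 0.45, 0.942408)],
    )
    def test_values(self, k_d, ar, expected):
        assert m.partition_probability(k_d, ar) == pytest.approx(expected, abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(
        ar=st.floats(0.01, 0.9),
        k1=st.floats(0.0, 100.0),
        k2=st.floats(0.0, 100.0),
    )
    def test_monotone_in_k(self, ar, k1, k2):
        lo, hi = sorted([k1, k2])
        assert m.partition_probability(lo, ar) <= m.partition_probability(hi, ar) + 1e-12

    def test_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            m.partition_probability(-1.0, 0.3)
        with pytest.raises(ValueError):
            m.partition_probability(1.0, 1.0)


class TestPlaceProbes:
    def test_no_preference_matches_area_fraction(self, nanodomain_layout):
        field = m.place_probes(
            nanodomain_layout, 100_000, 10, m.PartitionCoefficients(1.0, 1.0), seed=1
        )
        p = nanodomain_layout.achieved_area_fraction
        bound = 4 * np.sqrt(p * (1 - p) / 100_000)
        assert abs(field.donor_inside.mean() - p) < bound

    def test_strong_partitioning_puts_all_inside(self, nanodomain_layout):
        field = m.place_probes(
            nanodomain_layout, 2000, 10, m.PartitionCoefficients(1e6, 1e6), seed=2
        )
        assert field.donor_inside.all()

    def test_inside_fraction_follows_partition_law(self):
        layout = m.place_domains(200.0, 8.0, 0.45, seed=9)
        field = m.place_probes(layout, 10_000, 10, m.PartitionCoefficients(20.0, 20.0), seed=3)
        p = m.partition_probability(20.0, layout.achieved_area_fraction)
        bound = 4 * np.sqrt(p * (1 - p) / 10_000)
        assert abs(field.donor_inside.mean() - p) < bound

    def test_flags_consistent_with_geometry(self, nanodomain_layout):
        field = m.place_probes(
            nanodomain_layout, 5000, 5000, m.PartitionCoefficients(5.0, 5.0), seed=4
        )
        np.testing.assert_array_equal(
            nanodomain_layout.contains(field.donor_xy), field.donor_inside
        )
        np.testing.assert_array_equal(
            nanodomain_layout.contains(field.acceptor_xy), field.acceptor_inside
        )

    def test_leaflets_split_evenly(self, nanodomain_layout):
        field = m.place_probes(
            nanodomain_layout, 20_000, 10, m.PartitionCoefficients(1.0, 1.0), seed=5
        )
        assert abs(field.donor_leaflet.mean() - 0.5) < 4 * np.sqrt(0.25 / 20_000)

    def test_reproducible_given_seed(self, nanodomain_layout):
        a = m.place_probes(nanodomain_layout, 100, 100, m.PartitionCoefficients(2, 2), seed=6)
        b = m.place_probes(nanodomain_layout, 100, 100, m.PartitionCoefficients(2, 2), seed=6)
        np.testing.assert_array_equal(a.donor_xy, b.donor_xy)
        np.testing.assert_array_equal(a.acceptor_xy, b.acceptor_xy)

    def test_rejects_empty_counts(self, nanodomain_layout):
        with pytest.raises(ValueError):
            m.place_probes(nanodomain_layout, 0, 10, m.PartitionCoefficients(), seed=0)
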
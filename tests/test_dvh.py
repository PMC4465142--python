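"""DVH containers, conversions and dose/volume metrics."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gatedose import (CumulativeDVH, DifferentialDVH, StructurePlan,
                      cumulative_to_differential, differential_to_cumulative,
                      dose_at_volume, mean_dose, read_dvh_csv, volume_at_dose,
                      volume_at_relative_dose, write_dvh_csv)

from conftest import random_differential_dvh


def delta_dvh(dose, bin_width=0.05):
    return DifferentialDVH(bin_center=np.array([dose]),
                           volume_fraction=np.array([1.0]),
                           bin_width=bin_width)


class TestInvariants:
    def test_rejects_negative_fraction(self):
        with pytest.raises(ValueError, match="non-negative"):
            DifferentialDVH(bin_center=np.array([1.0, 1.05]),
                            volume_fraction=np.array([1.5, -0.5]))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="not normalized"):
            DifferentialDVH(bin_center=np.array([1.0]),
                            volume_fraction=np.array([0.9]))

    def test_rejects_irregular_grid(self):
        with pytest.raises(ValueError, match="constant spacing"):
            DifferentialDVH(bin_center=np.array([1.0, 1.2]),
                            volume_fraction=np.array([0.5, 0.5]),
                            bin_width=0.05)

    def test_rejects_negative_dose(self):
        with pytest.raises(ValueError, match="non-negative"):
            delta_dvh(-1.0)

    def test_cumulative_rejects_increasing_values(self):
        with pytest.raises(ValueError, match="monotone"):
            CumulativeDVH(dose=np.array([0.0, 1.0, 2.0]),
                          volume_fraction_at_or_above=np.array([1.0, 0.2, 0.6]))

    def test_structure_plan_rejects_bad_prescription(self):
        with pytest.raises(ValueError, match="prescription"):
            StructurePlan(organ="heart", technique="FB",
                          plan_type="tangential", dvh=delta_dvh(10.0),
                          prescription_dose=0.0)


class TestConversions:
    def test_delta_mass_becomes_step(self):
        c = differential_to_cumulative(delta_dvh(10.0))
        assert volume_at_dose(c, 5.0) == pytest.approx(1.0)
        assert volume_at_dose(c, 9.9) == pytest.approx(1.0)
        assert volume_at_dose(c, 10.5) == pytest.approx(0.0)

    def test_two_spikes_make_half_step(self):
        centers = 0.025 + 0.05 * np.arange(401)
        fracs = np.zeros(401)
        fracs[0] = 0.5
        fracs[400] = 0.5
        d = DifferentialDVH(bin_center=centers, volume_fraction=fracs)
        c = differential_to_cumulative(d)
        for mid in (0.5, 5.0, 19.9):
            assert volume_at_dose(c, mid) == pytest.approx(0.5)
        assert volume_at_dose(c, 25.0) == pytest.approx(0.0)

    def test_round_trip_identity(self, rng):
        for _ in range(10):
            d = random_differential_dvh(rng)
            back = cumulative_to_differential(
                differential_to_cumulative(d), d.bin_width)
            # shared grid -> per-bin recovery
            i = np.searchsorted(back.bin_center, d.bin_center[0] - 1e-9)
            np.testing.assert_allclose(
                back.volume_fraction[i:i + d.bin_center.size],
                d.volume_fraction, atol=1e-9)

    def test_step_cumulative_differences_to_single_mass(self):
        c = CumulativeDVH(dose=np.array([0.0, 24.999, 25.0, 50.0]),
                          volume_fraction_at_or_above=np.array(
                              [1.0, 1.0, 0.0, 0.0]))
        d = cumulative_to_differential(c, bin_width=0.05)
        hot = d.bin_center[d.volume_fraction > 0.99]
        assert hot.size == 1
        assert abs(hot[0] - 25.0) <= 0.05

    def test_linear_cumulative_gives_equal_masses(self, linear_cumulative):
        d = cumulative_to_differential(linear_cumulative, bin_width=0.05)
        assert d.volume_fraction.size == 1000
        np.testing.assert_allclose(d.volume_fraction, 1e-3, atol=1e-12)

    def test_rejects_unnormalized_conversion(self):
        d = DifferentialDVH(bin_center=np.array([1.0]),
                            volume_fraction=np.array([1.0]))
        object.__setattr__(d, "volume_fraction", np.array([0.99]))
        with pytest.raises(ValueError, match="not normalized"):
            differential_to_cumulative(d)


class TestMetrics:
    def test_mean_dose_point_masses(self):
        assert mean_dose(delta_dvh(10.0)) == pytest.approx(10.0)
        centers = 0.05 + 0.05 * np.arange(601)
        fracs = np.zeros(601)
        fracs[np.argmin(np.abs(centers - 10.0))] = 0.5
        fracs[np.argmin(np.abs(centers - 30.0))] = 0.5
        d = DifferentialDVH(bin_center=centers, volume_fraction=fracs)
        assert mean_dose(d) == pytest.approx(20.0, abs=1e-9)

    def test_mean_dose_matches_weighted_sum_oracle(self, rng):
        d = random_differential_dvh(rng)
        oracle = sum(float(c) * float(v)
                     for c, v in zip(d.bin_center, d.volume_fraction))
        assert mean_dose(d) == pytest.approx(oracle, abs=1e-12)

    def test_volume_at_dose_interpolates(self, linear_cumulative):
        assert volume_at_dose(linear_cumulative, 25.0) == pytest.approx(0.5)
        assert volume_at_dose(linear_cumulative, 0.0) == pytest.approx(1.0)
        assert volume_at_dose(linear_cumulative, 60.0) == pytest.approx(0.0)

    def test_relative_dose_metrics(self, linear_cumulative):
        # V_93% of 50 Gy on the linear ramp = V(46.5) = 0.07
        assert volume_at_relative_dose(linear_cumulative, 93.0, 50.0) == \
            pytest.approx(0.07)
        # target entirely above 95% of prescription -> full coverage
        hot = differential_to_cumulative(delta_dvh(49.0))
        assert volume_at_relative_dose(hot, 95.0, 50.0) == pytest.approx(1.0)
        # nothing above 105%
        assert volume_at_relative_dose(hot, 105.0, 50.0) == pytest.approx(0.0)

    def test_dose_at_volume_interpolates(self):
        c = CumulativeDVH(dose=np.array([0.0, 40.0, 50.0]),
                          volume_fraction_at_or_above=np.array(
                              [1.0, 0.10, 0.0]))
        assert dose_at_volume(c, 0.02) == pytest.approx(48.0)
        assert dose_at_volume(c, 1.0) == pytest.approx(0.0)

    def test_dose_at_volume_uniform_organ(self):
        c = differential_to_cumulative(delta_dvh(30.0))
        assert dose_at_volume(c, 0.02) == pytest.approx(30.0, abs=0.05)

    def test_dose_at_volume_nearest_mode(self):
        c = CumulativeDVH(dose=np.array([0.0, 40.0, 50.0]),
                          volume_fraction_at_or_above=np.array(
                              [1.0, 0.10, 0.0]))
        assert dose_at_volume(c, 0.02, method="nearest") in (40.0, 50.0)

    def test_excess_volume_fraction_warns(self, linear_cumulative):
        c = CumulativeDVH(dose=np.array([0.5, 40.0]),
                          volume_fraction_at_or_above=np.array([0.8, 0.1]))
        with pytest.warns(UserWarning, match="exceeds"):
            assert dose_at_volume(c, 0.9) == 0.0


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_random(self, seed):
        rng = np.random.default_rng(seed)
        d = random_differential_dvh(rng, n_bins=50)
        back = cumulative_to_differential(
            differential_to_cumulative(d), d.bin_width)
        i = np.searchsorted(back.bin_center, d.bin_center[0] - 1e-9)
        np.testing.assert_allclose(
            back.volume_fraction[i:i + 50], d.volume_fraction, atol=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(1.1, 3.0))
    def test_dose_scaling(self, seed, k):
        """Scaling doses by k > 1 scales D_mean by k and can only raise
        V at a fixed threshold."""
        rng = np.random.default_rng(seed)
        d = random_differential_dvh(rng, n_bins=50)
        scaled = DifferentialDVH(bin_center=d.bin_center * k,
                                 volume_fraction=d.volume_fraction,
                                 bin_width=d.bin_width * k)
        assert mean_dose(scaled) == pytest.approx(k * mean_dose(d),
                                                  rel=1e-12)
        c, cs = (differential_to_cumulative(x) for x in (d, scaled))
        for thr in (1.0, 5.0, 15.0):
            assert volume_at_dose(cs, thr) >= volume_at_dose(c, thr) - 1e-12

    def test_volume_at_dose_monotone_in_threshold(self, rng):
        c = differential_to_cumulative(random_differential_dvh(rng))
        thresholds = np.linspace(0.0, 40.0, 200)
        vols = [volume_at_dose(c, t) for t in thresholds]
        assert np.all(np.diff(vols) <= 1e-12)

    def test_dose_volume_inverse_on_strict_segment(self, linear_cumulative):
        for v in (0.9, 0.5, 0.1):
            d = dose_at_volume(linear_cumulative, v)
            assert volume_at_dose(linear_cumulative, d) == \
                pytest.approx(v, abs=1e-9)


class TestCsvDialect:
    def test_differential_round_trip(self, rng):
        d = random_differential_dvh(rng, n_bins=40)
        buf = io.StringIO()
        write_dvh_csv(buf, d, technique="FB", plan_type="tangential",
                      prescription_dose=50.0)
        buf.seek(0)
        back, meta = read_dvh_csv(buf)
        assert isinstance(back, DifferentialDVH)
        assert meta["technique"] == "FB"
        np.testing.assert_allclose(back.bin_center, d.bin_center, atol=1e-6)
        np.testing.assert_allclose(back.volume_fraction, d.volume_fraction,
                                   atol=1e-5)

    def test_writer_is_byte_stable(self, rng, tmp_path):
        d = random_differential_dvh(rng, n_bins=40)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dvh_csv(p1, d)
        back, _ = read_dvh_csv(p1)
        write_dvh_csv(p2, back)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cumulative_kind_detected(self, linear_cumulative, tmp_path):
        p = tmp_path / "c.csv"
        write_dvh_csv(p, linear_cumulative)
        back, meta = read_dvh_csv(p)
        assert isinstance(back, CumulativeDVH)
        assert meta["kind"] == "cumulative"

    def test_unnormalized_file_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# kind=differential\ndose_Gy,volume_fraction\n"
                     "1.000000,0.500000\n")
        with pytest.raises(ValueError, match="not normalized"):
            read_dvh_csv(p)
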
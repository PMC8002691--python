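"""Rate regression, source partitioning, interface finding, depth integration."""

import numpy as np
import pytest

from tracern2o.errors import DomainError, EstimationError
from tracern2o.isotope import (
    IsotopeMeasurement,
    TracerSpec,
    amount_to_delta,
)
from tracern2o.rates import (
    IncubationSeries,
    PartitionedProfile,
    RateEstimate,
    Treatment,
    censor_below_detection,
    find_interface,
    fit_rate,
    integrate_contribution,
    partition_depth,
)

V = 0.118


def make_tracer(f15=0.5, substrate="nitrate"):
    return TracerSpec(
        substrate=substrate,
        added_nmol=500.0,
        purity_fraction=0.99,
        ambient_umolL=0.0,
        liquid_volume_L=V,
        f15=f15,
    )


def series_from_n15(n15_by_time, constants, f15=0.5, n2o=100.0,
                    treatment=Treatment.NO3):
    """Build a series whose labelled amounts are exactly the given values."""
    measurements = tuple(
        IsotopeMeasurement(
            time_h=t,
            n2o_nmolN=n2o,
            delta15n_permil=amount_to_delta(n15, n2o, constants),
        )
        for t, n15 in n15_by_time
    )
    return IncubationSeries(
        station="S", depth_m=100.0, treatment=treatment,
        tracer=make_tracer(f15), measurements=measurements,
    )


class TestFitRate:
    def test_noise_free_three_point_closed_form(self, constants):
        # 15N(t) = 1 + 0.05 t -> slope 0.05 nmol/h -> 0.05*24/(0.5*0.118)
        series = series_from_n15(
            [(0.0, 1.0), (12.0, 1.6), (24.0, 2.2)], constants
        )
        est = fit_rate(series, constants)
        assert est.slope_nmol15N_per_h == pytest.approx(0.05, rel=1e-10)
        assert est.rate_nmolN_L_d == pytest.approx(
            0.05 * 24 / (0.5 * V), rel=1e-10
        )
        assert est.rate_nmolN_L_d == pytest.approx(20.339, abs=1e-3)
        assert est.slope_se is not None and est.p_one_sided is not None

    def test_constant_series_gives_zero_rate(self, constants):
        series = series_from_n15([(0.0, 2.0), (12.0, 2.0), (24.0, 2.0)], constants)
        est = fit_rate(series, constants)
        assert est.rate_nmolN_L_d == pytest.approx(0.0, abs=1e-9)

    def test_two_point_difference_quotient(self, constants):
        series = series_from_n15([(0.0, 1.0), (24.0, 2.2)], constants)
        est = fit_rate(series, constants)
        assert est.slope_nmol15N_per_h == pytest.approx(1.2 / 24, rel=1e-10)
        assert est.slope_se is None
        assert est.p_one_sided is None
        assert est.n_points == 2

    def test_ols_matches_normal_equations_oracle(self, constants):
        """OLS slope equals the brute-force normal-equations solution."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 6)
            t = np.sort(rng.uniform(0, 24, n))
            while len(np.unique(t)) < 2:
                t = np.sort(rng.uniform(0, 24, n))
            n15 = rng.uniform(0.1, 5.0, n)
            series = series_from_n15(list(zip(t, n15)), constants)
            est = fit_rate(series, constants)
            # independent oracle: solve X'X b = X'y explicitly
            X = np.column_stack([np.ones_like(t), t])
            beta = np.linalg.solve(X.T @ X, X.T @ n15)
            assert est.slope_nmol15N_per_h == pytest.approx(
                beta[1], rel=1e-12, abs=1e-12
            )

    def test_scale_equivariance(self, constants):
        pts = [(0.0, 1.0), (12.0, 1.7), (24.0, 2.1)]
        base = fit_rate(series_from_n15(pts, constants), constants)
        tripled = fit_rate(
            series_from_n15([(t, 3 * y) for t, y in pts], constants), constants
        )
        halved_f15 = fit_rate(series_from_n15(pts, constants, f15=0.25), constants)
        assert tripled.rate_nmolN_L_d == pytest.approx(
            3 * base.rate_nmolN_L_d, rel=1e-9
        )
        assert halved_f15.rate_nmolN_L_d == pytest.approx(
            2 * base.rate_nmolN_L_d, rel=1e-9
        )

    def test_too_few_usable_points_raises(self, constants):
        series = series_from_n15([(0.0, 1.0), (24.0, 2.0)], constants)
        censored = censor_below_detection(series, detection_limit_nmolN=1e6)
        with pytest.raises(EstimationError):
            fit_rate(censored, constants)


class TestCensoring:
    def test_no_points_below_limit_unchanged(self, constants):
        series = series_from_n15([(0.0, 1.0), (24.0, 2.0)], constants, n2o=50.0)
        out = censor_below_detection(series, 1.0)
        assert out.censored_count == 0
        assert [m.n2o_nmolN for m in out.measurements] == [50.0, 50.0]

    def test_single_point_flagged(self, constants):
        measurements = (
            IsotopeMeasurement(0.0, 0.5, 10.0),
            IsotopeMeasurement(12.0, 5.0, 100.0),
            IsotopeMeasurement(24.0, 9.0, 200.0),
        )
        series = IncubationSeries(
            "S", 100.0, Treatment.NO3, make_tracer(), measurements
        )
        out = censor_below_detection(series, 1.0)
        assert out.censored_count == 1
        assert out.measurements[0].below_detection
        assert len(out.usable) == 2


class TestPartition:
    @staticmethod
    def est(treatment, rate, station="S", depth=100.0):
        return RateEstimate(
            station=station, depth_m=depth, treatment=treatment,
            rate_nmolN_L_d=rate, slope_nmol15N_per_h=rate, slope_se=None,
            n_points=3, p_one_sided=None, censored_points=0,
        )

    def test_basic_split(self):
        p = partition_depth(
            self.est(Treatment.NO3, 10.0), self.est(Treatment.NO3_CAP, 4.0),
            None, 100.0, 0.5,
        )
        assert (p.fungal_rate, p.bacterial_rate) == (4.0, 6.0)
        assert p.fungal_rate + p.bacterial_rate == p.total_no3_rate
        assert not p.clamped
        assert p.nitrification_missing

    def test_zero_cap_gives_zero_fungal_share(self):
        p = partition_depth(
            self.est(Treatment.NO3, 10.0), self.est(Treatment.NO3_CAP, 0.0),
            self.est(Treatment.NH4, 1.5), 100.0, 0.5,
        )
        assert p.fungal_rate == 0.0
        assert p.bacterial_rate == 10.0
        assert p.nitrification_rate == 1.5

    def test_clamp_when_cap_exceeds_total(self):
        p = partition_depth(
            self.est(Treatment.NO3, 10.0), self.est(Treatment.NO3_CAP, 12.0),
            None, 100.0, 0.5,
        )
        assert p.clamped
        assert p.fungal_rate == 12.0
        assert p.bacterial_rate == 0.0

    def test_negative_inputs_floored(self):
        p = partition_depth(
            self.est(Treatment.NO3, -0.3), self.est(Treatment.NO3_CAP, 0.1),
            None, 100.0, 0.5,
        )
        assert p.floored_inputs
        assert p.total_no3_rate == 0.0
        assert p.fungal_rate == 0.1

    def test_mismatch_rejected(self):
        with pytest.raises(DomainError):
            partition_depth(
                self.est(Treatment.NO3, 10.0),
                self.est(Treatment.NO3_CAP, 4.0, depth=200.0),
                None, 100.0, 0.5,
            )
        with pytest.raises(DomainError):
            partition_depth(
                self.est(Treatment.NO3, 10.0), self.est(Treatment.NO3, 4.0),
                None, 100.0, 0.5,
            )


class TestInterface:
    def test_interpolated_crossing(self):
        # hand computation: 90 + 30*(10-1)/(10-0.5)
        z = find_interface([60.0, 90.0, 120.0], [50.0, 10.0, 0.5], 1.0)
        assert z == pytest.approx(90 + 30 * 9 / 9.5, rel=1e-12)
        assert z == pytest.approx(118.42, abs=0.01)

    def test_already_below_at_first_depth(self):
        assert find_interface([60.0, 90.0], [0.5, 0.1], 1.0) == 60.0

    def test_never_crosses_raises(self):
        with pytest.raises(DomainError, match="never falls below"):
            find_interface([60.0, 90.0], [50.0, 20.0], 1.0)

    def test_non_monotone_depths_rejected(self):
        with pytest.raises(DomainError):
            find_interface([60.0, 50.0], [50.0, 0.5], 1.0)


def make_profiles(depths, fungal, total, station="S"):
    return [
        PartitionedProfile(
            station=station, depth_m=z, o2_uM=0.0,
            total_no3_rate=t, fungal_rate=f,
            bacterial_rate=t - f, nitrification_rate=0.0,
        )
        for z, f, t in zip(depths, fungal, total)
    ]


class TestIntegration:
    def test_constant_profile_rectangle(self):
        profiles = make_profiles([60.0, 140.0], [2.0, 2.0], [10.0, 10.0])
        c = integrate_contribution(profiles, 60.0, 140.0)
        assert c.integral_fungal == pytest.approx(160.0, rel=1e-12)
        assert c.integral_total_no3 == pytest.approx(800.0, rel=1e-12)
        assert c.fungal_fraction_percent == pytest.approx(20.0, rel=1e-12)

    def test_linear_profile_triangles(self):
        profiles = make_profiles([60.0, 140.0], [0.0, 2.5], [0.0, 10.0])
        c = integrate_contribution(profiles, 60.0, 140.0)
        assert c.fungal_fraction_percent == pytest.approx(25.0, rel=1e-12)

    def test_matches_fine_grid_oracle(self):
        """Trapezoid equals 1 cm brute-force numeric integration."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            depths = np.sort(rng.uniform(50, 300, 6))
            while np.any(np.diff(depths) < 1.0):
                depths = np.sort(rng.uniform(50, 300, 6))
            fungal = rng.uniform(0, 5, 6)
            total = fungal + rng.uniform(0, 10, 6)
            z_top = depths[0] + 0.3 * (depths[-1] - depths[0]) * rng.uniform()
            z_bot = depths[-1] - 0.3 * (depths[-1] - depths[0]) * rng.uniform()
            c = integrate_contribution(
                make_profiles(depths, fungal, total), z_top, z_bot
            )
            grid = np.union1d(
                np.linspace(z_top, z_bot, int((z_bot - z_top) * 100) + 1),
                depths[(depths > z_top) & (depths < z_bot)],
            )
            oracle_f = np.trapezoid(np.interp(grid, depths, fungal), grid)
            oracle_t = np.trapezoid(np.interp(grid, depths, total), grid)
            assert c.integral_fungal == pytest.approx(oracle_f, rel=1e-9)
            assert c.integral_total_no3 == pytest.approx(oracle_t, rel=1e-9)

    def test_conservation_of_partition_under_integration(self):
        rng = np.random.default_rng(11)
        depths = np.array([60.0, 90.0, 120.0, 150.0])
        fungal = rng.uniform(0, 3, 4)
        bacterial = rng.uniform(0, 5, 4)
        total = fungal + bacterial
        c = integrate_contribution(
            make_profiles(depths, fungal, total), 60.0, 150.0
        )
        grid_b = np.trapezoid(bacterial, depths)
        assert c.integral_fungal + grid_b == pytest.approx(
            c.integral_total_no3, rel=1e-12
        )

    def test_extrapolation_refused(self):
        profiles = make_profiles([60.0, 140.0], [2.0, 2.0], [10.0, 10.0])
        with pytest.raises(DomainError, match="extrapolation"):
            integrate_contribution(profiles, 50.0, 140.0)

    def test_zero_total_fraction_undefined(self):
        profiles = make_profiles([60.0, 140.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(EstimationError, match="undefined"):
            integrate_contribution(profiles, 60.0, 140.0)
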
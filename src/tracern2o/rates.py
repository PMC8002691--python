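"""Volumetric N₂O production rates from ¹⁵N₂O time series, and their
partitioning into fungal / bacterial / nitrification sources.

The production rate in a tracer incubation is

    R_N₂O = (d¹⁵N₂O/dt) / (f¹⁵ × V)

where d¹⁵N₂O/dt is the slope of labelled N₂O amount against time (ordinary
least squares; a simple difference quotient for the two-point endpoint
design), f¹⁵ the atom fraction of the labelled substrate pool and V the
incubation liquid volume. Rates are reported in nmol N L⁻¹ d⁻¹.

Source attribution follows the selective-inhibition design: incubations
with ¹⁵NO₃⁻ plus chloramphenicol (prokaryotic protein-synthesis inhibitor)
approximate the fungal contribution; the remainder of the plain ¹⁵NO₃⁻ rate
is attributed to bacterial denitrification; ¹⁵NH₄⁺ incubations trace
nitrification. Fungal and total NO₃⁻-derived rates are depth-integrated
from the top of the oxycline to the oxic–anoxic interface by the
trapezoidal rule to yield the fractional fungal contribution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError
from .isotope import IsotopeConstants, IsotopeMeasurement, TracerSpec, labeled_n_amount

HOURS_PER_DAY = 24.0


class Treatment(str, enum.Enum):
    """Incubation treatment labels as they appear in input tables."""

    NO3 = "NO3"  # 15N-nitrate, no inhibitor: total denitrification-derived N2O
    NO3_CAP = "NO3_CAP"  # 15N-nitrate + chloramphenicol: fungal upper limit
    NH4 = "NH4"  # 15N-ammonium: nitrification-derived N2O

    @property
    def substrate(self) -> str:
        return "ammonium" if self is Treatment.NH4 else "nitrate"


@dataclass(frozen=True)
class IncubationSeries:
    """A time series of measurements from one (station, depth, treatment)."""

    station: str
    depth_m: float
    treatment: Treatment
    tracer: TracerSpec
    measurements: tuple[IsotopeMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        object.__setattr__(self, "measurements", tuple(self.measurements))
        times = [m.time_h for m in self.measurements]
        if len(set(times)) < 2:
            raise DomainError(
                f"series {self.station}/{self.depth_m} m/{self.treatment.value}: "
                f"need >= 2 measurements at distinct times, got times {times}"
            )
        if self.treatment.substrate != self.tracer.substrate:
            raise DomainError(
                f"treatment {self.treatment.value} is inconsistent with tracer "
                f"substrate {self.tracer.substrate!r}"
            )

    @property
    def usable(self) -> tuple[IsotopeMeasurement, ...]:
        return tuple(m for m in self.measurements if not m.below_detection)

    @property
    def censored_count(self) -> int:
        return sum(m.below_detection for m in self.measurements)


@dataclass(frozen=True)
class RateEstimate:
    """A fitted volumetric N₂O production rate with its regression diagnostics.

    ``slope_se`` and ``p_one_sided`` are ``None`` for two-point series, where
    the slope is a difference quotient with no residual degrees of freedom.
    """

    station: str
    depth_m: float
    treatment: Treatment
    rate_nmolN_L_d: float
    slope_nmol15N_per_h: float
    slope_se: Optional[float]
    n_points: int
    p_one_sided: Optional[float]
    censored_points: int


def censor_below_detection(
    series: IncubationSeries, detection_limit_nmolN: float
) -> IncubationSeries:
    """Flag measurements whose N₂O quantity falls below the detection limit.

    Flagged points are retained in the series (for reporting) but excluded
    from the regression by :func:`fit_rate`.
    """
    if detection_limit_nmolN < 0:
        raise DomainError(
            f"detection limit must be >= 0, got {detection_limit_nmolN}"
        )
    flagged = tuple(
        replace(m, below_detection=m.n2o_nmolN < detection_limit_nmolN)
        for m in series.measurements
    )
    return replace(series, measurements=flagged)


def fit_rate(series: IncubationSeries, c: IsotopeConstants) -> RateEstimate:
    """Estimate the volumetric N₂O production rate from a labelled time series.

    Each measurement is converted to nmol ¹⁵N; the slope of ¹⁵N₂O against
    time (h) is fitted by ordinary least squares, and

        rate = slope × 24 / (f¹⁵ × V)   [nmol N L⁻¹ d⁻¹].

    Two usable points give the exact difference quotient with no standard
    error; three or more also yield the slope SE and a one-sided p-value for
    slope > 0.
    """
    usable = series.usable
    times = np.array([m.time_h for m in usable], dtype=float)
    if len(usable) < 2 or len(np.unique(times)) < 2:
        raise EstimationError(
            f"series {series.station}/{series.depth_m} m/"
            f"{series.treatment.value}: fewer than 2 usable measurements at "
            f"distinct times ({series.censored_count} censored)"
        )
    if series.tracer.f15 <= 0:
        raise EstimationError("tracer f15 must be > 0 to convert slope to a rate")

    n15 = np.array([labeled_n_amount(m, c) for m in usable], dtype=float)

    if len(usable) == 2:
        slope = (n15[1] - n15[0]) / (times[1] - times[0])
        se: Optional[float] = None
        p: Optional[float] = None
    else:
        fit = stats.linregress(times, n15)
        slope = float(fit.slope)
        se = float(fit.stderr)
        # one-sided test of slope > 0
        p = float(fit.pvalue / 2.0 if slope > 0 else 1.0 - fit.pvalue / 2.0)

    rate = slope * HOURS_PER_DAY / (series.tracer.f15 * series.tracer.liquid_volume_L)
    return RateEstimate(
        station=series.station,
        depth_m=series.depth_m,
        treatment=series.treatment,
        rate_nmolN_L_d=float(rate),
        slope_nmol15N_per_h=float(slope),
        slope_se=se,
        n_points=len(usable),
        p_one_sided=p,
        censored_points=series.censored_count,
    )


@dataclass(frozen=True)
class PartitionedProfile:
    """Per-depth source-partitioned rates (all nmol N L⁻¹ d⁻¹, non-negative)."""

    station: str
    depth_m: float
    o2_uM: float
    total_no3_rate: float
    fungal_rate: float
    bacterial_rate: float
    nitrification_rate: float
    clamped: bool = False
    floored_inputs: bool = False
    nitrification_missing: bool = False


def partition_depth(
    total: RateEstimate,
    cap: RateEstimate,
    nh4: Optional[RateEstimate],
    depth_m: float,
    o2_uM: float,
) -> PartitionedProfile:
    """Attribute one depth's rates to fungal / bacterial / nitrification sources.

    fungal = chloramphenicol rate (upper limit of fungal denitrification);
    bacterial = total − fungal, clamped at zero with a flag if the inhibited
    rate exceeded the uninhibited one; nitrification = the ¹⁵NH₄⁺ rate.
    Negative fitted inputs (regression noise around zero) are floored at
    zero and flagged before partitioning.
    """
    if total.treatment is not Treatment.NO3 or cap.treatment is not Treatment.NO3_CAP:
        raise DomainError(
            f"partition needs treatments NO3 and NO3_CAP, got "
            f"{total.treatment.value} and {cap.treatment.value}"
        )
    if (total.station, total.depth_m) != (cap.station, cap.depth_m):
        raise DomainError(
            f"mismatched series: total from {total.station}/{total.depth_m} m, "
            f"cap from {cap.station}/{cap.depth_m} m"
        )
    if nh4 is not None and (
        nh4.treatment is not Treatment.NH4
        or (nh4.station, nh4.depth_m) != (total.station, total.depth_m)
    ):
        raise DomainError("NH4 estimate does not match station/depth/treatment")

    floored = False
    t_rate, c_rate = total.rate_nmolN_L_d, cap.rate_nmolN_L_d
    n_rate = nh4.rate_nmolN_L_d if nh4 is not None else 0.0
    if min(t_rate, c_rate, n_rate) < 0:
        floored = True
        t_rate, c_rate, n_rate = (max(x, 0.0) for x in (t_rate, c_rate, n_rate))

    clamped = c_rate > t_rate
    fungal = c_rate
    bacterial = max(t_rate - c_rate, 0.0)
    if not clamped:
        # re-sum so fungal + bacterial == total holds exactly in floats
        t_rate = fungal + bacterial
    return PartitionedProfile(
        station=total.station,
        depth_m=depth_m,
        o2_uM=o2_uM,
        total_no3_rate=t_rate,
        fungal_rate=fungal,
        bacterial_rate=bacterial,
        nitrification_rate=n_rate,
        clamped=clamped,
        floored_inputs=floored,
        nitrification_missing=nh4 is None,
    )


def find_interface(
    depths_m: Sequence[float], o2_uM: Sequence[float], threshold_uM: float
) -> float:
    """Depth (m) where O₂ first falls below ``threshold_uM``.

    The profile is scanned downward; the crossing is linearly interpolated
    between the bracketing sampled depths. If the shallowest sample is
    already below the threshold, that depth is returned.
    """
    z = np.asarray(depths_m, dtype=float)
    o2 = np.asarray(o2_uM, dtype=float)
    if z.size < 2 or z.size != o2.size:
        raise DomainError("need >= 2 matching (depth, O2) points")
    if not np.all(np.diff(z) > 0):
        raise DomainError("depth grid must be strictly increasing")
    if threshold_uM < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold_uM}")

    below = o2 < threshold_uM
    if below[0]:
        return float(z[0])
    if not below.any():
        raise DomainError(
            f"O2 never falls below {threshold_uM} µM within the sampled "
            f"profile (min {o2.min():.3g} µM)"
        )
    i = int(np.argmax(below))  # first True
    z0, z1, c0, c1 = z[i - 1], z[i], o2[i - 1], o2[i]
    return float(z0 + (z1 - z0) * (c0 - threshold_uM) / (c0 - c1))


@dataclass(frozen=True)
class IntegratedContribution:
    """Depth-integrated fungal and total NO₃⁻-derived N₂O production.

    Integrals are in µmol N m⁻² d⁻¹ (nmol N L⁻¹ d⁻¹ integrated over metres
    converts one-to-one).
    """

    station: str
    z_top_m: float
    z_bottom_m: float
    integral_fungal: float
    integral_total_no3: float
    fungal_fraction_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.z_top_m < self.z_bottom_m:
            raise DomainError(
                f"z_top ({self.z_top_m}) must be above z_bottom ({self.z_bottom_m})"
            )
        if self.integral_total_no3 == 0:
            raise EstimationError(
                "total NO3-derived integral is zero; fungal fraction undefined"
            )
        object.__setattr__(
            self,
            "fungal_fraction_percent",
            100.0 * self.integral_fungal / self.integral_total_no3,
        )


def integrate_contribution(
    profiles: Sequence[PartitionedProfile], z_top_m: float, z_bottom_m: float
) -> IntegratedContribution:
    """Trapezoidal depth integrals of fungal and total rates over [z_top, z_bottom].

    Rates are linearly interpolated at the clip boundaries; extrapolation
    beyond the sampled depth range is refused.
    """
    if len(profiles) < 2:
        raise DomainError("need >= 2 partitioned depths to integrate")
    stations = {p.station for p in profiles}
    if len(stations) > 1:
        raise DomainError(f"profiles span multiple stations: {sorted(stations)}")
    ordered = sorted(profiles, key=lambda p: p.depth_m)
    z = np.array([p.depth_m for p in ordered], dtype=float)
    if np.any(np.diff(z) <= 0):
        raise DomainError("duplicate depths in partitioned profiles")
    if not (z_top_m < z_bottom_m):
        raise DomainError(f"z_top ({z_top_m}) must be above z_bottom ({z_bottom_m})")
    if z_top_m < z[0] or z_bottom_m > z[-1]:
        raise DomainError(
            f"integration bounds [{z_top_m}, {z_bottom_m}] m extend beyond the "
            f"sampled range [{z[0]}, {z[-1]}] m; extrapolation is refused"
        )

    fungal = np.array([p.fungal_rate for p in ordered], dtype=float)
    total = np.array([p.total_no3_rate for p in ordered], dtype=float)

    inside = (z > z_top_m) & (z < z_bottom_m)
    grid = np.concatenate(([z_top_m], z[inside], [z_bottom_m]))
    integral_fungal = float(np.trapezoid(np.interp(grid, z, fungal), grid))
    integral_total = float(np.trapezoid(np.interp(grid, z, total), grid))

    return IntegratedContribution(
        station=ordered[0].station,
        z_top_m=float(z_top_m),
        z_bottom_m=float(z_bottom_m),
        integral_fungal=integral_fungal,
        integral_total_no3=integral_total,
    )
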
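"""Synthetic incubation experiments with the noise structure of the assay.

The generator builds a "truth" for each station — per-pathway volumetric
N₂O production rates as a function of depth through an oxycline — and then
simulates the measurements an isotope-ratio mass spectrometer would return
for bottle incubations at each depth: whole-bottle N₂O quantities (nmol N)
and bulk δ¹⁵N-N₂O (‰) at 2–3 time points over 24 h.

Oxygen control of the pathways uses a single-parameter exponential
inhibition, R(O₂) = R_max · exp(−O₂ / k_O₂). Fungal denitrification is
given a larger k_O₂ than bacterial denitrification by default, so the
fungal share of NO₃⁻-derived N₂O rises as O₂ increases through the
0–1 µM band — the niche structure the partitioning method is designed to
resolve. Chloramphenicol is modelled as multiplying the bacterial rate by a
residual ``cap_leakage_fraction`` (0 = perfect inhibition), which makes the
"fungal" rate from inhibited bottles an upper limit by construction.

Observation noise: N₂O quantities carry multiplicative lognormal noise
(mean 1, coefficient of variation ``n2o_cv``); δ¹⁵N carries additive
Gaussian noise with σ = 2.0‰, the instrument precision. All draws come
from one seeded generator per simulated series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigError, DomainError
from .isotope import (
    DELTA_FLOOR_PERMIL,
    IsotopeMeasurement,
    amount_to_delta,
    compute_label_fraction,
    labeled_n_amount,
)
from .rates import (
    HOURS_PER_DAY,
    IncubationSeries,
    PartitionedProfile,
    Treatment,
    find_interface,
    integrate_contribution,
)


@dataclass(frozen=True)
class PathwayParams:
    """Maximum (anoxic) rate and O₂ inhibition constant of one pathway.

    ``r_max`` in nmol N L⁻¹ d⁻¹; ``k_o2_uM`` is the e-folding O₂
    concentration of the exponential inhibition, in µM.
    """

    r_max: float
    k_o2_uM: float

    def __post_init__(self) -> None:
        if self.r_max < 0:
            raise ConfigError(f"r_max must be >= 0, got {self.r_max}")
        if self.k_o2_uM <= 0:
            raise ConfigError(f"k_o2_uM must be > 0, got {self.k_o2_uM}")


def true_rate(params: PathwayParams, o2_uM: float) -> float:
    """Pathway rate at ambient O₂: R_max · exp(−O₂ / k_O₂)."""
    if o2_uM < 0:
        raise DomainError(f"o2_uM must be >= 0, got {o2_uM}")
    return params.r_max * math.exp(-o2_uM / params.k_o2_uM)


@dataclass(frozen=True)
class O2Profile:
    """Sigmoidal oxycline: O₂(z) = surface / (1 + exp((z − center)/scale)).

    Monotone non-increasing in depth for positive ``scale_m``.
    """

    surface_uM: float
    center_m: float
    scale_m: float

    def __post_init__(self) -> None:
        if self.surface_uM < 0:
            raise ConfigError(f"surface_uM must be >= 0, got {self.surface_uM}")
        if self.scale_m <= 0:
            raise ConfigError(f"scale_m must be > 0, got {self.scale_m}")

    def at(self, depth_m: float) -> float:
        return self.surface_uM / (1.0 + math.exp((depth_m - self.center_m) / self.scale_m))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise of the simulated instrument."""

    delta_sigma_permil: float = 2.0
    n2o_cv: float = 0.02
    detection_limit_nmolN: float = 1.0

    def __post_init__(self) -> None:
        if min(self.delta_sigma_permil, self.n2o_cv, self.detection_limit_nmolN) < 0:
            raise ConfigError("noise parameters must be non-negative")


#: Noise-free variant used in round-trip and oracle tests.
NOISE_FREE = NoiseModel(delta_sigma_permil=0.0, n2o_cv=0.0, detection_limit_nmolN=0.0)


@dataclass(frozen=True)
class StationScenario:
    """Synthetic truth for one station: sampling grid, oxycline, pathway rates.

    The ambient nitrate profile is linear in depth,
    NO₃⁻(z) = no3_surface + no3_slope · z (µmol L⁻¹). Background dissolved
    N₂O (nM of N₂O molecules) sits at ``background_delta15n_permil`` before
    tracer-derived production accrues on top of it.
    """

    name: str
    depths_m: tuple[float, ...]
    o2: O2Profile
    fungal: PathwayParams
    bacterial: PathwayParams
    nitrification: PathwayParams
    z_top_m: float  # top of the oxycline; upper integration bound
    no3_surface_umolL: float = 15.0
    no3_slope_umolL_per_m: float = 0.05
    background_n2o_nM: float = 50.0
    background_delta15n_permil: float = 0.0
    cap_leakage_fraction: float = 0.0
    timepoints_h: tuple[float, ...] = (0.0, 12.0, 24.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths_m", tuple(float(z) for z in self.depths_m))
        object.__setattr__(
            self, "timepoints_h", tuple(float(t) for t in self.timepoints_h)
        )
        if len(self.depths_m) < 2 or any(np.diff(self.depths_m) <= 0):
            raise ConfigError("depths_m must be >= 2 strictly increasing depths")
        if not (0.0 <= self.cap_leakage_fraction <= 1.0):
            raise ConfigError(
                f"cap_leakage_fraction must be in [0, 1], got "
                f"{self.cap_leakage_fraction}"
            )
        if 0.0 not in self.timepoints_h or len(self.timepoints_h) < 2:
            raise ConfigError("timepoints_h must include 0 and one later time")
        if self.background_n2o_nM <= 0:
            raise ConfigError("background_n2o_nM must be > 0")
        o2_grid = [self.o2.at(z) for z in self.depths_m]
        if any(np.diff(o2_grid) > 1e-12) or min(o2_grid) < 0:
            raise ConfigError("O2 profile must be non-negative and non-increasing")

    def no3_at(self, depth_m: float) -> float:
        return self.no3_surface_umolL + self.no3_slope_umolL_per_m * depth_m

    def pathway_rates_at(self, depth_m: float) -> dict[str, float]:
        """True fungal/bacterial/nitrification rates at a depth's in-situ O₂."""
        o2 = self.o2.at(depth_m)
        return {
            "fungal": true_rate(self.fungal, o2),
            "bacterial": true_rate(self.bacterial, o2),
            "nitrification": true_rate(self.nitrification, o2),
        }

    def labelled_rate(self, depth_m: float, treatment: Treatment) -> float:
        """Rate of N₂O production fed by the labelled substrate pool."""
        r = self.pathway_rates_at(depth_m)
        if treatment is Treatment.NO3:
            return r["fungal"] + r["bacterial"]
        if treatment is Treatment.NO3_CAP:
            return r["fungal"] + self.cap_leakage_fraction * r["bacterial"]
        return r["nitrification"]


def _tracer_for(
    scenario: StationScenario, depth_m: float, treatment: Treatment, config: RunConfig
):
    substrate = treatment.substrate
    dose = config.dose_for(substrate)
    if substrate == "nitrate":
        ambient = scenario.no3_at(depth_m)
        detection = config.no3_detection_umolL
    else:
        # ambient NH4 in the oxycline sits at/below the 15 nM detection limit
        ambient = 0.0
        detection = config.nh4_detection_umolL
    return compute_label_fraction(
        substrate,
        dose.added_nmol,
        dose.purity_fraction,
        ambient,
        config.liquid_volume_L,
        config.constants,
        include_ambient=config.f15_includes_ambient,
        ambient_detection_umolL=detection,
    )


def simulate_incubation(
    scenario: StationScenario,
    depth_m: float,
    treatment: Treatment | str,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    config: Optional[RunConfig] = None,
    timepoints_h: Optional[Sequence[float]] = None,
) -> IncubationSeries:
    """Simulate one bottle series at a station depth under one treatment.

    Truth construction: the whole-bottle N₂O pool grows linearly,
    N(t) = N₀ + R·V·t, and its labelled part as ¹⁵N(t) = ¹⁵N₀ + R·f¹⁵·V·t,
    where R is the labelled-substrate production rate for the treatment and
    N₀ the background N₂O at the background δ¹⁵N. Observations then get
    lognormal quantity noise and Gaussian δ noise. Deterministic given the
    seed; fitting the noise-free output returns R to float precision.
    """
    treatment = Treatment(treatment)
    config = config or RunConfig()
    if depth_m not in scenario.depths_m:
        raise DomainError(
            f"depth {depth_m} m is not on the scenario grid {scenario.depths_m}"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    times = tuple(timepoints_h) if timepoints_h is not None else scenario.timepoints_h

    tracer = _tracer_for(scenario, depth_m, treatment, config)
    v = config.liquid_volume_L
    rate = scenario.labelled_rate(depth_m, treatment)

    # background pool: nM N2O molecules -> nmol N atoms in the bottle
    n0 = scenario.background_n2o_nM * 2.0 * v
    n15_0 = labeled_n_amount(
        IsotopeMeasurement(0.0, n0, scenario.background_delta15n_permil),
        config.constants,
    )

    sigma_ln = math.sqrt(math.log1p(noise.n2o_cv**2))
    measurements = []
    for t in times:
        n_true = n0 + rate * v * t / HOURS_PER_DAY
        n15_true = n15_0 + rate * tracer.f15 * v * t / HOURS_PER_DAY
        delta_true = amount_to_delta(n15_true, n_true, config.constants)
        if sigma_ln > 0:
            n_obs = n_true * rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln)
        else:
            n_obs = n_true
        delta_obs = delta_true + (
            rng.normal(0.0, noise.delta_sigma_permil)
            if noise.delta_sigma_permil > 0
            else 0.0
        )
        delta_obs = max(delta_obs, math.nextafter(DELTA_FLOOR_PERMIL, math.inf))
        measurements.append(
            IsotopeMeasurement(
                time_h=t,
                n2o_nmolN=n_obs,
                delta15n_permil=delta_obs,
                below_detection=n_obs < noise.detection_limit_nmolN,
            )
        )

    return IncubationSeries(
        station=scenario.name,
        depth_m=depth_m,
        treatment=treatment,
        tracer=tracer,
        measurements=tuple(measurements),
    )


def station_truth(
    scenario: StationScenario, config: Optional[RunConfig] = None
) -> dict:
    """The scenario's true partitioned profile and integrated fungal fraction.

    Uses the same interface criterion and trapezoidal integration as the
    analysis pipeline, on the noise-free per-depth rates, so a noise-free
    simulated run recovers these numbers exactly.
    """
    config = config or RunConfig()
    profiles = []
    for z in scenario.depths_m:
        r = scenario.pathway_rates_at(z)
        profiles.append(
            PartitionedProfile(
                station=scenario.name,
                depth_m=z,
                o2_uM=scenario.o2.at(z),
                total_no3_rate=r["fungal"] + r["bacterial"],
                fungal_rate=r["fungal"],
                bacterial_rate=r["bacterial"],
                nitrification_rate=r["nitrification"],
            )
        )
    o2_grid = [p.o2_uM for p in profiles]
    z_interface = find_interface(
        scenario.depths_m, o2_grid, config.o2_threshold_uM
    )
    contrib = integrate_contribution(profiles, scenario.z_top_m, z_interface)
    return {
        "station": scenario.name,
        "z_top_m": scenario.z_top_m,
        "z_interface_m": z_interface,
        "integral_fungal_umolN_m2_d": contrib.integral_fungal,
        "integral_total_no3_umolN_m2_d": contrib.integral_total_no3,
        "fungal_fraction_percent": contrib.fungal_fraction_percent,
    }


def generate_station(
    scenario: StationScenario,
    noise: NoiseModel,
    seed: int,
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit the tables the analysis pipeline reads, plus a sidecar truth.

    Returns ``(profile, incubations, truth)`` where ``profile`` has columns
    station, depth_m, o2_uM, no3_umolL, nh4_umolL; ``incubations`` has
    station, depth_m, treatment, time_h, n2o_nmolN, delta15n_permil; and
    ``truth`` records the generating rates and the true integrated fungal
    fraction for recovery tests. Deterministic given the seed.
    """
    config = config or RunConfig()
    profile = pd.DataFrame(
        {
            "station": scenario.name,
            "depth_m": scenario.depths_m,
            "o2_uM": [scenario.o2.at(z) for z in scenario.depths_m],
            "no3_umolL": [scenario.no3_at(z) for z in scenario.depths_m],
            "nh4_umolL": 0.0,
        }
    )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenario.depths_m) * len(Treatment))
    rows = []
    i = 0
    for z in scenario.depths_m:
        for treatment in Treatment:
            series = simulate_incubation(
                scenario, z, treatment, noise, np.random.default_rng(children[i]),
                config=config,
            )
            i += 1
            for m in series.measurements:
                rows.append(
                    {
                        "station": scenario.name,
                        "depth_m": z,
                        "treatment": treatment.value,
                        "time_h": m.time_h,
                        "n2o_nmolN": m.n2o_nmolN,
                        "delta15n_permil": m.delta15n_permil,
                    }
                )
    incubations = pd.DataFrame(rows)

    truth = station_truth(scenario, config)
    truth["seed"] = seed
    truth["cap_leakage_fraction"] = scenario.cap_leakage_fraction
    truth["per_depth_rates"] = {
        z: scenario.pathway_rates_at(z) for z in scenario.depths_m
    }
    return profile, incubations, truth


# ---------------------------------------------------------------------------
# Ready-made scenarios


def default_two_stations(
    cap_leakage_fraction: float = 0.0,
) -> tuple[StationScenario, StationScenario]:
    """The default study design: two oxycline stations.

    Station 1 (oxycline top at 60 m, endpoint sampling at 0 and 24 h) and
    Station 2 (oxycline top at 90 m, sampling at 0, 12 and 24 h). Bacterial
    denitrification is strongly O₂-inhibited (k_O₂ = 0.5 µM), fungal
    denitrification less so (k_O₂ = 2 µM), and nitrification weakly
    (k_O₂ = 30 µM). Fungal R_max values are fixed so that the true
    depth-integrated fungal share of NO₃⁻-derived N₂O production between
    the oxycline top and the oxic–anoxic interface is 20.0% at each
    station.
    """
    st1 = StationScenario(
        name="Station1",
        depths_m=(60.0, 70.0, 78.0, 84.0, 89.0, 93.0, 97.0, 101.0, 108.0, 120.0),
        o2=O2Profile(surface_uM=210.0, center_m=72.0, scale_m=4.0),
        fungal=PathwayParams(r_max=FUNGAL_RMAX_ST1, k_o2_uM=2.0),
        bacterial=PathwayParams(r_max=40.0, k_o2_uM=0.5),
        nitrification=PathwayParams(r_max=5.0, k_o2_uM=30.0),
        z_top_m=60.0,
        cap_leakage_fraction=cap_leakage_fraction,
        timepoints_h=(0.0, 24.0),
    )
    st2 = StationScenario(
        name="Station2",
        depths_m=(90.0, 100.0, 108.0, 114.0, 119.0, 123.0, 127.0, 131.0, 140.0, 275.0),
        o2=O2Profile(surface_uM=205.0, center_m=100.0, scale_m=5.0),
        fungal=PathwayParams(r_max=FUNGAL_RMAX_ST2, k_o2_uM=2.0),
        bacterial=PathwayParams(r_max=40.0, k_o2_uM=0.5),
        nitrification=PathwayParams(r_max=5.0, k_o2_uM=30.0),
        z_top_m=90.0,
        cap_leakage_fraction=cap_leakage_fraction,
        timepoints_h=(0.0, 12.0, 24.0),
    )
    return st1, st2


#: Fungal anoxic maximum rates (nmol N L⁻¹ d⁻¹) fixed so each default
#: station's true integrated fungal fraction is 20.0% on its sampling grid.
FUNGAL_RMAX_ST1 = 1.2167015
FUNGAL_RMAX_ST2 = 1.1306701


def scenario_from_dict(d: dict) -> StationScenario:
    """Build a station scenario from a plain mapping (YAML-friendly).

    Nested blocks ``o2`` (surface_uM/center_m/scale_m) and ``fungal`` /
    ``bacterial`` / ``nitrification`` (r_max/k_o2_uM) mirror the dataclass
    fields; unknown keys raise a config error.
    """
    try:
        d = dict(d)
        o2 = O2Profile(**d.pop("o2"))
        pathways = {
            name: PathwayParams(**d.pop(name))
            for name in ("fungal", "bacterial", "nitrification")
        }
        return StationScenario(o2=o2, **pathways, **d)
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"invalid scenario definition: {exc}") from exc


def load_scenarios(path) -> tuple[list[StationScenario], NoiseModel]:
    """Read a scenario YAML: a ``stations`` list and an optional ``noise`` block."""
    import yaml

    raw = yaml.safe_load(open(path))
    if not isinstance(raw, dict) or "stations" not in raw:
        raise ConfigError(f"{path}: scenario file needs a 'stations' list")
    try:
        noise = NoiseModel(**raw.get("noise", {}))
    except TypeError as exc:
        raise ConfigError(f"{path}: invalid noise block: {exc}") from exc
    return [scenario_from_dict(s) for s in raw["stations"]], noise


def constant_rate_scenario(
    rate_nmolN_L_d: float, depth_m: float = 100.0
) -> StationScenario:
    """A single effective depth with zero O₂ and a fixed NO₃⁻-fed rate.

    Used for rate-recovery experiments where the truth must be a known
    constant: the whole labelled production is assigned to the bacterial
    pathway at O₂ = 0, so the NO₃⁻-treatment labelled rate equals
    ``rate_nmolN_L_d`` exactly.
    """
    return StationScenario(
        name="ConstantRate",
        depths_m=(depth_m, depth_m + 10.0),
        o2=O2Profile(surface_uM=0.0, center_m=depth_m, scale_m=10.0),
        fungal=PathwayParams(r_max=0.0, k_o2_uM=2.0),
        bacterial=PathwayParams(r_max=rate_nmolN_L_d, k_o2_uM=1.0),
        nitrification=PathwayParams(r_max=0.0, k_o2_uM=30.0),
        z_top_m=depth_m,
    )


def rate_recovery_errors(
    rate_nmolN_L_d: float,
    n_seeds: int,
    noise: NoiseModel,
    seed: int,
    config: Optional[RunConfig] = None,
    timepoints_h: Sequence[float] = (0.0, 12.0, 24.0),
) -> np.ndarray:
    """Relative errors of the fitted rate over ``n_seeds`` replicate bottles.

    Each replicate simulates a ¹⁵NO₃⁻ incubation at a fixed true rate and
    refits it; returns (fitted − true)/true per replicate.
    """
    from .rates import fit_rate  # local import to avoid cycle at module load

    config = config or RunConfig()
    scenario = constant_rate_scenario(rate_nmolN_L_d)
    ss = np.random.SeedSequence(seed)
    errors = np.empty(n_seeds)
    for i, child in enumerate(ss.spawn(n_seeds)):
        series = simulate_incubation(
            scenario,
            scenario.depths_m[0],
            Treatment.NO3,
            noise,
            np.random.default_rng(child),
            config=config,
            timepoints_h=timepoints_h,
        )
        est = fit_rate(series, config.constants)
        errors[i] = (est.rate_nmolN_L_d - rate_nmolN_L_d) / rate_nmolN_L_d
    return errors
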
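"""High-level orchestration: simulate → fit → partition → integrate.

These functions connect the domain operations on whole tables and are what
the command line, the analysis drivers and the recovery experiments call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .errors import DomainError, EstimationError
from .io import (
    integration_to_frame,
    partition_to_frame,
    rates_to_frame,
)
from .rates import (
    IncubationSeries,
    IntegratedContribution,
    PartitionedProfile,
    RateEstimate,
    Treatment,
    censor_below_detection,
    find_interface,
    fit_rate,
    integrate_contribution,
    partition_depth,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All tables produced by one end-to-end run."""

    rates: pd.DataFrame
    partition: pd.DataFrame
    integration: pd.DataFrame
    excluded: list[tuple[str, float, str, str]]


def fit_all(
    series_list: Sequence[IncubationSeries], config: RunConfig
) -> tuple[list[RateEstimate], list[tuple[str, float, str, str]]]:
    """Censor and fit every series; series that cannot be fitted are
    collected as (station, depth, treatment, reason) instead of aborting
    the run."""
    estimates: list[RateEstimate] = []
    excluded: list[tuple[str, float, str, str]] = []
    for series in series_list:
        censored = censor_below_detection(series, config.detection_limit_nmolN)
        try:
            estimates.append(fit_rate(censored, config.constants))
        except EstimationError as exc:
            excluded.append(
                (series.station, series.depth_m, series.treatment.value, str(exc))
            )
    return estimates, excluded


def partition_all(
    estimates: Sequence[RateEstimate], profile: pd.DataFrame
) -> list[PartitionedProfile]:
    """Partition every (station, depth) that has both NO3 and NO3_CAP rates.

    The NH4 (nitrification) estimate is optional per depth. In-situ O₂ is
    looked up from the profile table; depths absent from it are skipped
    with a warning, since they cannot be placed on the O₂ axis.
    """
    o2: dict[tuple[str, float], float] = {
        (str(r.station), float(r.depth_m)): float(r.o2_uM)
        for r in profile.itertuples()
    }
    by_key: dict[tuple[str, float], dict[Treatment, RateEstimate]] = {}
    for e in estimates:
        by_key.setdefault((e.station, e.depth_m), {})[e.treatment] = e

    profiles: list[PartitionedProfile] = []
    for (station, depth), group in sorted(by_key.items()):
        if Treatment.NO3 not in group or Treatment.NO3_CAP not in group:
            logger.warning(
                "%s / %s m: missing NO3 or NO3_CAP estimate; depth not partitioned",
                station,
                depth,
            )
            continue
        if (station, depth) not in o2:
            logger.warning(
                "%s / %s m: no O2 in profile table; depth not partitioned",
                station,
                depth,
            )
            continue
        profiles.append(
            partition_depth(
                group[Treatment.NO3],
                group[Treatment.NO3_CAP],
                group.get(Treatment.NH4),
                depth_m=depth,
                o2_uM=o2[(station, depth)],
            )
        )
    return profiles


def integrate_all(
    profiles: Sequence[PartitionedProfile],
    profile_table: pd.DataFrame,
    config: RunConfig,
    z_top: float | Mapping[str, float] | None = None,
) -> list[IntegratedContribution]:
    """Integrate each station from its oxycline top to the oxic–anoxic interface.

    The interface depth is found per station from the O₂ profile at the
    configured threshold. ``z_top`` may be a single depth, a per-station
    mapping, or None (the station's shallowest partitioned depth).
    """
    contributions: list[IntegratedContribution] = []
    stations = sorted({p.station for p in profiles})
    for station in stations:
        station_profiles = [p for p in profiles if p.station == station]
        prof = profile_table.loc[profile_table["station"] == station]
        z_interface = find_interface(
            prof["depth_m"].to_numpy(),
            prof["o2_uM"].to_numpy(),
            config.o2_threshold_uM,
        )
        if z_top is None:
            top = min(p.depth_m for p in station_profiles)
        elif isinstance(z_top, Mapping):
            if station not in z_top:
                raise DomainError(f"no z_top given for station {station!r}")
            top = float(z_top[station])
        else:
            top = float(z_top)
        contributions.append(
            integrate_contribution(station_profiles, top, z_interface)
        )
    return contributions


def simulate_and_recover(
    scenario,
    noise,
    seed: int,
    config: Optional[RunConfig] = None,
) -> tuple[float, dict]:
    """Simulate one station and run the full analysis on its tables.

    Returns the recovered depth-integrated fungal fraction (percent) and
    the scenario's sidecar truth; the recovery experiments repeat this over
    seeds to characterise estimator noise and bias.
    """
    from .io import incubations_from_frame
    from .simulate import generate_station

    config = config or RunConfig()
    profile, incubations, truth = generate_station(scenario, noise, seed, config)
    series = incubations_from_frame(incubations, config, profile)
    result = run_pipeline(series, profile, config, z_top=scenario.z_top_m)
    return float(result.integration["fungal_fraction_percent"].iloc[0]), truth


def run_pipeline(
    series_list: Sequence[IncubationSeries],
    profile_table: pd.DataFrame,
    config: RunConfig,
    z_top: float | Mapping[str, float] | None = None,
) -> PipelineResult:
    """Fit, partition and integrate a whole campaign in one call."""
    estimates, excluded = fit_all(series_list, config)
    profiles = partition_all(estimates, profile_table)
    contributions = (
        integrate_all(profiles, profile_table, config, z_top) if profiles else []
    )
    return PipelineResult(
        rates=rates_to_frame(estimates),
        partition=partition_to_frame(profiles),
        integration=integration_to_frame(contributions),
        excluded=excluded,
    )
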
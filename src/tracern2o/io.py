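"""Readers and writers for the pipeline's CSV tables and the run report.

Schemas (exact column names):

* ``incubations.csv`` — station, depth_m, treatment {NO3|NO3_CAP|NH4},
  time_h, n2o_nmolN, delta15n_permil
* ``profile.csv`` — station, depth_m, o2_uM, no3_umolL, nh4_umolL
* outputs ``rates.csv``, ``partition.csv``, ``integration.csv`` mirror the
  result types field-for-field.

Floats are written at full repr precision so write-then-read round-trips
reproduce in-memory values exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .errors import DomainError, SchemaError
from .isotope import IsotopeMeasurement, compute_label_fraction
from .rates import (
    IncubationSeries,
    IntegratedContribution,
    PartitionedProfile,
    RateEstimate,
    Treatment,
)

logger = logging.getLogger(__name__)

INCUBATION_COLUMNS = (
    "station",
    "depth_m",
    "treatment",
    "time_h",
    "n2o_nmolN",
    "delta15n_permil",
)
PROFILE_COLUMNS = ("station", "depth_m", "o2_uM", "no3_umolL", "nh4_umolL")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(required)}"
        )


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read a depth-profile table, sorted by station then depth."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROFILE_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: profile table is empty")
    if (df["depth_m"] < 0).any() or (df["o2_uM"] < 0).any():
        raise SchemaError(f"{path}: depths and O2 must be non-negative")
    return df.sort_values(["station", "depth_m"], kind="stable").reset_index(drop=True)


def read_incubations(
    path: str | Path,
    config: RunConfig,
    profile: Optional[pd.DataFrame] = None,
) -> list[IncubationSeries]:
    """Read an incubation table and assemble one series per bottle group.

    Rows are grouped by (station, depth_m, treatment); within each group
    measurements are ordered by time. The tracer specification (dose,
    purity, ambient pool, f¹⁵) is attached from the config, taking the
    ambient nitrate concentration at the matching station/depth from
    ``profile`` when provided (ambient is 0 otherwise, i.e. f¹⁵ = tracer
    purity diluted only by the natural-abundance pool actually present).
    """
    return incubations_from_frame(pd.read_csv(path, float_precision="round_trip"), config, profile, source=str(path))


def incubations_from_frame(
    df: pd.DataFrame,
    config: RunConfig,
    profile: Optional[pd.DataFrame] = None,
    source: str = "incubation table",
) -> list[IncubationSeries]:
    """Frame-based core of :func:`read_incubations` (same validation)."""
    path = source
    _require_columns(df, INCUBATION_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: incubation table is empty")

    allowed = {t.value for t in Treatment}
    bad = df.loc[~df["treatment"].isin(allowed)]
    if not bad.empty:
        values = sorted(bad["treatment"].unique())
        raise SchemaError(
            f"{path}: invalid treatment value(s) {values}; "
            f"allowed: {sorted(allowed)}"
        )
    neg = df.loc[df["n2o_nmolN"] < 0]
    if not neg.empty:
        lines = [int(i) + 2 for i in neg.index[:5]]  # +2: header + 1-based
        raise SchemaError(
            f"{path}: negative n2o_nmolN at line(s) {lines}"
        )
    key = ["station", "depth_m", "treatment", "time_h"]
    dupes = df.loc[df.duplicated(key, keep=False)]
    if not dupes.empty:
        raise SchemaError(
            f"{path}: duplicate (station, depth, treatment, time) rows:\n"
            f"{dupes[key].drop_duplicates().to_string(index=False)}"
        )

    ambient_no3: dict[tuple[str, float], float] = {}
    if profile is not None:
        for row in profile.itertuples():
            ambient_no3[(str(row.station), float(row.depth_m))] = float(row.no3_umolL)

    series_list: list[IncubationSeries] = []
    df = df.sort_values(["station", "depth_m", "treatment", "time_h"], kind="stable")
    for (station, depth, treat_val), group in df.groupby(
        ["station", "depth_m", "treatment"], sort=True
    ):
        treatment = Treatment(treat_val)
        dose = config.dose_for(treatment.substrate)
        if treatment.substrate == "nitrate":
            ambient = ambient_no3.get((str(station), float(depth)), 0.0)
            detection = config.no3_detection_umolL
        else:
            ambient = 0.0
            detection = config.nh4_detection_umolL
        tracer = compute_label_fraction(
            treatment.substrate,
            dose.added_nmol,
            dose.purity_fraction,
            ambient,
            config.liquid_volume_L,
            config.constants,
            include_ambient=config.f15_includes_ambient,
            ambient_detection_umolL=detection,
        )
        try:
            measurements = tuple(
                IsotopeMeasurement(
                    time_h=float(r.time_h),
                    n2o_nmolN=float(r.n2o_nmolN),
                    delta15n_permil=float(r.delta15n_permil),
                )
                for r in group.itertuples()
            )
            series_list.append(
                IncubationSeries(
                    station=str(station),
                    depth_m=float(depth),
                    treatment=treatment,
                    tracer=tracer,
                    measurements=measurements,
                )
            )
        except DomainError as exc:
            raise SchemaError(
                f"{path}: invalid series {station}/{depth} m/{treat_val}: {exc}"
            ) from exc
    return series_list


# ---------------------------------------------------------------------------
# Output tables


def rates_from_frame(df: pd.DataFrame) -> list[RateEstimate]:
    """Rebuild rate estimates from a ``rates.csv`` table (NaN → None)."""
    required = (
        "station",
        "depth_m",
        "treatment",
        "rate_nmolN_L_d",
        "slope_nmol15N_per_h",
        "slope_se",
        "n_points",
        "p_one_sided",
        "censored_points",
    )
    _require_columns(df, required, "rates table")
    out = []
    for r in df.itertuples():
        out.append(
            RateEstimate(
                station=str(r.station),
                depth_m=float(r.depth_m),
                treatment=Treatment(r.treatment),
                rate_nmolN_L_d=float(r.rate_nmolN_L_d),
                slope_nmol15N_per_h=float(r.slope_nmol15N_per_h),
                slope_se=None if pd.isna(r.slope_se) else float(r.slope_se),
                n_points=int(r.n_points),
                p_one_sided=None if pd.isna(r.p_one_sided) else float(r.p_one_sided),
                censored_points=int(r.censored_points),
            )
        )
    return out


def partition_from_frame(df: pd.DataFrame) -> list[PartitionedProfile]:
    """Rebuild partitioned profiles from a ``partition.csv`` table."""
    required = (
        "station",
        "depth_m",
        "o2_uM",
        "total_no3_rate",
        "fungal_rate",
        "bacterial_rate",
        "nitrification_rate",
        "clamped",
        "floored_inputs",
        "nitrification_missing",
    )
    _require_columns(df, required, "partition table")
    return [
        PartitionedProfile(
            station=str(r.station),
            depth_m=float(r.depth_m),
            o2_uM=float(r.o2_uM),
            total_no3_rate=float(r.total_no3_rate),
            fungal_rate=float(r.fungal_rate),
            bacterial_rate=float(r.bacterial_rate),
            nitrification_rate=float(r.nitrification_rate),
            clamped=bool(r.clamped),
            floored_inputs=bool(r.floored_inputs),
            nitrification_missing=bool(r.nitrification_missing),
        )
        for r in df.itertuples()
    ]


def rates_to_frame(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "station": e.station,
                "depth_m": e.depth_m,
                "treatment": e.treatment.value,
                "rate_nmolN_L_d": e.rate_nmolN_L_d,
                "slope_nmol15N_per_h": e.slope_nmol15N_per_h,
                "slope_se": e.slope_se,
                "n_points": e.n_points,
                "p_one_sided": e.p_one_sided,
                "censored_points": e.censored_points,
            }
            for e in estimates
        ]
    )


def partition_to_frame(profiles: Iterable[PartitionedProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "station": p.station,
                "depth_m": p.depth_m,
                "o2_uM": p.o2_uM,
                "total_no3_rate": p.total_no3_rate,
                "fungal_rate": p.fungal_rate,
                "bacterial_rate": p.bacterial_rate,
                "nitrification_rate": p.nitrification_rate,
                "clamped": p.clamped,
                "floored_inputs": p.floored_inputs,
                "nitrification_missing": p.nitrification_missing,
            }
            for p in profiles
        ]
    )


def integration_to_frame(
    contributions: Iterable[IntegratedContribution],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "station": c.station,
                "z_top_m": c.z_top_m,
                "z_bottom_m": c.z_bottom_m,
                "integral_fungal": c.integral_fungal,
                "integral_total_no3": c.integral_total_no3,
                "fungal_fraction_percent": c.fungal_fraction_percent,
            }
            for c in contributions
        ]
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV at full float precision (repr round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def render_report(
    rates: pd.DataFrame,
    partition: Optional[pd.DataFrame],
    integration: Optional[pd.DataFrame],
    excluded: Sequence[tuple[str, float, str, str]] = (),
) -> str:
    """Render the run's tables and flags as a human-readable markdown report.

    ``excluded`` lists (station, depth, treatment, reason) for series that
    produced no rate estimate (e.g. all points censored below detection).
    """
    lines = ["# N2O production rate report", ""]
    lines += ["## Volumetric rates (nmol N L^-1 d^-1)", ""]
    lines.append("```\n" + rates.to_string(index=False) + "\n```")
    lines.append("")
    if partition is not None and not partition.empty:
        lines += ["## Source partition per depth", ""]
        lines.append("```\n" + partition.to_string(index=False) + "\n```")
        lines.append("")
        flagged = partition.loc[partition["clamped"] | partition["floored_inputs"]]
        if not flagged.empty:
            lines += [
                "Flags: `clamped` marks depths where the inhibited (CAP) rate "
                "exceeded the uninhibited rate (bacterial set to 0); "
                "`floored_inputs` marks negative fitted rates floored at 0.",
                "",
            ]
    if integration is not None and not integration.empty:
        lines += ["## Depth-integrated fungal contribution", ""]
        lines.append("```\n" + integration.to_string(index=False) + "\n```")
        lines.append("")
        for row in integration.itertuples():
            lines.append(
                f"- {row.station}: fungi account for "
                f"{row.fungal_fraction_percent:.1f}% of NO3-derived N2O "
                f"production integrated over {row.z_top_m:.0f}-"
                f"{row.z_bottom_m:.1f} m."
            )
        lines.append("")
    if excluded:
        lines += ["## Excluded series", ""]
        for station, depth, treatment, reason in excluded:
            lines.append(f"- {station} / {depth} m / {treatment}: {reason}")
        lines.append("")
    return "\n".join(lines)
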
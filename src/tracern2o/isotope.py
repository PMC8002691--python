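"""Delta-notation arithmetic for ¹⁵N tracer experiments.

The mass spectrometer reports the bulk isotopic composition of N₂O in delta
notation, δ¹⁵N (‰), relative to a reference gas with ¹⁵N/¹⁴N ratio ``r_ref``.
The quantity of labelled nitrogen in a sample follows from

    ¹⁵N₂O = N₂O × R / (1 + R),    R = (δ/1000 + 1) × R_ref,

where N₂O is the total nitrous-oxide quantity in nmol of N atoms and
R/(1+R) is the ¹⁵N atom fraction. This module implements that conversion,
its exact inverse (needed by the simulator), and the atom fraction f¹⁵ of a
substrate pool after tracer addition.

Delta values are per mil throughout; ratios and atom fractions are
dimensionless. δ = −1000‰ corresponds to a pool with no ¹⁵N at all and is
excluded from the domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import ConfigError, DomainError

logger = logging.getLogger(__name__)

#: ¹⁵N/¹⁴N of atmospheric N₂ (AIR), the universal δ¹⁵N reference.
R_AIR = 0.0036765

#: Lower bound of the delta domain (‰); at −1000‰ the isotope ratio is zero.
DELTA_FLOOR_PERMIL = -1000.0


@dataclass(frozen=True)
class IsotopeConstants:
    """Isotope ratios of the measurement reference and of natural nitrogen.

    Parameters
    ----------
    r_ref : float
        ¹⁵N/¹⁴N isotope ratio of the reference gas against which δ¹⁵N-N₂O
        is reported. Defaults to AIR.
    r_air : float
        ¹⁵N/¹⁴N of atmospheric N₂, used for the natural abundance of
        ambient (unlabelled) substrate pools.
    """

    r_ref: float = R_AIR
    r_air: float = R_AIR

    def __post_init__(self) -> None:
        for name in ("r_ref", "r_air"):
            value = getattr(self, name)
            if not (0.0 < value < 0.05):
                raise ConfigError(
                    f"{name} must be a positive nitrogen isotope ratio below "
                    f"0.05, got {value!r}"
                )

    @property
    def natural_atom_fraction(self) -> float:
        """Atom fraction ¹⁵N of nitrogen at natural abundance."""
        return ratio_to_atom_fraction(self.r_air)


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One time point of an incubation: N₂O quantity and its bulk δ¹⁵N.

    ``n2o_nmolN`` is the whole-bottle N₂O quantity expressed in nmol of N
    atoms (two per molecule), matching the units of the instrument's
    detection limit.
    """

    time_h: float
    n2o_nmolN: float
    delta15n_permil: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise DomainError(f"time_h must be >= 0, got {self.time_h}")
        if self.n2o_nmolN < 0:
            raise DomainError(f"n2o_nmolN must be >= 0, got {self.n2o_nmolN}")
        if not self.delta15n_permil > DELTA_FLOOR_PERMIL:
            raise DomainError(
                f"delta15n_permil must exceed {DELTA_FLOOR_PERMIL}‰ "
                f"(isotope ratio must stay positive), got {self.delta15n_permil}"
            )


@dataclass(frozen=True)
class TracerSpec:
    """What was added to a bottle and the resulting substrate label fraction.

    ``f15`` is the atom fraction ¹⁵N of the total substrate pool (tracer +
    ambient) and is what the rate equation divides by. It is computed by
    :func:`compute_label_fraction`, not supplied directly.
    """

    substrate: str  # "nitrate" | "ammonium"
    added_nmol: float
    purity_fraction: float
    ambient_umolL: float
    liquid_volume_L: float
    f15: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.substrate not in ("nitrate", "ammonium"):
            raise ConfigError(
                f"substrate must be 'nitrate' or 'ammonium', got {self.substrate!r}"
            )
        if not (0.0 < self.purity_fraction <= 1.0):
            raise ConfigError(
                f"purity_fraction must be in (0, 1], got {self.purity_fraction}"
            )
        if self.liquid_volume_L <= 0:
            raise ConfigError(
                f"liquid_volume_L must be > 0, got {self.liquid_volume_L}"
            )
        if self.added_nmol < 0 or self.ambient_umolL < 0:
            raise ConfigError("tracer and ambient amounts must be non-negative")
        if not (0.0 <= self.f15 <= self.purity_fraction + 1e-12):
            raise ConfigError(
                f"f15 ={self.f15} outside [0, purity={self.purity_fraction}]"
            )


def delta_to_ratio(delta_permil: float, r_std: float) -> float:
    """Convert a delta value (‰) to an isotope ratio against standard ``r_std``."""
    if not delta_permil > DELTA_FLOOR_PERMIL:
        raise DomainError(
            f"delta must exceed {DELTA_FLOOR_PERMIL}‰, got {delta_permil}"
        )
    if r_std <= 0:
        raise DomainError(f"r_std must be > 0, got {r_std}")
    return r_std * (delta_permil / 1000.0 + 1.0)


def ratio_to_delta(r: float, r_std: float) -> float:
    """Inverse of :func:`delta_to_ratio`."""
    if r <= 0:
        raise DomainError(f"ratio must be > 0, got {r}")
    if r_std <= 0:
        raise DomainError(f"r_std must be > 0, got {r_std}")
    return (r / r_std - 1.0) * 1000.0


def ratio_to_atom_fraction(r: float) -> float:
    """Atom fraction ¹⁵N from the ¹⁵N/¹⁴N ratio: r / (1 + r)."""
    if r < 0:
        raise DomainError(f"isotope ratio must be >= 0, got {r}")
    return r / (1.0 + r)


def atom_fraction_to_ratio(f: float) -> float:
    """Inverse of :func:`ratio_to_atom_fraction`: f / (1 − f)."""
    if not (0.0 <= f < 1.0):
        raise DomainError(f"atom fraction must be in [0, 1), got {f}")
    return f / (1.0 - f)


def labeled_n_amount(m: IsotopeMeasurement, c: IsotopeConstants) -> float:
    """nmol of ¹⁵N in the measured N₂O.

    Applies the atom-fraction form of the delta equation to the bulk
    measurement: ¹⁵N₂O = N₂O × R/(1+R) with R = (δ/1000+1)·R_ref. The
    result is bounded by [0, n2o_nmolN).
    """
    r = delta_to_ratio(m.delta15n_permil, c.r_ref)
    return m.n2o_nmolN * ratio_to_atom_fraction(r)


def amount_to_delta(n15_nmol: float, n2o_nmolN: float, c: IsotopeConstants) -> float:
    """Bulk δ¹⁵N (‰) of N₂O containing ``n15_nmol`` of ¹⁵N out of ``n2o_nmolN``.

    Exact inverse of :func:`labeled_n_amount`; used by the simulator to turn
    true labelled amounts into instrument-scale observations.
    """
    if n2o_nmolN <= 0:
        raise DomainError(f"n2o_nmolN must be > 0, got {n2o_nmolN}")
    if not (0.0 <= n15_nmol < n2o_nmolN):
        raise DomainError(
            f"n15_nmol must lie in [0, n2o_nmolN={n2o_nmolN}), got {n15_nmol}"
        )
    f = n15_nmol / n2o_nmolN
    if f == 0.0:
        # ratio 0 is below the open delta domain; represent as -1000 + eps
        return math.nextafter(DELTA_FLOOR_PERMIL, math.inf)
    return ratio_to_delta(atom_fraction_to_ratio(f), c.r_ref)


def compute_label_fraction(
    substrate: str,
    added_nmol: float,
    purity_fraction: float,
    ambient_umolL: float,
    liquid_volume_L: float,
    c: IsotopeConstants,
    *,
    include_ambient: bool = True,
    ambient_detection_umolL: float = 0.0,
) -> TracerSpec:
    """Atom fraction ¹⁵N of the substrate pool after tracer addition.

    The pool is the amount-weighted mixture of tracer (atom fraction =
    ``purity_fraction``) and ambient substrate at natural abundance:

        f¹⁵ = (added·purity + ambient_pool·f_nat) / (added + ambient_pool)

    with ``ambient_pool = ambient_umolL × liquid_volume_L × 1000`` nmol and
    ``f_nat = r_air/(1 + r_air)``. Ambient concentrations at or below the
    analytical detection limit are treated as zero (logged). With
    ``include_ambient=False`` the ambient pool is ignored entirely and
    f¹⁵ equals the tracer purity.
    """
    if added_nmol < 0 or ambient_umolL < 0:
        raise DomainError("amounts must be non-negative")
    if liquid_volume_L <= 0:
        raise DomainError(f"liquid_volume_L must be > 0, got {liquid_volume_L}")

    ambient = ambient_umolL
    if ambient <= ambient_detection_umolL and ambient > 0:
        logger.warning(
            "ambient %s %.4g µmol/L at or below detection limit %.4g µmol/L; "
            "treated as zero in f15",
            substrate,
            ambient,
            ambient_detection_umolL,
        )
        ambient = 0.0
    if not include_ambient:
        ambient = 0.0

    ambient_pool_nmol = ambient * liquid_volume_L * 1000.0
    total = added_nmol + ambient_pool_nmol
    if total == 0:
        raise DomainError("substrate pool is empty: no tracer and no ambient")
    f15 = (
        added_nmol * purity_fraction
        + ambient_pool_nmol * c.natural_atom_fraction
    ) / total
    return TracerSpec(
        substrate=substrate,
        added_nmol=added_nmol,
        purity_fraction=purity_fraction,
        ambient_umolL=ambient,
        liquid_volume_L=liquid_volume_L,
        f15=f15,
    )
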
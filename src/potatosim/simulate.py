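"""Daily potential-yield simulation (LINTUL / Solanum scheme).

The loop is the classic light-interception-and-utilization chain run on a
daily time step from crop emergence to physiological maturity:

    thermal time  →  canopy cover (beta function)
                  →  intercepted PAR (par_fraction × SR × cover)
                  →  dry biomass (RUE × cumulative IPAR)
                  →  tuber dry mass (Gompertz harvest index × biomass)
                  →  fresh tuber yield (dry mass / dry-matter fraction)

Potential production only: no water, nitrogen or frost limitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import (
    CanopyParameters,
    PartitionParameters,
    beta_canopy,
    gompertz_partition,
)
from .weather import (
    DEFAULT_BASE_TEMPERATURE,
    DailyWeather,
    MonthlyClimate,
    disaggregate_monthly,
    thermal_time,
)

__all__ = [
    "CropParameters",
    "Phenology",
    "SimulationResult",
    "daily_par",
    "cumulative_ipar",
    "harvest_index",
    "simulate",
    "potential_yield",
    "GM2_TO_T_HA",
    "DEFAULT_PAR_FRACTION",
    "DEFAULT_DRY_MATTER_FRACTION",
]

#: g·m⁻² → t·ha⁻¹.
GM2_TO_T_HA = 0.01
#: PAR as a fraction of total solar radiation.
DEFAULT_PAR_FRACTION = 0.5
#: Tuber dry-matter content used to convert dry to fresh yield.  Fresh
#: yield scales inversely with this value; override per cultivar if known.
DEFAULT_DRY_MATTER_FRACTION = 0.20


@dataclass(frozen=True)
class CropParameters:
    """Full Solanum parameter vector for one genotype × season."""

    canopy: CanopyParameters
    partition: PartitionParameters
    rue: float  # g dry mass per MJ intercepted PAR
    dry_matter_fraction: float = DEFAULT_DRY_MATTER_FRACTION
    base_temperature: float = DEFAULT_BASE_TEMPERATURE

    def __post_init__(self) -> None:
        if self.rue < 0:
            raise ValueError(f"rue must be non-negative, got {self.rue}")
        if not (0 < self.dry_matter_fraction < 1):
            raise ValueError(
                f"dry_matter_fraction must be in (0, 1), got {self.dry_matter_fraction}"
            )

    def to_dict(self) -> dict:
        return {
            "wmax": self.canopy.wmax,
            "tm": self.canopy.tm,
            "te": self.canopy.te,
            "a_max": self.partition.a_max,
            "tu": self.partition.tu,
            "b": self.partition.b,
            "rue": self.rue,
            "dry_matter_fraction": self.dry_matter_fraction,
            "base_temperature": self.base_temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropParameters":
        return cls(
            canopy=CanopyParameters(d["wmax"], d["tm"], d["te"]),
            partition=PartitionParameters(d["a_max"], d["tu"], d["b"]),
            rue=d["rue"],
            dry_matter_fraction=d.get("dry_matter_fraction", DEFAULT_DRY_MATTER_FRACTION),
            base_temperature=d.get("base_temperature", DEFAULT_BASE_TEMPERATURE),
        )

    @classmethod
    def from_json(cls, path) -> "CropParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Phenology:
    """Crop calendar: emergence and maturity as day indices since sowing."""

    emergence_day: int
    maturity_day: int
    senescence_day: int | None = None  # onset of linear canopy decline

    def __post_init__(self) -> None:
        if self.emergence_day > self.maturity_day:
            raise ValueError("emergence_day must not follow maturity_day")
        if self.senescence_day is not None and not (
            self.emergence_day < self.senescence_day <= self.maturity_day
        ):
            raise ValueError("senescence_day must lie in (emergence, maturity]")


@dataclass(frozen=True)
class SimulationResult:
    """Daily trajectories plus the final fresh tuber yield (t·ha⁻¹)."""

    trajectory: pd.DataFrame  # day, tt, cover, ipar, cum_ipar, biomass, hi, tuber_dm
    fresh_yield_t_ha: float
    final_biomass: float  # g·m⁻²
    final_tuber_dm: float  # g·m⁻²
    params: CropParameters

    def to_json(self, path) -> None:
        payload = {
            "fresh_yield_t_ha": self.fresh_yield_t_ha,
            "final_biomass_g_m2": self.final_biomass,
            "final_tuber_dm_g_m2": self.final_tuber_dm,
            "params": self.params.to_dict(),
            "trajectory": self.trajectory.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def daily_par(sr: float, par_fraction: float = DEFAULT_PAR_FRACTION) -> float:
    """Photosynthetically active radiation from total solar radiation."""
    if np.any(np.asarray(sr) < 0):
        raise ValueError("solar radiation must be non-negative")
    return par_fraction * sr


def cumulative_ipar(
    weather: Sequence[DailyWeather],
    cover_by_day: Sequence[float],
    par_fraction: float = DEFAULT_PAR_FRACTION,
) -> np.ndarray:
    """Cumulative intercepted PAR (MJ·m⁻²): Σ par_fraction · SR · cover.

    One PAR conversion is applied (``par_fraction``, default 0.5); the
    canopy cover fraction is the interception term.
    """
    cover = np.asarray(cover_by_day, dtype=float)
    if len(weather) != len(cover):
        raise ValueError(
            f"length mismatch: {len(weather)} weather days vs {len(cover)} cover values"
        )
    sr = np.array([w.sr for w in weather])
    return np.cumsum(daily_par(sr, par_fraction) * cover)


def harvest_index(tuber_dm: float, total_dm: float) -> float:
    """Harvest index: tuber dry mass over whole-plant dry mass."""
    if total_dm <= 0:
        raise ValueError("total dry mass must be positive")
    if tuber_dm < 0 or tuber_dm > total_dm:
        raise ValueError("tuber dry mass must lie in [0, total dry mass]")
    return tuber_dm / total_dm


def simulate(
    weather: Sequence[DailyWeather],
    params: CropParameters,
    emergence_day: int,
    maturity_day: int,
    senescence_day: int | None = None,
    par_fraction: float = DEFAULT_PAR_FRACTION,
    cover_modifier: Sequence[float] | None = None,
) -> SimulationResult:
    """Run the daily potential-yield loop from emergence to maturity.

    Thermal time accumulates from ``emergence_day``.  Canopy cover follows
    the beta function of thermal time, held at wmax past te; if
    ``senescence_day`` is given, cover declines linearly from that day to
    zero at maturity.  ``cover_modifier`` (per weather day, in [0, 1])
    scales the green cover — used e.g. to impose defoliation by disease.
    Biomass accumulates as RUE × daily intercepted PAR; tuber dry mass is
    the Gompertz harvest index times biomass; fresh yield converts the
    final tuber dry mass through the dry-matter fraction.
    """
    days = np.array([w.day for w in weather])
    if emergence_day > maturity_day:
        raise ValueError("emergence_day must not follow maturity_day")
    if emergence_day < days[0] or maturity_day > days[-1]:
        raise ValueError(
            f"growth window {emergence_day}..{maturity_day} outside weather days "
            f"{days[0]}..{days[-1]}"
        )
    tts = thermal_time(weather, params.base_temperature, origin_day=emergence_day)
    tt = tts.cumulative
    growing = (days >= emergence_day) & (days <= maturity_day)
    if emergence_day == maturity_day:
        # degenerate zero-length window: nothing is intercepted
        growing[:] = False
        tt = np.zeros_like(tt)

    cover = np.zeros(len(days))
    cover[growing] = beta_canopy(tt[growing], params.canopy)
    if senescence_day is not None:
        if not (emergence_day < senescence_day <= maturity_day):
            raise ValueError("senescence_day must lie in (emergence, maturity]")
        decline = (days > senescence_day) & growing
        frac = (maturity_day - days[decline]) / (maturity_day - senescence_day)
        cover[decline] *= np.clip(frac, 0.0, 1.0)
    if cover_modifier is not None:
        mod = np.asarray(cover_modifier, dtype=float)
        if len(mod) != len(days):
            raise ValueError("cover_modifier must have one value per weather day")
        cover *= np.clip(mod, 0.0, 1.0)

    sr = np.array([w.sr for w in weather])
    ipar = daily_par(sr, par_fraction) * cover
    ipar[~growing] = 0.0
    cum_ipar = np.cumsum(ipar)
    biomass = params.rue * cum_ipar
    hi = np.zeros(len(days))
    hi[growing] = gompertz_partition(tt[growing], params.partition)
    tuber = hi * biomass

    traj = pd.DataFrame(
        {
            "day": days,
            "tt": tt,
            "cover": cover,
            "ipar": ipar,
            "cum_ipar": cum_ipar,
            "biomass": biomass,
            "harvest_index": hi,
            "tuber_dm": tuber,
        }
    )
    end = int(np.searchsorted(days, maturity_day))
    final_biomass = float(biomass[end])
    final_tuber = float(tuber[end])
    fresh = final_tuber / params.dry_matter_fraction * GM2_TO_T_HA
    return SimulationResult(
        trajectory=traj,
        fresh_yield_t_ha=fresh,
        final_biomass=final_biomass,
        final_tuber_dm=final_tuber,
        params=params,
    )


def potential_yield(
    params: CropParameters,
    climate: MonthlyClimate,
    phenology: Phenology,
    days_per_month: int | Sequence[int] = 30,
    par_fraction: float = DEFAULT_PAR_FRACTION,
) -> float:
    """Potential fresh tuber yield (t·ha⁻¹) from a monthly climate.

    Convenience wrapper: disaggregate the climate to a daily series, run
    :func:`simulate` over the phenology window, return the final yield.
    """
    weather = disaggregate_monthly(climate, days_per_month)
    result = simulate(
        weather,
        params,
        phenology.emergence_day,
        phenology.maturity_day,
        senescence_day=phenology.senescence_day,
        par_fraction=par_fraction,
    )
    return result.fresh_yield_t_ha
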
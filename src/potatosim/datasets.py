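"""Packaged reference data from the Yunnan potato field study.

Three seasonal monthly climates (spring, autumn, early_spring) recorded
at the trial sites, and the fitted Solanum parameter sets for the three
assessed cultivars in each season, with their phenology and the seasonal
actual farm yields used in the yield-gap analysis.
"""

from __future__ import annotations

import json
from importlib import resources

import yaml

from .growth import CanopyParameters, PartitionParameters
from .simulate import CropParameters, Phenology
from .weather import MonthRecord, MonthlyClimate
from .yieldgap import SeasonYieldRecord

__all__ = [
    "SEASONS",
    "load_climate",
    "load_crop_table",
    "load_crop_parameters",
    "load_phenology",
    "load_actual_yield",
    "load_yield_records",
]

SEASONS = ("spring", "autumn", "early_spring")


def _data_text(name: str) -> str:
    return resources.files("potatosim.data").joinpath(name).read_text()


def load_climate(season: str) -> MonthlyClimate:
    """Monthly climate for one growing season of the field study."""
    table = yaml.safe_load(_data_text("yunnan_climate.yaml"))
    if season not in table:
        raise KeyError(f"unknown season {season!r}; choose from {sorted(table)}")
    months = tuple(
        MonthRecord(m["month"], m["tmax"], m["tmin"], m["rain"], m["sr"], m.get("snh"))
        for m in table[season]
    )
    return MonthlyClimate(season=season, months=months)


def load_crop_table() -> dict:
    """The raw genotype × season parameter table (dict form)."""
    return json.loads(_data_text("yunnan_crops.json"))


def load_crop_parameters(season: str, genotype: str) -> CropParameters:
    """Fitted CropParameters for one genotype in one season."""
    table = load_crop_table()
    g = table["seasons"][season]["genotypes"][genotype]
    return CropParameters(
        canopy=CanopyParameters(g["wmax"], g["tm"], g["te"]),
        partition=PartitionParameters(g["a_max"], g["tu"], g["b"]),
        rue=g["rue"],
        dry_matter_fraction=table["dry_matter_fraction"],
        base_temperature=table["base_temperature"],
    )


def load_phenology(season: str, genotype: str) -> Phenology:
    """Observed emergence/maturity (days after sowing) for one genotype."""
    g = load_crop_table()["seasons"][season]["genotypes"][genotype]
    return Phenology(g["emergence_day"], g["maturity_day"])


def load_actual_yield(season: str) -> float:
    """Seasonal actual farm yield (t·ha⁻¹) from regional surveys."""
    return float(load_crop_table()["seasons"][season]["actual_yield"])


def load_yield_records(use_reported: bool = True) -> list[SeasonYieldRecord]:
    """Season × genotype yield records for the gap analysis.

    With ``use_reported=True`` (default) the potential yields are the ones
    reported with the fitted parameter sets; the records carry the
    seasonal actual farm yield on every row.
    """
    table = load_crop_table()
    out = []
    for season, sdata in table["seasons"].items():
        for genotype, g in sdata["genotypes"].items():
            out.append(
                SeasonYieldRecord(
                    season=season,
                    genotype=genotype,
                    potential=g["reported_potential_yield"],
                    actual=sdata["actual_yield"],
                )
            )
    return out
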
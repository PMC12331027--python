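"""Seasonal yield-gap decomposition.

The yield gap of a season is the mean simulated potential yield across
genotypes minus the actual yield reported from farmers' fields.  Actual
yields are survey inputs, never simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeasonYieldRecord",
    "seasonal_mean_potential",
    "yield_gap",
    "gap_report",
    "read_records_csv",
]


@dataclass(frozen=True)
class SeasonYieldRecord:
    """Potential (and optionally actual) yield for one genotype × season."""

    season: str
    genotype: str
    potential: float  # t·ha⁻¹
    actual: float | None = None  # t·ha⁻¹, from farm surveys

    def __post_init__(self) -> None:
        if self.potential < 0:
            raise ValueError("potential yield must be non-negative")
        if self.actual is not None and self.actual < 0:
            raise ValueError("actual yield must be non-negative")


def read_records_csv(path) -> list[SeasonYieldRecord]:
    """Read records from a CSV with columns season,genotype,potential,actual."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        actual = row.get("actual")
        out.append(
            SeasonYieldRecord(
                season=str(row["season"]),
                genotype=str(row["genotype"]),
                potential=float(row["potential"]),
                actual=None if pd.isna(actual) else float(actual),
            )
        )
    return out


def seasonal_mean_potential(
    records: list[SeasonYieldRecord], season: str
) -> float:
    """Unweighted mean potential yield over the season's genotypes (t·ha⁻¹)."""
    vals = [r.potential for r in records if r.season == season]
    if not vals:
        raise ValueError(f"no records for season {season!r}")
    return float(np.mean(vals))


def yield_gap(potential: float, actual: float) -> float:
    """Yield gap = potential − actual (t·ha⁻¹); warns when negative."""
    if potential < 0 or actual < 0:
        raise ValueError("yields must be non-negative")
    gap = potential - actual
    if gap < 0:
        warnings.warn(
            f"actual yield ({actual}) exceeds potential ({potential}): negative gap",
            stacklevel=2,
        )
    return gap


def gap_report(
    records: list[SeasonYieldRecord], potential_decimals: int | None = 1
) -> pd.DataFrame:
    """Per-season table of mean potential, actual, gap and relative gap.

    The seasonal mean potential is rounded to ``potential_decimals``
    (default one decimal, the conventional t·ha⁻¹ reporting precision)
    before the gap is taken, so the table satisfies gap + actual =
    reported potential exactly.  Pass ``None`` to keep full precision.
    Per-season actual is the mean of the actual yields provided.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    seasons = list(dict.fromkeys(r.season for r in records))  # keep input order
    for season in seasons:
        pot = seasonal_mean_potential(records, season)
        if potential_decimals is not None:
            pot = round(pot, potential_decimals)
        actuals = [r.actual for r in records if r.season == season and r.actual is not None]
        actual = float(np.mean(actuals)) if actuals else np.nan
        gap = yield_gap(pot, actual) if not np.isnan(actual) else np.nan
        rel = gap / pot * 100.0 if pot > 0 and not np.isnan(gap) else np.nan
        rows.append(
            {
                "season": season,
                "mean_potential": pot,
                "actual": actual,
                "gap": gap,
                "relative_gap_pct": rel,
            }
        )
    return pd.DataFrame(rows)
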
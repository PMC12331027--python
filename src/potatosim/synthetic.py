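"""Synthetic field-trial generator.

No observation series are deposited with the study, so every pipeline
stage is exercised on generated data carrying the statistical structure
the analysis assumes: daily weather whose monthly aggregates match one of
the recorded seasonal climates, canopy-cover observations following the
beta function with additive Gaussian image-analysis error, destructive
biomass samples linear in cumulative intercepted PAR with multiplicative
log-normal error, Gompertz harvest-index trajectories, and paired
controlled/uncontrolled late-blight epidemics in which the uncontrolled
epidemic terminates light interception early (the mechanism by which the
disease removes yield).  The generating truth is recorded alongside the
data so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .estimate import BiomassSeries, CanopySeries, estimate_rue, fit_beta_canopy, fit_gompertz_hi
from .epidemics import DiseaseAssessment, YieldCurve
from .simulate import CropParameters, Phenology, simulate
from .weather import DailyWeather, MonthlyClimate, disaggregate_monthly, weather_to_frame

__all__ = ["SyntheticConfig", "SyntheticTrial", "generate_weather", "generate_trial",
           "recover_parameters", "write_trial"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Reproducible recipe for one synthetic trial.

    Noise defaults are date-level errors of the replicate means the field
    protocol records: each canopy observation is the mean of ~60 segmented
    photographs (sd 0.01), each harvest index the ratio from a 12-plant
    destructive sample (sd 0.015), each biomass total a replicate-plot
    mean (CV 5%), and severity a visual score (sd 2% absolute).  Sampling
    every 10 days matches the 10–15-day field cadence.  The default truth
    is the spring Yunshu 401 parameter set under the spring climate.
    """

    seed: int = 0
    season: str = "spring"
    genotype: str = "Yunshu 401"
    crop: CropParameters | None = None        # overrides the genotype lookup
    phenology: Phenology | None = None
    climate: MonthlyClimate | None = None     # overrides the season lookup
    days_per_month: int = 30
    cadence_days: int = 10
    canopy_sd: float = 0.01
    biomass_cv: float = 0.05
    hi_sd: float = 0.015
    severity_sd: float = 2.0
    weather_jitter_temp: float = 0.0   # daily sd, °C (monthly means preserved)
    weather_jitter_sr: float = 0.0     # daily sd, MJ·m⁻²·d⁻¹
    epidemic_onset_day: int | None = None  # default: 60% through the growth window
    epidemic_rate: float = 0.15            # logistic severity rate, d⁻¹
    controlled_max_severity: float = 5.0   # % cap under fungicide control
    controlled_onset_delay: int = 20       # days the controlled epidemic lags

    def __post_init__(self) -> None:
        for name in ("canopy_sd", "biomass_cv", "hi_sd", "severity_sd",
                     "weather_jitter_temp", "weather_jitter_sr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolve(self) -> tuple[MonthlyClimate, CropParameters, Phenology]:
        climate = self.climate or datasets.load_climate(self.season)
        crop = self.crop or datasets.load_crop_parameters(self.season, self.genotype)
        phen = self.phenology or datasets.load_phenology(self.season, self.genotype)
        return climate, crop, phen


@dataclass(frozen=True)
class SyntheticTrial:
    """One generated trial plus the truth that produced it."""

    config: SyntheticConfig
    weather: list[DailyWeather]
    canopy: CanopySeries
    hi_series: np.ndarray            # (tt, harvest index) pairs
    biomass: BiomassSeries
    ipar_cumulative: pd.Series       # clean cumulative IPAR by day
    yield_controlled: YieldCurve
    yield_uncontrolled: YieldCurve
    disease_controlled: DiseaseAssessment
    disease_uncontrolled: DiseaseAssessment
    truth: dict


def generate_weather(config: SyntheticConfig) -> list[DailyWeather]:
    """Daily weather consistent with the configured monthly climate.

    With zero jitter each day simply carries its month's values (monthly
    re-aggregation is exact).  With jitter, daily Gaussian perturbations
    are re-centered within each month so monthly mean temperatures and
    radiation are still reproduced exactly, and monthly rainfall is
    redistributed across days by a Dirichlet draw conserving the total.
    """
    climate, _, _ = config.resolve()
    base = disaggregate_monthly(climate, config.days_per_month)
    if config.weather_jitter_temp == 0 and config.weather_jitter_sr == 0:
        return base
    rng = np.random.default_rng(config.seed)
    out: list[DailyWeather] = []
    i = 0
    for rec in climate.months:
        n = config.days_per_month
        dtemp = rng.normal(0, config.weather_jitter_temp, n)
        dtemp -= dtemp.mean()  # same shift on tmax and tmin keeps tmax >= tmin
        dsr = rng.normal(0, config.weather_jitter_sr, n)
        dsr -= dsr.mean()
        rain_w = rng.dirichlet(np.full(n, 2.0)) * rec.rain
        for j in range(n):
            w = base[i + j]
            out.append(
                DailyWeather(
                    w.day,
                    w.tmax + dtemp[j],
                    w.tmin + dtemp[j],
                    max(w.sr + dsr[j], 0.0),
                    rain_w[j],
                )
            )
        i += n
    return out


def _severity_curves(config: SyntheticConfig, days: np.ndarray, phen: Phenology):
    """True severity (%) for uncontrolled and controlled treatments."""
    onset = config.epidemic_onset_day
    if onset is None:
        onset = phen.emergence_day + int(0.6 * (phen.maturity_day - phen.emergence_day))
    sev_u = 100.0 / (1.0 + np.exp(-config.epidemic_rate * (days - onset)))
    sev_c = config.controlled_max_severity / (
        1.0 + np.exp(-config.epidemic_rate * (days - onset - config.controlled_onset_delay))
    )
    return sev_u, sev_c, onset


def generate_trial(config: SyntheticConfig) -> SyntheticTrial:
    """Generate one complete trial (all series) with recorded truth."""
    climate, crop, phen = config.resolve()
    weather = generate_weather(config)
    rng = np.random.default_rng((config.seed, 1))
    days = np.array([w.day for w in weather])

    clean = simulate(weather, crop, phen.emergence_day, phen.maturity_day,
                     senescence_day=phen.senescence_day)
    traj = clean.trajectory.set_index("day")

    # --- observation series at the sampling cadence, post emergence ---
    obs_days = np.arange(phen.emergence_day, phen.maturity_day + 1, config.cadence_days)
    tt_obs = traj.loc[obs_days, "tt"].to_numpy()
    cover_true = traj.loc[obs_days, "cover"].to_numpy()
    cover_obs = np.clip(cover_true + rng.normal(0, config.canopy_sd, len(obs_days)), 0.0, 1.0)
    canopy = CanopySeries(tt_obs, cover_obs)

    hi_true = traj.loc[obs_days, "harvest_index"].to_numpy()
    hi_obs = np.clip(hi_true + rng.normal(0, config.hi_sd, len(obs_days)), 0.0, 1.0)
    hi_series = np.column_stack([tt_obs, hi_obs])

    sigma = np.sqrt(np.log1p(config.biomass_cv**2))
    total_true = traj.loc[obs_days, "biomass"].to_numpy()
    total_obs = total_true * rng.lognormal(0.0, sigma, len(obs_days)) if sigma > 0 else total_true
    tuber_obs = hi_obs * total_obs
    biomass = BiomassSeries(obs_days, total_obs, tuber_obs)
    ipar_cum = pd.Series(traj["cum_ipar"].to_numpy(), index=traj.index)

    # --- paired epidemics: severity truncates light interception ---
    sev_u, sev_c, onset = _severity_curves(config, days, phen)
    run_u = simulate(weather, crop, phen.emergence_day, phen.maturity_day,
                     senescence_day=phen.senescence_day,
                     cover_modifier=1.0 - sev_u / 100.0)
    run_c = simulate(weather, crop, phen.emergence_day, phen.maturity_day,
                     senescence_day=phen.senescence_day,
                     cover_modifier=1.0 - sev_c / 100.0)

    season_days = np.arange(days[0], days[-1] + 1, config.cadence_days)
    # cumulative yield holds its final value once the crop is mature
    lookup_days = np.minimum(season_days, phen.maturity_day)
    to_t_ha = 0.01 / crop.dry_matter_fraction
    yc = YieldCurve(config.genotype, "controlled", season_days,
                    run_c.trajectory.set_index("day").loc[lookup_days, "tuber_dm"].to_numpy() * to_t_ha)
    yu = YieldCurve(config.genotype, "uncontrolled", season_days,
                    run_u.trajectory.set_index("day").loc[lookup_days, "tuber_dm"].to_numpy() * to_t_ha)

    sev_days = season_days
    idx = sev_days - days[0]
    dc = DiseaseAssessment(
        config.genotype, "controlled", sev_days,
        np.clip(sev_c[idx] + rng.normal(0, config.severity_sd, len(sev_days)), 0.0, 100.0))
    du = DiseaseAssessment(
        config.genotype, "uncontrolled", sev_days,
        np.clip(sev_u[idx] + rng.normal(0, config.severity_sd, len(sev_days)), 0.0, 100.0))

    truth = {
        "wmax": crop.canopy.wmax, "tm": crop.canopy.tm, "te": crop.canopy.te,
        "a_max": crop.partition.a_max, "tu": crop.partition.tu, "b": crop.partition.b,
        "rue": crop.rue,
        "dry_matter_fraction": crop.dry_matter_fraction,
        "emergence_day": phen.emergence_day, "maturity_day": phen.maturity_day,
        "epidemic_onset_day": int(onset),
        "clean_fresh_yield_t_ha": clean.fresh_yield_t_ha,
        "controlled_fresh_yield_t_ha": run_c.fresh_yield_t_ha,
        "uncontrolled_fresh_yield_t_ha": run_u.fresh_yield_t_ha,
    }
    return SyntheticTrial(
        config=config, weather=weather, canopy=canopy, hi_series=hi_series,
        biomass=biomass, ipar_cumulative=ipar_cum,
        yield_controlled=yc, yield_uncontrolled=yu,
        disease_controlled=dc, disease_uncontrolled=du, truth=truth,
    )


def recover_parameters(trial: SyntheticTrial) -> dict:
    """Refit all seven model parameters from a trial's observation series.

    Returns the estimates keyed like the trial's truth dict (wmax, tm, te,
    a_max, tu, b, rue) so recovery error can be scored directly.
    """
    beta_fit = fit_beta_canopy(trial.canopy)
    gomp_fit = fit_gompertz_hi(trial.hi_series)
    rue_est = estimate_rue(trial.biomass, trial.ipar_cumulative)
    out = {}
    if beta_fit.converged and beta_fit.params is not None:
        out.update(wmax=beta_fit.params.wmax, tm=beta_fit.params.tm, te=beta_fit.params.te)
    if gomp_fit.converged and gomp_fit.params is not None:
        out.update(a_max=gomp_fit.params.a_max, tu=gomp_fit.params.tu, b=gomp_fit.params.b)
    out["rue"] = rue_est.rue
    return out


def write_trial(trial: SyntheticTrial, outdir) -> None:
    """Write a trial as plain CSVs plus a truth.json manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weather_to_frame(trial.weather).to_csv(outdir / "weather.csv", index=False)
    pd.DataFrame({"tt": trial.canopy.x, "cover": trial.canopy.cover}).to_csv(
        outdir / "canopy.csv", index=False)
    pd.DataFrame({"tt": trial.hi_series[:, 0], "harvest_index": trial.hi_series[:, 1]}).to_csv(
        outdir / "harvest_index.csv", index=False)
    pd.DataFrame({"day": trial.biomass.day, "total_dm": trial.biomass.total_dm,
                  "tuber_dm": trial.biomass.tuber_dm}).to_csv(outdir / "biomass.csv", index=False)
    rows = []
    for a in (trial.disease_controlled, trial.disease_uncontrolled):
        for t, s in zip(a.t, a.severity):
            rows.append({"genotype": a.genotype, "treatment": a.treatment,
                         "day": t, "severity_pct": s})
    pd.DataFrame(rows).to_csv(outdir / "severity.csv", index=False)
    rows = []
    for c in (trial.yield_controlled, trial.yield_uncontrolled):
        for d, y in zip(c.day, c.yield_):
            rows.append({"genotype": c.genotype, "treatment": c.treatment,
                         "day": d, "yield": y})
    pd.DataFrame(rows).to_csv(outdir / "yield_curves.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(trial.truth, fh, indent=2)
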
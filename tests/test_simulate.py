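import numpy as np
import pytest

from potatosim import datasets
from potatosim.growth import CanopyParameters, PartitionParameters
from potatosim.simulate import (
    CropParameters,
    Phenology,
    cumulative_ipar,
    daily_par,
    harvest_index,
    potential_yield,
    simulate,
)
from potatosim.weather import DailyWeather

# Golden simulated yields for the nine packaged parameter sets under the
# packaged climates (30 d/month, Tb=2, DM fraction 0.2), pinned from the
# first computation as a regression guard.
GOLDEN_YIELDS = {
    ("spring", "Yunshu 401"): 144.83,
    ("spring", "Yunshu 505"): 123.74,
    ("spring", "Cooperation 88"): 121.95,
    ("autumn", "Yunshu 401"): 36.39,
    ("autumn", "Yunshu 505"): 54.83,
    ("autumn", "Cooperation 88"): 71.93,
    ("early_spring", "Yunshu 401"): 49.52,
    ("early_spring", "Yunshu 505"): 54.68,
    ("early_spring", "Cooperation 88"): 41.76,
}


def _const_weather(n, sr=20.0, tmax=20.0, tmin=10.0):
    return [DailyWeather(i + 1, tmax, tmin, sr, 0.0) for i in range(n)]


def _saturating_crop(rue=3.0, dmf=0.2):
    """Canopy and partition saturate after the first day: cover=1, HI=1."""
    return CropParameters(
        canopy=CanopyParameters(1.0, 0.0, 1.0),
        partition=PartitionParameters(1.0, 1e-3, 1e-3),
        rue=rue,
        dry_matter_fraction=dmf,
        base_temperature=2.0,
    )


class TestRadiationOps:
    def test_daily_par_is_half(self):
        assert daily_par(20.0) == 10.0
        assert daily_par(0.0) == 0.0
        assert daily_par(15.2) == pytest.approx(7.6)

    def test_daily_par_rejects_negative(self):
        with pytest.raises(ValueError):
            daily_par(-1.0)

    def test_cumulative_ipar_full_cover(self):
        w = _const_weather(10)
        out = cumulative_ipar(w, np.ones(10))
        assert out[-1] == pytest.approx(100.0)
        assert np.all(np.diff(out) >= 0)

    def test_cumulative_ipar_no_interception(self):
        assert cumulative_ipar(_const_weather(5), np.zeros(5))[-1] == 0.0

    def test_cumulative_ipar_linearity(self):
        assert cumulative_ipar(_const_weather(4), np.full(4, 0.5))[-1] == pytest.approx(20.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cumulative_ipar(_const_weather(4), np.ones(5))


class TestHarvestIndex:
    def test_ratio(self):
        assert harvest_index(82.0, 100.0) == pytest.approx(0.82)
        assert harvest_index(0.0, 50.0) == 0.0
        assert harvest_index(50.0, 50.0) == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            harvest_index(1.0, 0.0)
        with pytest.raises(ValueError):
            harvest_index(60.0, 50.0)


class TestSimulate:
    def test_closed_form_constant_weather(self):
        res = simulate(_const_weather(100), _saturating_crop(), 1, 100)
        assert res.final_biomass == pytest.approx(3000.0)
        assert res.fresh_yield_t_ha == pytest.approx(150.0)

    def test_null_model_zero_rue(self):
        res = simulate(_const_weather(50), _saturating_crop(rue=0.0), 1, 50)
        assert res.final_biomass == 0.0
        assert res.fresh_yield_t_ha == 0.0

    def test_biomass_equals_rue_times_ipar_exactly(self, crop_sets, climates):
        from potatosim.weather import disaggregate_monthly

        crop, phen = crop_sets[("autumn", "Yunshu 505")]
        weather = disaggregate_monthly(climates["autumn"], 30)
        res = simulate(weather, crop, phen.emergence_day, phen.maturity_day)
        final_cum_ipar = res.trajectory["cum_ipar"].iloc[-1]
        assert res.trajectory["biomass"].iloc[-1] == pytest.approx(
            crop.rue * final_cum_ipar, rel=1e-12
        )

    def test_fresh_yield_unit_round_trip(self):
        res = simulate(_const_weather(60), _saturating_crop(dmf=0.25), 1, 60)
        assert res.fresh_yield_t_ha * 0.25 / 0.01 == pytest.approx(res.final_tuber_dm)

    def test_tuber_never_exceeds_biomass(self, crop_sets, climates):
        from potatosim.weather import disaggregate_monthly

        crop, phen = crop_sets[("spring", "Yunshu 401")]
        weather = disaggregate_monthly(climates["spring"], 30)
        res = simulate(weather, crop, phen.emergence_day, phen.maturity_day)
        traj = res.trajectory
        assert np.all(traj["tuber_dm"] <= traj["biomass"] + 1e-9)
        assert np.all(np.diff(traj["biomass"]) >= -1e-12)
        assert np.all((traj["harvest_index"] >= 0) & (traj["harvest_index"] <= 1))

    def test_window_validation(self):
        with pytest.raises(ValueError):
            simulate(_const_weather(10), _saturating_crop(), 5, 20)
        with pytest.raises(ValueError):
            simulate(_const_weather(10), _saturating_crop(), 8, 3)

    def test_zero_length_window_zero_yield(self):
        res = simulate(_const_weather(10), _saturating_crop(), 5, 5)
        assert res.fresh_yield_t_ha == 0.0

    def test_senescence_reduces_yield(self):
        full = simulate(_const_weather(100), _saturating_crop(), 1, 100)
        sen = simulate(_const_weather(100), _saturating_crop(), 1, 100, senescence_day=50)
        assert sen.fresh_yield_t_ha < full.fresh_yield_t_ha


class TestPotentialYield:
    def test_golden_yields_pinned(self, crop_sets, climates):
        for (season, genotype), expected in GOLDEN_YIELDS.items():
            crop, phen = crop_sets[(season, genotype)]
            y = potential_yield(crop, climates[season], phen)
            assert y == pytest.approx(expected, abs=0.01), (season, genotype)

    def test_autumn_rank_matches_reported(self, crop_sets, climates):
        """Reported autumn potential yields rank C88 > YS505 > YS401."""
        ys = {}
        for g in ("Yunshu 401", "Yunshu 505", "Cooperation 88"):
            crop, phen = crop_sets[("autumn", g)]
            ys[g] = potential_yield(crop, climates["autumn"], phen)
        assert ys["Cooperation 88"] > ys["Yunshu 505"] > ys["Yunshu 401"]

    def test_doubling_rue_doubles_yield(self, crop_sets, climates):
        crop, phen = crop_sets[("autumn", "Yunshu 401")]
        doubled = CropParameters(crop.canopy, crop.partition, 2 * crop.rue,
                                 crop.dry_matter_fraction, crop.base_temperature)
        y1 = potential_yield(crop, climates["autumn"], phen)
        y2 = potential_yield(doubled, climates["autumn"], phen)
        assert y2 == pytest.approx(2 * y1, rel=1e-12)

    def test_monotone_in_drivers(self, climates):
        """Yield is nondecreasing in RUE, wmax, a_max and season length."""
        base = dict(wmax=0.8, tm=300.0, te=1000.0, a_max=0.85, tu=700.0, b=250.0, rue=3.0)

        def make(**kw):
            d = {**base, **kw}
            return CropParameters(
                CanopyParameters(d["wmax"], d["tm"], d["te"]),
                PartitionParameters(d["a_max"], d["tu"], d["b"]),
                d["rue"],
            )

        clim = climates["spring"]
        phen = Phenology(40, 160)
        y0 = potential_yield(make(), clim, phen)
        for kw in ({"rue": 4.0}, {"wmax": 0.95}, {"a_max": 0.95}):
            assert potential_yield(make(**kw), clim, phen) >= y0
        assert potential_yield(make(), clim, Phenology(40, 190)) >= y0

    def test_phenology_validation(self):
        with pytest.raises(ValueError):
            Phenology(100, 50)
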
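import numpy as np
import pandas as pd
import pytest

from potatosim.estimate import (
    BiomassSeries,
    CanopySeries,
    days_to_one_percent_cover,
    estimate_rue,
    fit_beta_canopy,
    fit_gompertz_hi,
)
from potatosim.growth import (
    CanopyParameters,
    PartitionParameters,
    beta_canopy,
    gompertz_partition,
)


def _rel_err(a, b):
    return abs(a - b) / abs(b)


class TestFitBetaCanopy:
    TRUTH = CanopyParameters(0.92, 449.0, 1027.0)

    def _series(self, n, noise_sd=0.0, seed=0):
        tt = np.linspace(30, 1300, n)
        cover = beta_canopy(tt, self.TRUTH)
        if noise_sd:
            rng = np.random.default_rng(seed)
            cover = np.clip(cover + rng.normal(0, noise_sd, n), 0, 1)
        return CanopySeries(tt, cover)

    def test_noise_free_recovery(self):
        fit = fit_beta_canopy(self._series(15))
        assert fit.converged
        for got, want in [(fit.params.wmax, 0.92), (fit.params.tm, 449), (fit.params.te, 1027)]:
            assert _rel_err(got, want) < 1e-3

    def test_noisy_recovery_within_five_percent(self):
        fit = fit_beta_canopy(self._series(20, noise_sd=0.02, seed=7))
        assert fit.converged
        for got, want in [(fit.params.wmax, 0.92), (fit.params.tm, 449), (fit.params.te, 1027)]:
            assert _rel_err(got, want) < 0.05

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_canopy(self._series(3))

    def test_order_invariance(self):
        tt = np.array([100.0, 900.0, 300.0, 600.0, 1200.0])
        cover = beta_canopy(np.sort(tt), self.TRUTH)
        a = fit_beta_canopy(CanopySeries(np.sort(tt), cover))
        b = fit_beta_canopy(CanopySeries(tt, cover[np.argsort(np.argsort(tt))]))
        assert a.params == b.params


class TestFitGompertzHi:
    TRUTH = PartitionParameters(0.97, 545.0, 186.0)

    def _series(self, n, noise_sd=0.0, seed=0):
        tt = np.linspace(50, 1500, n)
        hi = gompertz_partition(tt, self.TRUTH)
        if noise_sd:
            rng = np.random.default_rng(seed)
            hi = np.clip(hi + rng.normal(0, noise_sd, n), 0, 1)
        return np.column_stack([tt, hi])

    def test_noise_free_recovery(self):
        fit = fit_gompertz_hi(self._series(15))
        assert fit.converged
        for got, want in [(fit.params.a_max, 0.97), (fit.params.tu, 545), (fit.params.b, 186)]:
            assert _rel_err(got, want) < 1e-3

    def test_noisy_recovery_within_five_percent(self):
        fit = fit_gompertz_hi(self._series(20, noise_sd=0.03, seed=11))
        assert fit.converged
        for got, want in [(fit.params.a_max, 0.97), (fit.params.tu, 545), (fit.params.b, 186)]:
            assert _rel_err(got, want) < 0.05

    def test_all_zero_flagged_not_fitted(self):
        series = np.column_stack([np.linspace(0, 1000, 8), np.zeros(8)])
        fit = fit_gompertz_hi(series)
        assert not fit.converged
        assert fit.params is None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_gompertz_hi(self._series(3))


class TestEstimateRue:
    def test_exact_slope_recovery(self):
        days = np.array([20, 40, 60, 80, 100, 120])
        ipar = pd.Series(np.arange(1, 131, dtype=float).cumsum(), index=np.arange(1, 131))
        biomass = BiomassSeries(days, 3.13 * ipar.loc[days].to_numpy(), np.zeros(6))
        est = estimate_rue(biomass, ipar)
        assert est.rue == pytest.approx(3.13, rel=1e-12)
        assert est.stderr == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_three_percent(self):
        rng = np.random.default_rng(5)
        days = np.arange(10, 130, 12)
        ipar = pd.Series(np.linspace(2, 8, 130).cumsum(), index=np.arange(1, 131))
        truth = 4.2
        y = truth * ipar.loc[days].to_numpy() * (1 + rng.normal(0, 0.05, len(days)))
        est = estimate_rue(BiomassSeries(days, y, np.zeros(len(days))), ipar)
        assert _rel_err(est.rue, truth) < 0.03

    def test_single_point_rejected(self):
        ipar = pd.Series([1.0, 2.0], index=[1, 2])
        with pytest.raises(ValueError):
            estimate_rue(BiomassSeries([1], [3.0], [0.0]), ipar)

    def test_missing_day_rejected(self):
        ipar = pd.Series([1.0, 2.0], index=[1, 2])
        with pytest.raises(ValueError, match="absent"):
            estimate_rue(BiomassSeries([1, 5], [1.0, 2.0], [0.0, 0.0]), ipar)

    def test_zero_variance_ipar_rejected(self):
        ipar = pd.Series([2.0, 2.0, 2.0], index=[1, 2, 3])
        with pytest.raises(ValueError, match="variance"):
            estimate_rue(BiomassSeries([1, 2, 3], [1.0, 1.1, 1.2], [0, 0, 0]), ipar)

    def test_intercept_mode(self):
        days = np.array([10, 20, 30, 40])
        ipar = pd.Series(np.arange(1.0, 51.0).cumsum(), index=np.arange(1, 51))
        x = ipar.loc[days].to_numpy()
        est = estimate_rue(BiomassSeries(days, 2.5 * x + 40.0, np.zeros(4)), ipar,
                           through_origin=False)
        assert est.rue == pytest.approx(2.5, rel=1e-9)
        assert est.intercept == pytest.approx(40.0, rel=1e-6)


class TestDaysToOnePercent:
    def test_exact_quadratic(self):
        day = np.arange(5, 31, dtype=float)
        series = CanopySeries(day, 1e-4 * day**2)
        assert days_to_one_percent_cover(series) == pytest.approx(10.0, abs=1e-9)

    def test_noisy_within_one_day(self):
        rng = np.random.default_rng(3)
        day = np.arange(5, 31, dtype=float)
        cover = np.clip(1e-4 * day**2 + rng.normal(0, 2e-4, len(day)), 0, 1)
        assert days_to_one_percent_cover(CanopySeries(day, cover)) == pytest.approx(10.0, abs=1.0)

    def test_all_above_threshold_rejected(self):
        day = np.arange(5.0, 10.0)
        with pytest.raises(ValueError, match="above the threshold"):
            days_to_one_percent_cover(CanopySeries(day, 0.2 + 0.01 * day))


class TestRoundTripAllParameterSets:
    def test_dense_noise_free_refit_reproduces_table(self, crop_sets):
        for (season, genotype), (crop, _) in crop_sets.items():
            tt = np.linspace(20, crop.canopy.te * 1.4, 40)
            cfit = fit_beta_canopy(CanopySeries(tt, beta_canopy(tt, crop.canopy)))
            assert cfit.converged, (season, genotype)
            assert _rel_err(cfit.params.wmax, crop.canopy.wmax) < 1e-3
            assert _rel_err(cfit.params.tm, crop.canopy.tm) < 1e-3
            assert _rel_err(cfit.params.te, crop.canopy.te) < 1e-3
            tt2 = np.linspace(20, crop.partition.tu + 4 * crop.partition.b, 40)
            gfit = fit_gompertz_hi(
                np.column_stack([tt2, gompertz_partition(tt2, crop.partition)])
            )
            assert gfit.converged, (season, genotype)
            assert _rel_err(gfit.params.a_max, crop.partition.a_max) < 1e-3
            assert _rel_err(gfit.params.tu, crop.partition.tu) < 1e-3
            assert _rel_err(gfit.params.b, crop.partition.b) < 1e-3
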
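"""Daily statistics, percentile baseline, and EHF arithmetic contracts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from heatexposure import (
    classify_severity,
    compute_ehf,
    compute_t95,
    daily_statistics,
    ehf_episode_map,
    generate_climatology,
    generate_temperature_cube,
    rolling_previous_mean,
)
from heatexposure.domain import TemperatureCube
from heatexposure.ehf import (
    SEVERITY_HIGH,
    SEVERITY_MASKED,
    SEVERITY_NONE,
    SEVERITY_POSITIVE,
    DailyStatistics,
    mean_over_dates,
    severity_summary,
)
from heatexposure.errors import (
    CoverageError,
    EmptyOutputError,
    ParameterError,
    SampleSizeError,
)


def _hourly_cube(fn, n_hours, surface):
    ts = pd.date_range("2012-07-01", periods=n_hours, freq="h")
    vals = np.broadcast_to(
        fn(np.arange(n_hours))[:, None, None], (n_hours, *surface.shape)
    ).astype(float)
    return TemperatureCube(ts, vals.copy(), surface)


class TestDailyStatistics:
    def test_constant_day(self, surface):
        cube = _hourly_cube(lambda h: np.full(h.shape, 30.0), 24, surface)
        daily = daily_statistics(cube)
        assert np.allclose(daily.tmax, 30) and np.allclose(daily.tmin, 30)
        assert np.allclose(daily.tmean, 30)

    def test_sinusoid_matches_exhaustive_scan(self, surface):
        fn = lambda h: 30 + 5 * np.sin(2 * np.pi * ((h % 24) - 9) / 24)
        cube = _hourly_cube(fn, 48, surface)
        daily = daily_statistics(cube)
        hours = fn(np.arange(24))
        assert daily.tmax[0, 0, 0] == pytest.approx(hours.max(), abs=1e-12)
        assert daily.tmin[0, 0, 0] == pytest.approx(hours.min(), abs=1e-12)
        assert daily.tmean[0, 0, 0] == pytest.approx(hours.mean(), abs=1e-12)
        assert (daily.tmin <= daily.tmean).all() and (daily.tmean <= daily.tmax).all()

    def test_incomplete_day_excluded(self, surface):
        cube = _hourly_cube(lambda h: h.astype(float), 47, surface)
        daily = daily_statistics(cube)
        assert len(daily.dates) == 1  # second day has 23 hours

    def test_no_complete_day_raises(self, surface):
        cube = _hourly_cube(lambda h: h.astype(float), 12, surface)
        with pytest.raises(EmptyOutputError):
            daily_statistics(cube)


class TestComputeT95:
    def test_linear_interpolation_1_to_100(self):
        clim = np.tile(np.arange(1.0, 101.0)[:, None, None], (1, 2, 2))
        baseline = compute_t95(clim)
        assert np.allclose(baseline.t95, 95.05)
        assert baseline.percentile_method == "linear"
        assert baseline.n_days == 100

    def test_constant_series(self):
        clim = np.full((30, 2, 2), 26.0)
        assert np.allclose(compute_t95(clim).t95, 26.0)

    def test_order_invariance(self, rng):
        clim = rng.normal(28, 3, size=(60, 3, 3))
        shuffled = clim[rng.permutation(60)]
        assert np.allclose(compute_t95(clim).t95, compute_t95(shuffled).t95)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        clim = rng.normal(28, 3, size=(41, 4, 4))
        t95 = compute_t95(clim).t95
        for r in range(4):
            for c in range(4):
                xs = np.sort(clim[:, r, c])
                h = 0.95 * (len(xs) - 1)
                lo = int(np.floor(h))
                oracle = xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])
                assert t95[r, c] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_samples_names_cell(self):
        with pytest.raises(SampleSizeError, match=r"\(0, 0\)"):
            compute_t95(np.zeros((10, 2, 2)))


class TestRollingPreviousMean:
    @staticmethod
    def _daily(values, start="2012-06-01"):
        values = np.asarray(values, dtype=float)[:, None, None]
        dates = pd.date_range(start, periods=len(values), freq="D")
        return DailyStatistics(dates=dates, tmax=values, tmin=values, tmean=values)

    def test_three_day_mean(self):
        daily = self._daily([30, 32, 34])
        t3 = rolling_previous_mean(daily, 3, "2012-06-03")
        assert t3[0, 0] == pytest.approx(32.0)

    def test_constant_thirty_day_mean(self):
        daily = self._daily([26.0] * 30)
        t30 = rolling_previous_mean(daily, 30, "2012-06-30")
        assert t30[0, 0] == pytest.approx(26.0)

    def test_missing_day_named(self):
        daily = self._daily([26.0] * 29)  # June 1-29; the 30-day window needs May 31
        with pytest.raises(CoverageError, match="2012-05-31"):
            rolling_previous_mean(daily, 30, "2012-06-29")

    def test_explicit_date_list(self):
        daily = self._daily([30, 32, 34, 40])
        t3 = mean_over_dates(daily, ["2012-06-01", "2012-06-02", "2012-06-03"])
        assert t3[0, 0] == pytest.approx(32.0)


class TestComputeEHF:
    @pytest.mark.parametrize(
        "t3, t95, t30, sig, accl, ehf",
        [
            (35.0, 30.0, 28.0, 5.0, 7.0, 35.0),
            (30.5, 28.5, 30.0, 2.0, 0.5, 2.0),  # MAX clamp active
            (28.0, 30.0, 27.0, -2.0, 1.0, -2.0),  # negative passes through
        ],
    )
    def test_worked_triples(self, t3, t95, t30, sig, accl, ehf):
        g = lambda v: np.full((2, 2), v)
        field = compute_ehf(g(t3), g(t30), g(t95))
        assert np.allclose(field.ehi_sig, sig)
        assert np.allclose(field.ehi_accl, accl)
        assert np.allclose(field.ehf, ehf)

    def test_water_mask_propagates(self):
        g = lambda v: np.full((2, 2), v)
        mask = np.array([[True, False], [False, False]])
        field = compute_ehf(g(35.0), g(28.0), g(30.0), water_mask=mask)
        assert np.isnan(field.ehf[0, 0])
        assert field.severity[0, 0] == SEVERITY_MASKED
        assert field.severity[1, 1] == SEVERITY_HIGH

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception, match="congruent"):
            compute_ehf(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))

    @given(
        t3=hnp.arrays(float, (3, 3), elements=st.floats(-10, 50)),
        t30=hnp.arrays(float, (3, 3), elements=st.floats(-10, 50)),
        t95=hnp.arrays(float, (3, 3), elements=st.floats(-10, 50)),
        bump=st.floats(0.01, 5.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_t3_and_clamp_identity(self, t3, t30, t95, bump):
        # EHF is non-decreasing in T3 wherever the significance index is
        # non-negative (d/dT3 = max(1, accl) + sig there); with sig < -accl
        # the product genuinely decreases, so the heat-risk region is the
        # domain of the monotonicity property.
        base = compute_ehf(t3, t30, t95)
        more = compute_ehf(t3 + bump, t30, t95)
        heat = base.ehi_sig >= 0
        assert (more.ehf[heat] >= base.ehf[heat] - 1e-9).all()
        clamped = base.ehi_accl <= 1.0
        assert np.allclose(base.ehf[clamped], base.ehi_sig[clamped])


class TestClassifySeverity:
    @pytest.mark.parametrize(
        "value, code",
        [(35.0, SEVERITY_HIGH), (-2.0, SEVERITY_NONE), (1.0, SEVERITY_POSITIVE),
         (0.0, SEVERITY_NONE), (2.0, SEVERITY_POSITIVE), (2.01, SEVERITY_HIGH)],
    )
    def test_thresholding(self, value, code):
        assert classify_severity(np.array([[value]]))[0, 0] == code

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            classify_severity(np.zeros((1, 1)), high_threshold=-1.0)


@pytest.fixture(scope="module")
def episode(surface):
    from heatexposure import SyntheticScenario

    scenario = SyntheticScenario(
        n_days=35, noise_sd=0.2, seed=12,
        climatology_years=3, climatology_days_per_year=40,
    )
    cube = generate_temperature_cube(surface, scenario)
    clim = generate_climatology(surface, scenario, "tmean")
    t3_dates = pd.date_range("2012-07-04", periods=3, freq="D")
    return scenario, cube, clim, list(t3_dates)


class TestEpisodeMap:
    def test_equals_manual_stage_composition(self, surface, episode):
        _, cube, clim, t3_dates = episode
        field = ehf_episode_map(cube, clim, t3_dates, "tmean")
        daily = daily_statistics(cube)
        t3 = mean_over_dates(daily, t3_dates, "tmean")
        t30 = rolling_previous_mean(daily, 30, "2012-07-03", "tmean")
        t95 = compute_t95(clim, "tmean").t95
        manual = compute_ehf(t3, t30, t95, water_mask=surface.water_mask)
        np.testing.assert_array_equal(field.ehf, manual.ehf)
        np.testing.assert_array_equal(field.severity, manual.severity)

    def test_water_masked_exactly(self, surface, episode):
        _, cube, clim, t3_dates = episode
        field = ehf_episode_map(cube, clim, t3_dates, "tmean")
        assert np.isnan(field.ehf[surface.water_mask]).all()
        assert not np.isnan(field.ehf[surface.land_mask]).any()
        assert (field.severity[surface.water_mask] == SEVERITY_MASKED).all()

    def test_heatwave_raises_ehf_above_null(self, surface, episode):
        scenario, cube, clim, t3_dates = episode
        field = ehf_episode_map(cube, clim, t3_dates, "tmean")
        # the pulse puts every land cell far above its climatology
        assert (field.ehi_sig[surface.land_mask] > 0).all()
        null_cube = generate_temperature_cube(
            surface, scenario.replace(hw_amplitude_rural=0.0, hw_amplitude_urban=0.0,
                                      seed=77)
        )
        null = ehf_episode_map(null_cube, clim, t3_dates, "tmean")
        assert np.median(null.ehf[surface.land_mask]) <= 0.0

    def test_nonconsecutive_t3_dates_rejected(self, episode):
        _, cube, clim, _ = episode
        with pytest.raises(ParameterError, match="consecutive"):
            ehf_episode_map(cube, clim, ["2012-07-04", "2012-07-06"], "tmean")

    def test_summary_counts_land_cells(self, surface, episode):
        _, cube, clim, t3_dates = episode
        field = ehf_episode_map(cube, clim, t3_dates, "tmean")
        summary = severity_summary(field)
        assert summary["n_cells"].sum() == int(surface.land_mask.sum())
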
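import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habshift.bioclim import (ExtremeDef, ThresholdRegistry, absolute_humidity,
                              annual_predictors, climatological_stack,
                              compute_ahum, compute_bios, compute_exvs,
                              default_registry, longest_run)
from habshift.grid import GridSpec
from habshift.synthetic import climate_cube_from_arrays, generate_landuse

TOY_GRID = GridSpec(0, 2, 0, 2, 1.0)


def _constant_cube(year=2001, tmean=15.0, precip=2.0, dewpoint=10.0,
                   tmin=None, tmax=None):
    time = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(time)
    return climate_cube_from_arrays(
        TOY_GRID, time,
        tmean=np.full(n, tmean),
        tmin=np.full(n, tmean if tmin is None else tmin),
        tmax=np.full(n, tmean if tmax is None else tmax),
        precip=np.full(n, precip),
        dewpoint=np.full(n, dewpoint),
    )


def _monthly_oracle(series: pd.Series, how: str) -> np.ndarray:
    """Independent monthly aggregation for the quarter brute force."""
    grouped = series.groupby(series.index.month)
    return (grouped.mean() if how == "mean" else grouped.sum()).values


def _quarter_oracle(monthly: np.ndarray, how: str) -> np.ndarray:
    vals = []
    for i in range(12):
        window = [monthly[(i + k) % 12] for k in range(3)]
        vals.append(np.mean(window) if how == "mean" else np.sum(window))
    return np.array(vals)


class TestBios:
    def test_constant_climate_identities(self):
        cube = _constant_cube()
        bios = compute_bios(cube, 2001)
        cell = (0, 0)
        assert bios["BIO1"][cell] == pytest.approx(15.0)
        assert bios["BIO2"][cell] == pytest.approx(0.0)
        assert bios["BIO4"][cell] == pytest.approx(0.0)
        assert bios["BIO7"][cell] == pytest.approx(0.0)
        assert bios["BIO3"][cell] == pytest.approx(0.0)  # degenerate BIO7=0
        assert bios["BIO12"][cell] == pytest.approx(730.0)  # 365 x 2 mm

    def test_leap_year_annual_precip(self):
        cube = _constant_cube(year=2000)
        bios = compute_bios(cube, 2000)
        assert bios["BIO12"][0, 0] == pytest.approx(732.0)

    def test_sinusoid_construction(self):
        year = 2001
        time = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = time.dayofyear.values
        tmean = 10.0 + 8.0 * np.sin(2 * np.pi * doy / 365.0)
        cube = climate_cube_from_arrays(
            TOY_GRID, time, tmean=tmean, tmin=tmean - 1, tmax=tmean + 1,
            precip=np.ones(len(time)), dewpoint=tmean - 5)
        bios = compute_bios(cube, year)
        assert bios["BIO2"][0, 0] == pytest.approx(2.0, abs=1e-5)
        monthly_mean = _monthly_oracle(pd.Series(tmean, index=time), "mean")
        assert bios["BIO5"][0, 0] == pytest.approx(monthly_mean.max() + 1.0,
                                                   abs=1e-5)
        assert bios["BIO6"][0, 0] == pytest.approx(monthly_mean.min() - 1.0,
                                                   abs=1e-5)

    def test_bio8_brute_force_toy_series(self):
        # printed 12-month toy series: wettest quarter must be found by
        # exhaustive enumeration of all 12 wrap-around windows
        t_monthly = [0, 2, 5, 9, 14, 18, 22, 21, 16, 10, 5, 1]
        p_monthly = [50, 40, 35, 30, 25, 20, 60, 80, 55, 45, 70, 65]
        year = 2001
        time = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        month = time.month.values
        days_in_month = np.array([(month == m).sum() for m in range(1, 13)])
        tmean = np.array([t_monthly[m - 1] for m in month], dtype=float)
        precip = np.array([p_monthly[m - 1] / days_in_month[m - 1]
                           for m in month])
        cube = climate_cube_from_arrays(
            TOY_GRID, time, tmean=tmean, tmin=tmean, tmax=tmean,
            precip=precip, dewpoint=tmean - 5)
        bios = compute_bios(cube, year)

        q_prec = _quarter_oracle(np.array(p_monthly, dtype=float), "sum")
        q_temp = _quarter_oracle(np.array(t_monthly, dtype=float), "mean")
        expected_bio8 = q_temp[np.argmax(q_prec)]
        assert bios["BIO8"][0, 0] == pytest.approx(expected_bio8, abs=1e-6)
        assert bios["BIO9"][0, 0] == pytest.approx(q_temp[np.argmin(q_prec)],
                                                   abs=1e-6)
        assert bios["BIO18"][0, 0] == pytest.approx(q_prec[np.argmax(q_temp)],
                                                    abs=1e-3)

    def test_quarter_bios_match_exhaustive_oracle(self, climate_small):
        bios = compute_bios(climate_small, 2000)
        sel = climate_small.sel(time=slice("2000-01-01", "2000-12-31"))
        time = pd.DatetimeIndex(sel.time.values)
        for i, j in [(0, 0), (7, 13), (19, 19)]:
            t_m = _monthly_oracle(
                pd.Series(sel.tmean.values[:, i, j], index=time), "mean")
            p_m = _monthly_oracle(
                pd.Series(sel.precip.values[:, i, j], index=time), "sum")
            q_t = _quarter_oracle(t_m, "mean")
            q_p = _quarter_oracle(p_m, "sum")
            assert bios["BIO8"][i, j] == pytest.approx(q_t[np.argmax(q_p)],
                                                       abs=1e-4)
            assert bios["BIO9"][i, j] == pytest.approx(q_t[np.argmin(q_p)],
                                                       abs=1e-4)
            assert bios["BIO10"][i, j] == pytest.approx(q_t.max(), abs=1e-4)
            assert bios["BIO11"][i, j] == pytest.approx(q_t.min(), abs=1e-4)
            assert bios["BIO16"][i, j] == pytest.approx(q_p.max(), abs=1e-2)
            assert bios["BIO17"][i, j] == pytest.approx(q_p.min(), abs=1e-2)

    def test_bio_identities(self, climate_small):
        bios = compute_bios(climate_small, 1995)
        np.testing.assert_allclose(bios["BIO7"], bios["BIO5"] - bios["BIO6"],
                                   atol=1e-6)
        ok = bios["BIO7"] > 0
        np.testing.assert_allclose(bios["BIO3"][ok],
                                   100 * bios["BIO2"][ok] / bios["BIO7"][ok],
                                   atol=1e-6)
        assert (bios["BIO16"] >= bios["BIO17"]).all()
        assert (bios["BIO10"] >= bios["BIO11"]).all()

    def test_incomplete_year_rejected(self, climate_small):
        with pytest.raises(ValueError):
            compute_bios(climate_small, 2003)   # cube ends in 2002


class TestExvs:
    def test_no_qualifying_days(self):
        cube = _constant_cube(tmean=10.0)
        reg = ThresholdRegistry((
            ExtremeDef("ND_cold", "tmean", "<", 0.0, "ND"),
            ExtremeDef("LP_cold", "tmean", "<", 0.0, "LP"),
        ))
        out = compute_exvs(cube, 2001, reg)
        assert out["ND_cold"][0, 0] == 0
        assert out["LP_cold"][0, 0] == 0

    def test_crafted_run_positions(self):
        year = 2001
        time = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        tmean = np.full(len(time), 5.0)
        tmean[10:15] = -2.0    # run of 5
        tmean[100] = -2.0      # isolated day
        cube = climate_cube_from_arrays(
            TOY_GRID, time, tmean=tmean, tmin=tmean, tmax=tmean,
            precip=np.zeros(len(time)), dewpoint=tmean - 5)
        reg = ThresholdRegistry((
            ExtremeDef("ND_cold", "tmean", "<", 0.0, "ND"),
            ExtremeDef("LP_cold", "tmean", "<", 0.0, "LP"),
        ))
        out = compute_exvs(cube, year, reg)
        assert out["ND_cold"][0, 0] == 6
        assert out["LP_cold"][0, 0] == 5

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_longest_run_matches_brute_force(self, flags):
        mask = np.asarray(flags, dtype=bool)[:, None]
        # brute force: enumerate every run
        best = cur = 0
        for f in flags:
            cur = cur + 1 if f else 0
            best = max(best, cur)
        assert longest_run(mask)[0] == best

    def test_bounds_lp_le_nd_le_days(self, climate_small, registry):
        out = compute_exvs(climate_small, 2000, registry)
        nd = {e.name: out[e.name] for e in registry if e.statistic == "ND"}
        lp = {e.name: out[e.name] for e in registry if e.statistic == "LP"}
        for name, arr in {**nd, **lp}.items():
            assert (arr >= 0).all() and (arr <= 366).all()
        for e in registry:
            if e.statistic == "LP":
                partner = [f for f in registry if f.statistic == "ND"
                           and (f.variable, f.comparator, f.threshold)
                           == (e.variable, e.comparator, e.threshold)]
                if partner:
                    assert (out[e.name] <= out[partner[0].name]).all()

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            ExtremeDef("bad", "wind", ">", 1.0, "ND")

    def test_default_registry_has_18_entries(self, registry):
        assert len(registry) == 18


class TestAhum:
    def test_warm_dewpoint_oracle(self):
        # independent oracle: alternative Magnus fit (17.67 / 243.5)
        dp = 20.0
        e_hpa = 6.112 * np.exp(17.67 * dp / (dp + 243.5))
        expected = 1000.0 * 100.0 * e_hpa / (461.5 * (dp + 273.15))
        assert absolute_humidity(20.0) == pytest.approx(expected, rel=0.01)
        assert absolute_humidity(20.0) == pytest.approx(17.3, abs=0.3)

    def test_very_cold_dewpoint(self):
        assert absolute_humidity(-40.0) < 0.2

    def test_monotone_in_dewpoint(self):
        dps = np.linspace(-40, 30, 100)
        assert (np.diff(absolute_humidity(dps)) > 0).all()

    def test_compute_ahum_is_annual_mean(self):
        cube = _constant_cube(dewpoint=12.0)
        val = compute_ahum(cube, 2001)
        assert val[0, 0] == pytest.approx(absolute_humidity(12.0), rel=1e-6)

    def test_missing_dewpoint_rejected(self):
        cube = _constant_cube().drop_vars("dewpoint")
        with pytest.raises(ValueError, match="dewpoint"):
            compute_ahum(cube, 2001)


def _multi_year_cube(year0, n_years, tmean_by_year):
    time = pd.date_range(f"{year0}-01-01", f"{year0 + n_years - 1}-12-31",
                         freq="D")
    tmean = np.array([tmean_by_year[y - year0] for y in time.year],
                     dtype=float)
    return climate_cube_from_arrays(
        TOY_GRID, time, tmean=tmean, tmin=tmean - 1, tmax=tmean + 1,
        precip=np.ones(len(time)), dewpoint=tmean - 5)


class TestClimatologicalStack:
    def test_stationary_equals_single_year(self):
        cube = _multi_year_cube(2001, 3, [10.0, 10.0, 10.0])
        lu = generate_landuse(TOY_GRID, (2001, 2003), 0.0, seed=0)
        reg = default_registry()
        windowed = climatological_stack(cube, lu, 2003, reg, window=3)
        single = climatological_stack(cube, lu, 2003, reg, window=1)
        for name in windowed.names:
            np.testing.assert_allclose(windowed.array(name),
                                       single.array(name), atol=1e-4)

    def test_window_is_exactly_31_years(self):
        # target 2020 with a 1990-2020 cube: exactly the 31 annual values
        tm = [10.0 + 0.1 * k for k in range(31)]
        cube = _multi_year_cube(1990, 31, tm)
        lu = generate_landuse(TOY_GRID, (2020, 2020), 0.0, seed=0)
        stack = climatological_stack(cube, lu, 2020, default_registry())
        assert stack.data["BIO1"].attrs["window_length"] == 31
        assert stack.array("BIO1")[0, 0] == pytest.approx(np.mean(tm),
                                                          abs=1e-3)

    def test_linear_trend_mean_linearity(self):
        b = 0.2
        cube = _multi_year_cube(2000, 4, [b * k for k in range(4)])
        lu = generate_landuse(TOY_GRID, (2000, 2003), 0.0, seed=0)
        reg = default_registry()
        s2 = climatological_stack(cube, lu, 2002, reg, window=2)
        s3 = climatological_stack(cube, lu, 2003, reg, window=2)
        diff = s3.array("BIO1")[0, 0] - s2.array("BIO1")[0, 0]
        assert diff == pytest.approx(b, abs=1e-3)

    def test_missing_window_years_named(self):
        cube = _multi_year_cube(2000, 2, [10.0, 10.0])
        lu = generate_landuse(TOY_GRID, (2000, 2001), 0.0, seed=0)
        with pytest.raises(ValueError, match="missing years"):
            climatological_stack(cube, lu, 2001, default_registry(), window=5)

    def test_landuse_copied_from_target_year_only(self, climate_small,
                                                  landuse_small, registry):
        stack = climatological_stack(climate_small, landuse_small, 2002,
                                     registry)
        lu_2002 = landuse_small.sel(year=2002)
        for cls in lu_2002.lu_class.values:
            np.testing.assert_array_equal(stack.array(str(cls)),
                                          lu_2002.sel(lu_class=cls).values)
            assert stack.group_of(str(cls)) == "landuse"

    def test_metadata_groups(self, stack_2002):
        assert set(stack_2002.climate_names) >= {"BIO1", "BIO19", "AHUM"}
        assert len(stack_2002.landuse_names) == 14
        assert len(stack_2002.names) == 19 + 18 + 1 + 14

    def test_annual_predictors_reuse(self, climate_small, landuse_small,
                                     registry, stack_2002):
        annual = annual_predictors(climate_small, registry,
                                   list(range(1972, 2003)))
        via_annual = climatological_stack(None, landuse_small, 2002, registry,
                                          annual=annual)
        np.testing.assert_allclose(via_annual.array("BIO1"),
                                   stack_2002.array("BIO1"), atol=1e-6)
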
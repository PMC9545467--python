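"""Windowing, filtering, classification, year policy and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ventiscan import DetectionConfig, select_reporting_year, select_years
from ventiscan.detector import (
    DEGENERATE,
    STABILITY_SWC,
    STABILITY_UNEVALUABLE,
    TOO_FEW_RECORDS,
    classify_window,
    emission_period,
    filter_records,
    make_windows,
    summarize_coefficients,
    swc_percentile_at_ve,
    ve_verdict,
    window_stability,
    detect_site,
)

from conftest import make_series, year_frame


def five_day_frame(start="2013-07-15", **columns):
    idx = pd.date_range(start, periods=240, freq="30min")
    base = {
        "FC": 1.0, "USTAR": 0.4, "TA": 25.0, "SW_IN": 400.0, "SWC": 4.0,
        "P": 0.0, "FC_QC": 0.0,
    }
    base.update(columns)
    frame = pd.DataFrame(index=idx)
    for name, value in base.items():
        frame[name] = value
    return frame


class TestMakeWindows:
    @pytest.mark.parametrize("year,ndays", [(2013, 365), (2012, 366)])
    def test_73_windows_per_year(self, year, ndays):
        frame = year_frame(year)
        starts = make_windows(make_series(frame), year, DetectionConfig())
        assert len(starts) == 73
        assert starts[0] == pd.Timestamp(f"{year}-01-01")
        assert starts[-1].dayofyear == 361  # DOY 366 falls in the remainder

    def test_first_window_covers_doy_1_to_5(self):
        starts = make_windows(
            make_series(year_frame()), 2013, DetectionConfig()
        )
        end = starts[0] + pd.Timedelta(days=5) - pd.Timedelta(minutes=30)
        assert end.dayofyear == 5


class TestWindowStability:
    def test_boundary_three_degrees_is_admitted(self):
        frame = five_day_frame()
        days = frame.index.normalize()
        frame.loc[days == frame.index[0].normalize(), "TA"] = 20.0
        frame.loc[days == days[-1], "TA"] = 23.0
        ok, reason = window_stability(frame, frame.index[0], DetectionConfig())
        assert ok and reason is None

    def test_swc_drift_above_one_percent_rejected(self):
        frame = five_day_frame()
        days = frame.index.normalize()
        frame.loc[days == frame.index[0].normalize(), "SWC"] = 10.0
        frame.loc[days == days[-1], "SWC"] = 11.5
        ok, reason = window_stability(frame, frame.index[0], DetectionConfig())
        assert not ok and reason == STABILITY_SWC

    def test_all_missing_day5_ta_is_unevaluable(self):
        frame = five_day_frame()
        frame.loc[frame.index.normalize() == frame.index.normalize()[-1], "TA"] = np.nan
        ok, reason = window_stability(frame, frame.index[0], DetectionConfig())
        assert not ok and reason == STABILITY_UNEVALUABLE

    def test_unmapped_swc_skips_its_test(self):
        frame = five_day_frame().drop(columns=["SWC"])
        ok, _ = window_stability(frame, frame.index[0], DetectionConfig())
        assert ok


class TestFilterRecords:
    def test_constructed_violation_counts(self):
        """240 records: 30 night-only, 20 rain-only, 15 low-u*-only, 175 clean."""
        frame = five_day_frame()
        frame.iloc[0:30, frame.columns.get_loc("SW_IN")] = 20.0
        frame.iloc[30:50, frame.columns.get_loc("P")] = 0.5
        frame.iloc[50:65, frame.columns.get_loc("USTAR")] = 0.1
        surviving, report = filter_records(frame, DetectionConfig())
        assert report.records_surviving == len(surviving) == 175
        assert report.removed["night"] == 30
        assert report.removed["rain"] == 20
        assert report.removed["low_ustar"] == 15
        assert report.removed["nonpositive_fc"] == 0

    def test_order_independence(self):
        frame = five_day_frame()
        frame.iloc[0:30, frame.columns.get_loc("SW_IN")] = 20.0
        frame.iloc[30:50, frame.columns.get_loc("P")] = 0.5
        frame.iloc[50:65, frame.columns.get_loc("USTAR")] = 0.1
        shuffled = frame.sample(frac=1.0, random_state=3)
        _, a = filter_records(frame, DetectionConfig())
        _, b = filter_records(shuffled, DetectionConfig())
        assert a.removed == b.removed
        assert a.records_surviving == b.records_surviving

    @pytest.mark.parametrize(
        "column,value,criterion",
        [
            ("SW_IN", 50.0, "night"),        # "> 50" strict
            ("SW_IN", 49.0, "night"),
            ("FC", 0.0, "nonpositive_fc"),    # "> 0" strict
            ("USTAR", 0.2, "low_ustar"),      # "> 0.2" strict
            ("P", 0.5, "rain"),
            ("FC_QC", 2.0, "bad_qc"),
        ],
    )
    def test_boundary_strictness(self, column, value, criterion):
        frame = five_day_frame()
        frame.iloc[0, frame.columns.get_loc(column)] = value
        _, report = filter_records(frame, DetectionConfig())
        assert report.removed[criterion] == 1
        assert report.records_surviving == 239

    def test_missing_precip_drops_record_when_mapped(self):
        frame = five_day_frame()
        frame.iloc[0, frame.columns.get_loc("P")] = np.nan
        _, report = filter_records(frame, DetectionConfig())
        assert report.removed["rain"] == 1
        no_p = frame.drop(columns=["P"])
        _, report = filter_records(no_p, DetectionConfig())
        assert report.removed["rain"] == 0

    def test_surviving_records_satisfy_all_predicates(self):
        rng = np.random.default_rng(11)
        frame = five_day_frame(
            FC=rng.normal(1.0, 1.0, 240),
            USTAR=rng.lognormal(-1.2, 0.5, 240),
            SW_IN=rng.uniform(0, 600, 240),
            P=rng.exponential(0.02, 240),
        )
        cfg = DetectionConfig()
        surviving, report = filter_records(frame, cfg)
        assert (surviving["SW_IN"] > 50).all()
        assert (surviving["FC"] > 0).all()
        assert (surviving["P"] <= cfg.precip_zero_tol).all()
        assert (surviving["USTAR"] > 0.2).all()
        assert report.records_surviving + sum(report.removed.values()) == 240


class TestClassifyWindow:
    def _classify(self, surviving, cfg=None):
        return classify_window(
            "S", 2013, 0, pd.Timestamp("2013-07-15"), surviving,
            cfg or DetectionConfig(),
        )

    def test_n_equal_40_is_too_few(self):
        frame = five_day_frame().iloc[:40]
        res = self._classify(frame)
        assert not res.admitted and res.rejection_reason == TOO_FEW_RECORDS
        assert res.rho is None

    def test_verdict_boundaries(self, cfg):
        assert ve_verdict(0.25, 0.01, cfg)
        assert not ve_verdict(0.2, 0.001, cfg)   # "above 0.2" strict
        assert not ve_verdict(0.5, 0.05, cfg)    # "p < .05" strict
        assert not ve_verdict(-0.5, 1e-9, cfg)   # direction matters

    def test_coupled_window_is_ve(self):
        rng = np.random.default_rng(21)
        n = 100
        ustar = rng.lognormal(-1.0, 0.4, n)
        frame = five_day_frame()[:n].copy()
        frame["USTAR"] = ustar
        frame["FC"] = 1.0 + 3.0 * ustar + rng.normal(0, 0.3, n)
        frame["TA"] = rng.normal(25, 1, n)
        res = self._classify(frame)
        assert res.admitted and res.is_ve and res.rho > 0.2

    def test_degenerate_constant_fc_is_not_ve(self):
        frame = five_day_frame()  # FC constant
        frame["USTAR"] = np.linspace(0.25, 0.8, 240)
        res = self._classify(frame)
        assert res.admitted and not res.is_ve
        assert res.rejection_reason == DEGENERATE

    def test_constant_covariates_are_pruned(self):
        rng = np.random.default_rng(31)
        frame = five_day_frame(
            FC=rng.normal(1, 0.5, 240), USTAR=rng.lognormal(-1, 0.3, 240),
            TA=rng.normal(25, 1, 240),
        )  # SWC, P constant
        res = self._classify(frame)
        assert "SWC" not in res.covariates_used
        assert "TA" in res.covariates_used

    def test_rank_collinear_covariate_is_dropped(self):
        rng = np.random.default_rng(41)
        frame = five_day_frame(
            FC=rng.normal(1, 0.5, 240), USTAR=rng.lognormal(-1, 0.3, 240),
            TA=rng.normal(25, 1, 240),
        )
        frame["SW_IN"] = rng.uniform(60, 600, 240)
        frame["PPFD_IN"] = 2.1 * frame["SW_IN"]
        res = self._classify(frame)
        assert res.admitted
        assert "PPFD_IN" not in res.covariates_used
        assert "SW_IN" in res.covariates_used

    def test_empty_covariate_set_reduces_to_plain_spearman(self):
        from ventiscan.stats_core import spearman

        rng = np.random.default_rng(51)
        frame = five_day_frame(
            FC=rng.normal(1, 0.5, 240), USTAR=rng.lognormal(-1, 0.3, 240),
        )
        cfg = DetectionConfig(covariate_set=())
        res = self._classify(frame, cfg)
        ref = spearman(frame["FC"].to_numpy(), frame["USTAR"].to_numpy())
        assert res.rho == ref.rho and res.p_value == ref.p_value


class TestYearPolicy:
    @pytest.mark.parametrize(
        "years,expected",
        [
            (range(2001, 2004), [2001, 2002, 2003]),
            (range(2001, 2005), [2001, 2002, 2003, 2004]),
            (range(2001, 2007), [2001, 2002, 2003, 2004]),
            (range(2001, 2009), [2001, 2003, 2005, 2007]),
            (range(2001, 2013), [2001, 2003, 2005, 2007]),
        ],
    )
    def test_policies(self, years, expected):
        assert select_years(list(years), DetectionConfig()) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_years([], DetectionConfig())

    def test_reporting_year_max_then_earliest(self):
        assert select_reporting_year({2001: 0, 2002: 3}) == 2002
        assert select_reporting_year({2001: 2, 2003: 2}) == 2001
        assert select_reporting_year({2001: 0, 2002: 0}) == 2001


class TestDiagnostics:
    def test_emission_period_examples(self):
        frame = year_frame(columns=("FC", "USTAR", "SW_IN"))
        frame["FC"] = -1.0
        series = make_series(frame)
        assert emission_period(series, 2013) is None
        mask = (frame.index.dayofyear >= 100) & (frame.index.dayofyear <= 110)
        frame.loc[mask, "FC"] = 2.0
        assert emission_period(make_series(frame), 2013) == (100, 110, 11)

    def test_swc_percentiles_min_and_median(self):
        frame = year_frame(columns=("FC", "USTAR", "SW_IN", "SWC"))
        frame["SWC"] = np.linspace(30, 2, len(frame))  # strictly decreasing
        series = make_series(frame)

        class Win:
            pass

        last = Win(); last.start = pd.Timestamp("2013-12-23").date()
        mid = Win(); mid.start = pd.Timestamp("2013-07-02").date()
        pct = swc_percentile_at_ve(series, 2013, [last, mid])
        assert pct[0] < 2.0          # near the annual minimum
        assert pct[1] == pytest.approx(50, abs=1.0)

    def test_summary_matches_sort_oracle(self):
        rng = np.random.default_rng(61)
        values = rng.uniform(0.2, 0.8, 1000).tolist()
        summary = summarize_coefficients({"g": values})["g"]
        s = np.sort(values)

        def quantile_sorted(q):  # same linear interpolation, via plain sort
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert summary["min"] == s[0] and summary["max"] == s[-1]
        assert summary["median"] == pytest.approx(quantile_sorted(0.5), rel=1e-12)
        assert summary["q1"] == pytest.approx(quantile_sorted(0.25), rel=1e-12)
        assert summary["q3"] == pytest.approx(quantile_sorted(0.75), rel=1e-12)
        assert summarize_coefficients({"empty": []}) == {}
        single = summarize_coefficients({"g": [0.4]})["g"]
        assert {single[k] for k in ("min", "q1", "median", "q3", "max")} == {0.4}


class TestDetectorProperties:
    def test_verdict_monotone_in_thresholds(self, default_site):
        series, _ = default_site
        base = detect_site(series, DetectionConfig())
        stricter_rho = detect_site(series, DetectionConfig(rho_min=0.4))
        stricter_alpha = detect_site(series, DetectionConfig(alpha=0.01))
        assert stricter_rho.ve_count_selected_year <= base.ve_count_selected_year
        assert stricter_alpha.ve_count_selected_year <= base.ve_count_selected_year

    def test_detector_is_deterministic(self, default_site):
        series, _ = default_site
        a = detect_site(series, DetectionConfig())
        b = detect_site(series, DetectionConfig())
        assert a.ve_count_selected_year == b.ve_count_selected_year
        for year in a.years_analyzed:
            assert a.windows[year] == b.windows[year]
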
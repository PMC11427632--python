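"""Control limits, outlier flags, yearly CV and report assembly.

Brute-force oracles recompute limits and yearly statistics with plain
Python loops, independent of the vectorised implementation.
"""

import datetime
import math

import numpy as np
import pandas as pd
import pytest

from phantomqc import MetricSeries, control_limits, flag_outliers, yearly_cv
from phantomqc.errors import (
    InsufficientHistoryError,
    StoreLookupError,
    ValidationError,
)
from phantomqc.io_mri import STORE_COLUMNS, MetricStore
from phantomqc.monitoring import (
    MonitorConfig,
    find_single_metric_alerts,
    monitor_report,
    summarize_scanner,
)


def series_from(values, start=datetime.date(2016, 1, 1), cadence=7, name="drift"):
    dates = tuple(start + datetime.timedelta(days=i * cadence)
                  for i in range(len(values)))
    return MetricSeries("scanner-01", name, dates, np.asarray(values, float))


def store_from(metric_values: dict, scanner_id="scanner-01",
               start=datetime.date(2016, 1, 1), cadence=7) -> MetricStore:
    """Build a metric store directly from per-metric value arrays."""
    n = len(next(iter(metric_values.values())))
    rows = []
    for i in range(n):
        date = start + datetime.timedelta(days=i * cadence)
        row = dict.fromkeys(STORE_COLUMNS, 0.0)
        row.update(
            site="SIM", scanner_id=scanner_id, date=date.isoformat(),
            session_type="phantom", id="phantom01", flag_misplaced=False,
            n_volumes_used=95, flag_duplicate=False,
        )
        for name, vals in metric_values.items():
            row[name] = float(vals[i])
        rows.append(row)
    return MetricStore(records=pd.DataFrame(rows, columns=STORE_COLUMNS))


def brute_force_global_limits(values, k):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, k * sd


def brute_force_yearly(dates, values):
    out = {}
    by_year = {}
    for d, v in zip(dates, values):
        by_year.setdefault(d.year, []).append(v)
    for year in range(min(by_year), max(by_year) + 1):
        vals = by_year.get(year, [])
        if not vals:
            out[year] = ("missing", None)
        elif len(vals) < 2:
            out[year] = ("undefined", None)
        else:
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            out[year] = ("ok", sd / mean) if mean != 0 else ("undefined", None)
    return out


class TestControlLimits:
    def test_hand_computed_example(self):
        limits = control_limits(series_from([1, 2, 3, 4, 5]), k=2.5)
        assert limits.global_center == pytest.approx(3.0)
        assert limits.global_half_width == pytest.approx(2.5 * math.sqrt(2.5))

    def test_constant_series_has_zero_width(self):
        s = series_from([4.2] * 8)
        limits = control_limits(s)
        assert limits.global_half_width == 0.0
        deviant = series_from([4.2] * 7 + [4.3])
        assert flag_outliers(deviant, limits)[-1]

    def test_single_observation_insufficient(self):
        with pytest.raises(InsufficientHistoryError, match="2"):
            control_limits(series_from([1.0]))

    def test_rolling_needs_ten_observations(self):
        with pytest.raises(InsufficientHistoryError, match="10"):
            control_limits(series_from(range(9)), mode="rolling")
        with pytest.raises(ValidationError):
            control_limits(series_from(range(30)), mode="rolling", n_window=5)

    def test_rolling_excludes_evaluated_point(self, rng):
        values = list(rng.normal(10, 1, size=25))
        values[20] = 1e6  # huge spike
        s = series_from(values)
        limits = control_limits(s, mode="rolling", n_window=20)
        # the spike's own limit comes from the 20 points before it
        clean_mean = np.mean(values[0:20])
        assert limits.center[20] == pytest.approx(clean_mean)
        assert flag_outliers(s, limits)[20]
        # warm-up points (fewer than 10 trailing) carry no limits
        assert np.isnan(limits.center[:10]).all()

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n)
            limits = control_limits(series_from(list(values)), k=2.5)
            mean, half = brute_force_global_limits(list(values), 2.5)
            assert limits.global_center == pytest.approx(mean, abs=1e-12)
            assert limits.global_half_width == pytest.approx(half, abs=1e-12)


class TestFlagOutliers:
    def test_point_exactly_on_limit_not_flagged(self):
        values = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
        s = series_from(values)
        sd = np.std(values, ddof=1)
        limits = control_limits(s, k=1.0 / sd)  # half-width exactly 1.0
        assert limits.global_half_width == pytest.approx(1.0)
        assert not flag_outliers(s, limits).any()

    def test_monotone_in_k(self, rng):
        s = series_from(list(rng.normal(0, 1, 40)))
        none = flag_outliers(s, control_limits(s, k=np.inf))
        all_dev = flag_outliers(s, control_limits(s, k=0.0))
        assert not none.any()
        expected = s.values != control_limits(s).global_center
        np.testing.assert_array_equal(all_dev, expected)

    def test_false_flag_rate_matches_gaussian_tail(self, rng):
        # two-sided P(|z| > 2.5) = 1.24%
        values = rng.normal(0, 1, 10_000)
        s = series_from(list(values), cadence=1)
        flags = flag_outliers(s, control_limits(s, k=2.5))
        rate = 100.0 * flags.mean()
        assert rate == pytest.approx(1.24, abs=0.6)

    def test_known_anomalies_recovered(self, rng):
        values = rng.normal(5, 0.5, 60)
        limits_ref = brute_force_global_limits(list(values), 1.0)[1]
        for idx in (10, 30, 50):
            values[idx] = 5 + 4 * limits_ref  # +4 SD of the clean series
        s = series_from(list(values))
        flags = flag_outliers(s, control_limits(s, k=2.5))
        assert set(np.flatnonzero(flags)) >= {10, 30, 50}
        assert flags.sum() <= 4  # at most one false positive


class TestYearlyCV:
    def test_hand_computed_example(self):
        dates = [datetime.date(2016, m, 1) for m in (1, 4, 7, 10)]
        s = MetricSeries("sc", "drift", tuple(dates),
                         np.array([10.0, 12.0, 8.0, 10.0]))
        summary = yearly_cv(s)
        stats = summary.years[2016]
        assert stats.cv == pytest.approx(math.sqrt(8 / 3) / 10, abs=1e-12)
        assert stats.marker == "ok"

    def test_single_observation_year_is_undefined(self):
        dates = (datetime.date(2019, 5, 1), datetime.date(2020, 5, 1),
                 datetime.date(2020, 9, 1))
        s = MetricSeries("sc", "drift", dates, np.array([3.0, 2.0, 4.0]))
        summary = yearly_cv(s)
        assert summary.years[2019].marker == "undefined"
        assert summary.years[2020].marker == "ok"

    def test_absent_year_is_missing(self):
        dates = (datetime.date(2018, 5, 1), datetime.date(2018, 7, 1),
                 datetime.date(2020, 5, 1), datetime.date(2020, 7, 1))
        s = MetricSeries("sc", "drift", dates, np.array([1.0, 2.0, 3.0, 4.0]))
        assert yearly_cv(s).years[2019].marker == "missing"

    def test_zero_mean_year_is_undefined_with_reason(self):
        dates = (datetime.date(2018, 5, 1), datetime.date(2018, 7, 1))
        s = MetricSeries("sc", "drift", dates, np.array([-1.0, 1.0]))
        stats = yearly_cv(s).years[2018]
        assert stats.marker == "undefined"
        assert "zero" in stats.reason

    def test_matches_brute_force_on_random_dated_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            dates = sorted(
                datetime.date(2015, 1, 1)
                + datetime.timedelta(days=int(d))
                for d in rng.integers(0, 6 * 365, size=n)
            )
            values = rng.normal(10, 2, size=n)
            s = MetricSeries("sc", "m", tuple(dates), values)
            got = yearly_cv(s)
            expected = brute_force_yearly(dates, list(values))
            assert set(got.years) == set(expected)
            for year, (marker, cv) in expected.items():
                assert got.years[year].marker == marker, year
                if marker == "ok":
                    assert got.years[year].cv == pytest.approx(cv, abs=1e-12)


class TestSummaries:
    def test_per_metric_summary_shape_and_values(self, rng):
        store = store_from({"snr": rng.normal(600, 10, 12),
                            "drift": rng.normal(1.5, 0.1, 12)})
        summary = summarize_scanner(store, "scanner-01")
        assert summary.loc["snr", "n"] == 12
        assert summary.loc["snr", "mean"] == pytest.approx(600, rel=0.05)
        assert {"mean", "sd", "median", "iqr"} <= set(summary.columns)

    def test_single_session_has_undefined_sd(self):
        store = store_from({"snr": [600.0]})
        summary = summarize_scanner(store, "scanner-01")
        assert np.isnan(summary.loc["snr", "sd"])
        assert summary.loc["snr", "mean"] == 600.0

    def test_unknown_scanner_errors(self):
        store = store_from({"snr": [600.0, 610.0]})
        with pytest.raises(StoreLookupError):
            summarize_scanner(store, "nope")


class TestAlertsAndReport:
    def _stable_store(self, n=60):
        rng = np.random.default_rng(2018)
        return store_from({
            "snr": rng.normal(600, 6, n),
            "sfnr": rng.normal(100, 1, n),
            "psc": rng.normal(0.03, 0.003, n),
            "psg": rng.normal(0.5, 0.02, n),
            "drift": rng.normal(1.5, 0.1, n),
        })

    def test_stable_history_reports_no_alerts(self, tmp_path):
        report = monitor_report(self._stable_store(), out_dir=tmp_path)
        assert report.alerts == []
        assert (tmp_path / "report.md").exists()
        assert (tmp_path / "scanner-01_drift.csv").exists()

    def test_isolated_ghosting_rise_raises_single_metric_alert(self):
        # a sustained shift inflates its own global SD, so the
        # early-warning configuration (rolling limits from trailing
        # clean history) is the one that must catch it
        store = self._stable_store()
        psg = store.records["psg"].to_numpy().copy()
        psg[-8:] *= 10  # tenfold ghosting rise over the final sessions
        store.records["psg"] = psg
        report = monitor_report(store, MonitorConfig(mode="rolling"))
        assert [a.metric_name for a in report.alerts] == ["psg"]
        assert report.alerts[0].n_flagged >= 3

    def test_simultaneous_jumps_are_not_single_metric_alerts(self):
        store = self._stable_store()
        for name in ("psg", "snr"):
            col = store.records[name].to_numpy().copy()
            col[-5:] *= 10
            store.records[name] = col
        report = monitor_report(store)
        assert report.alerts == []

    def test_isolated_foreign_flag_does_not_veto_alert(self):
        # a lone snr false flag inside the span is not a systematic
        # change and must not suppress the psg alert
        flags = {
            "psg": np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=bool),
            "snr": np.array([0, 0, 0, 1, 0, 0, 0, 0], dtype=bool),
        }
        dates = tuple(datetime.date(2018, 1, 1) + datetime.timedelta(d)
                      for d in range(8))
        alerts = find_single_metric_alerts(flags, dates, "sc", min_consecutive=3)
        assert [a.metric_name for a in alerts] == ["psg"]
        assert alerts[0].n_flagged == 5

    def test_concurrent_systematic_run_vetoes_alert(self):
        flags = {
            "psg": np.array([0, 0, 1, 1, 1, 1, 1, 0], dtype=bool),
            "snr": np.array([0, 0, 0, 1, 1, 1, 0, 0], dtype=bool),
        }
        dates = tuple(datetime.date(2018, 1, 1) + datetime.timedelta(d)
                      for d in range(8))
        alerts = find_single_metric_alerts(flags, dates, "sc", min_consecutive=3)
        assert [a.metric_name for a in alerts] == []

    def test_single_session_store_renders_partial_report(self):
        store = store_from({"snr": [600.0]})
        report = monitor_report(store)
        assert report.errors  # limits impossible with one observation
        assert "Summary" in report.markdown

    def test_empty_store_errors(self):
        with pytest.raises(InsufficientHistoryError):
            monitor_report(MetricStore())

    def test_plots_written_when_requested(self, rng, tmp_path):
        store = store_from({"snr": rng.normal(600, 6, 12),
                            "sfnr": rng.normal(100, 1, 12),
                            "psc": rng.normal(0.03, 0.003, 12),
                            "psg": rng.normal(0.5, 0.02, 12),
                            "drift": rng.normal(1.5, 0.1, 12)})
        monitor_report(store, MonitorConfig(make_plots=True), out_dir=tmp_path)
        assert (tmp_path / "scanner-01_drift.png").exists()
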
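"""Longitudinal scanner monitoring: control limits, outliers, yearly CV.

A scanner's QA metrics are treated as a dated control chart.  Limits are
``center ± k * SD`` with k = 2.5 by default; the sample SD (n-1
denominator) is used throughout because yearly sample sizes are small.
Two modes exist:

* ``global`` — centre and SD from all observations, the retrospective
  (post-hoc) analysis of a completed study;
* ``rolling`` — centre and SD from the trailing ``n_window`` (default
  20, minimum 10) observations *excluding* the evaluated point, the
  prospective early-warning variant.

A point lying exactly on a limit is not flagged (strict inequality).
Yearly summaries report the coefficient of variation CV = SD/mean per
calendar year; a year with fewer than two observations yields an
"undefined" marker and an absent year a "missing" marker.

A *single-metric alert* is a run of at least ``min_consecutive``
(default 3) consecutively flagged sessions on one metric while no other
metric shows a systematic change (its own such run) in the same span —
the signature of a localized hardware fault (e.g. a failing body coil
driving ghosting up tenfold while SNR stays stable).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError, PhantomQCError, ValidationError
from .io_mri import MetricStore

__all__ = [
    "QA_METRIC_NAMES",
    "MetricSeries",
    "ControlLimits",
    "YearStats",
    "YearlySummary",
    "MonitorConfig",
    "MonitorReport",
    "control_limits",
    "flag_outliers",
    "yearly_cv",
    "summarize_scanner",
    "monitor_report",
]

QA_METRIC_NAMES = ["snr", "sfnr", "psc", "psg", "drift"]


@dataclass(frozen=True)
class MetricSeries:
    """A scanner's dated sequence of one QA metric."""

    scanner_id: str
    metric_name: str
    dates: tuple[_dt.date, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(values):
            raise ValidationError("dates and values must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValidationError("metric values must be finite")
        if any(b < a for a, b in zip(self.dates, self.dates[1:])):
            raise ValidationError("dates must be ascending")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dates", tuple(self.dates))

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_store(
        cls, store: MetricStore, scanner_id: str, metric_name: str
    ) -> "MetricSeries":
        df = store.for_scanner(scanner_id)
        df = df.assign(_d=pd.to_datetime(df["date"]).dt.date).sort_values(
            "_d", kind="stable"
        )
        return cls(
            scanner_id=scanner_id,
            metric_name=metric_name,
            dates=tuple(df["_d"]),
            values=df[metric_name].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ControlLimits:
    """Per-observation centre and half-width (k * SD) of the control band.

    In global mode all entries are identical; in rolling mode entries
    are NaN until enough trailing history (>= 10 points) exists.
    """

    center: np.ndarray
    half_width: np.ndarray
    k: float
    mode: str
    n_window: int | None = None

    @property
    def global_center(self) -> float:
        return float(self.center[0])

    @property
    def global_half_width(self) -> float:
        return float(self.half_width[0])


def control_limits(
    series: MetricSeries,
    k: float = 2.5,
    mode: str = "global",
    n_window: int = 20,
) -> ControlLimits:
    """Compute ±k·SD control limits for a metric series."""
    v = series.values
    n = len(v)
    if mode == "global":
        if n < 2:
            raise InsufficientHistoryError(
                f"global limits need >= 2 observations, got {n}"
            )
        center = float(v.mean())
        half = k * float(v.std(ddof=1))
        return ControlLimits(
            center=np.full(n, center),
            half_width=np.full(n, half),
            k=k,
            mode=mode,
        )
    if mode == "rolling":
        n_min = 10
        if n_window < n_min:
            raise ValidationError(f"n_window must be >= {n_min}, got {n_window}")
        if n < n_min:
            raise InsufficientHistoryError(
                f"rolling limits need >= {n_min} observations, got {n}"
            )
        center = np.full(n, np.nan)
        half = np.full(n, np.nan)
        for i in range(n):
            window = v[max(0, i - n_window) : i]  # trailing, excludes point i
            if len(window) >= n_min:
                center[i] = window.mean()
                half[i] = k * window.std(ddof=1)
        return ControlLimits(
            center=center, half_width=half, k=k, mode=mode, n_window=n_window
        )
    raise ValidationError(f"unknown mode {mode!r}")


def flag_outliers(series: MetricSeries, limits: ControlLimits) -> np.ndarray:
    """Boolean flag per observation: |value - center| > half_width.

    Strict inequality: a point exactly on the limit passes.  Points
    without defined limits (rolling warm-up) are never flagged.
    """
    with np.errstate(invalid="ignore"):
        dev = np.abs(series.values - limits.center)
        flags = dev > limits.half_width
    flags[~np.isfinite(limits.half_width)] = False
    return flags


@dataclass(frozen=True)
class YearStats:
    year: int
    n: int
    mean: float | None
    sd: float | None
    cv: float | None
    marker: str  # "ok" | "undefined" | "missing"
    reason: str = ""


@dataclass(frozen=True)
class YearlySummary:
    scanner_id: str
    metric_name: str
    years: dict[int, YearStats]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "year": y.year,
                "n": y.n,
                "mean": y.mean,
                "sd": y.sd,
                "cv": y.cv,
                "marker": y.marker,
                "reason": y.reason,
            }
            for y in sorted(self.years.values(), key=lambda s: s.year)
        ]
        return pd.DataFrame(rows)


def yearly_cv(series: MetricSeries) -> YearlySummary:
    """Per-calendar-year n/mean/SD/CV with undefined and missing markers."""
    years: dict[int, YearStats] = {}
    if len(series) == 0:
        return YearlySummary(series.scanner_id, series.metric_name, years)
    by_year: dict[int, list[float]] = {}
    for d, v in zip(series.dates, series.values):
        by_year.setdefault(d.year, []).append(float(v))
    for year in range(min(by_year), max(by_year) + 1):
        vals = by_year.get(year)
        if not vals:
            years[year] = YearStats(year, 0, None, None, None, "missing",
                                    "no measurements in this year")
            continue
        arr = np.asarray(vals)
        mean = float(arr.mean())
        if len(arr) < 2:
            years[year] = YearStats(
                year, len(arr), mean, None, None, "undefined",
                "only one measurement; CV requires at least two",
            )
            continue
        sd = float(arr.std(ddof=1))
        if mean == 0:
            years[year] = YearStats(
                year, len(arr), mean, sd, None, "undefined", "mean is zero"
            )
            continue
        years[year] = YearStats(year, len(arr), mean, sd, sd / mean, "ok")
    return YearlySummary(series.scanner_id, series.metric_name, years)


def summarize_scanner(store: MetricStore, scanner_id: str) -> pd.DataFrame:
    """Per-metric n/mean/SD/median/IQR for one scanner (comparison table)."""
    df = store.for_scanner(scanner_id)
    rows = []
    for name in QA_METRIC_NAMES + ["offset_mm"]:
        v = df[name].to_numpy(dtype=float)
        q75, q25 = np.percentile(v, [75, 25])
        rows.append(
            {
                "metric": name,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                "median": float(np.median(v)),
                "iqr": float(q75 - q25),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


@dataclass(frozen=True)
class MonitorConfig:
    k: float = 2.5
    mode: str = "global"
    n_window: int = 20
    min_consecutive: int = 3
    make_plots: bool = False


@dataclass(frozen=True)
class Alert:
    scanner_id: str
    metric_name: str
    start: _dt.date
    end: _dt.date
    n_flagged: int


@dataclass
class MonitorReport:
    markdown: str
    tables: dict[str, pd.DataFrame]
    alerts: list[Alert]
    errors: list[str] = field(default_factory=list)

    def flagged(self, scanner_id: str, metric_name: str) -> np.ndarray:
        return self.tables[f"{scanner_id}_{metric_name}"]["flag"].to_numpy(dtype=bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def find_single_metric_alerts(
    flags_by_metric: dict[str, np.ndarray],
    dates: tuple[_dt.date, ...],
    scanner_id: str,
    min_consecutive: int = 3,
) -> list[Alert]:
    """Sustained flag runs on one metric while the others stay systematic-free.

    An alert is a maximal run of >= ``min_consecutive`` consecutively
    flagged sessions on one metric during which no *other* metric shows a
    systematic change, i.e. no other metric has its own run of
    >= ``min_consecutive`` consecutive flags inside the span.  Isolated
    single-session flags on other metrics do not veto the alert: the
    control limits themselves produce those at the Gaussian tail rate.
    """
    alerts = []
    for name, flags in flags_by_metric.items():
        for start, stop in _runs(flags):
            if stop - start < min_consecutive:
                continue
            others_systematic = any(
                any(e - s >= min_consecutive for s, e in _runs(f[start:stop]))
                for m, f in flags_by_metric.items()
                if m != name
            )
            if others_systematic:
                continue
            alerts.append(
                Alert(scanner_id, name, dates[start], dates[stop - 1], stop - start)
            )
    return alerts


def monitor_report(
    store: MetricStore,
    config: MonitorConfig = MonitorConfig(),
    out_dir: str | Path | None = None,
) -> MonitorReport:
    """Full monitoring report for every scanner in the store.

    Per scanner x metric: time series with limits and flags (CSV), a
    yearly CV table, a summary block, and a single-metric alert section.
    Errors on individual scanners/metrics are collected into the report
    rather than aborting.
    """
    if len(store) == 0:
        raise InsufficientHistoryError("metric store is empty")
    lines = ["# Scanner monitoring report", ""]
    tables: dict[str, pd.DataFrame] = {}
    alerts: list[Alert] = []
    errors: list[str] = []

    for scanner_id in sorted(store.records["scanner_id"].unique()):
        lines.append(f"## Scanner {scanner_id}")
        lines.append("")
        try:
            summary = summarize_scanner(store, scanner_id)
            lines.append("### Summary")
            lines.append("")
            lines.append(summary.reset_index().to_markdown(index=False))
            lines.append("")
        except PhantomQCError as exc:
            errors.append(f"{scanner_id}: summary failed: {exc}")

        flags_by_metric: dict[str, np.ndarray] = {}
        dates: tuple[_dt.date, ...] = ()
        for name in QA_METRIC_NAMES:
            try:
                series = MetricSeries.from_store(store, scanner_id, name)
                limits = control_limits(
                    series, k=config.k, mode=config.mode, n_window=config.n_window
                )
                flags = flag_outliers(series, limits)
            except PhantomQCError as exc:
                errors.append(f"{scanner_id}/{name}: {exc}")
                continue
            dates = series.dates
            flags_by_metric[name] = flags
            table = pd.DataFrame(
                {
                    "date": [d.isoformat() for d in series.dates],
                    "value": series.values,
                    "center": limits.center,
                    "half_width": limits.half_width,
                    "flag": flags,
                }
            )
            tables[f"{scanner_id}_{name}"] = table
            yc = yearly_cv(series).to_frame()
            tables[f"{scanner_id}_{name}_yearly"] = yc
            lines.append(f"### {name}: {int(flags.sum())} flagged of {len(series)}")
            lines.append("")
            lines.append(yc.to_markdown(index=False))
            lines.append("")

        scanner_alerts = find_single_metric_alerts(
            flags_by_metric, dates, scanner_id, config.min_consecutive
        )
        alerts.extend(scanner_alerts)

    lines.append("## Single-metric alerts")
    lines.append("")
    if alerts:
        for a in alerts:
            lines.append(
                f"- **{a.scanner_id} / {a.metric_name}**: {a.n_flagged} consecutive "
                f"flagged sessions from {a.start} to {a.end} with all other "
                "metrics stable"
            )
    else:
        lines.append("- none")
    lines.append("")
    if errors:
        lines.append("## Errors")
        lines.append("")
        lines.extend(f"- {e}" for e in errors)
        lines.append("")

    report = MonitorReport("\n".join(lines), tables, alerts, errors)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(report.markdown)
        for key, table in tables.items():
            table.to_csv(out / f"{key}.csv", index=False)
        if config.make_plots:
            _write_plots(tables, out)
    return report


def _write_plots(tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for key, table in tables.items():
        if key.endswith("_yearly"):
            continue
        fig, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(len(table))
        ax.plot(x, table["value"], "o-", ms=3, lw=0.8)
        ax.plot(x, table["center"] + table["half_width"], "r--", lw=0.8)
        ax.plot(x, table["center"] - table["half_width"], "r--", lw=0.8)
        flagged = table["flag"].to_numpy(dtype=bool)
        ax.plot(x[flagged], table["value"][flagged], "rv", ms=6)
        ax.set_title(key)
        fig.tight_layout()
        fig.savefig(out / f"{key}.png", dpi=90)
        plt.close(fig)
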
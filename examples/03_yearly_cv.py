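"""Year-by-year coefficient of variation of a scanner's drift metric.

Builds a four-year dated drift series with a gap year (no measurements)
and a year with a single measurement, then prints the yearly CV table —
including the "missing" and "CV undefined" markers such gaps produce.
"""

import datetime

import numpy as np

from phantomqc import MetricSeries, yearly_cv

rng = np.random.default_rng(3)
dates, values = [], []
for year, n in ((2016, 10), (2017, 12), (2019, 1)):   # 2018 has no sessions
    for i in range(n):
        dates.append(datetime.date(year, 1 + (i % 12), 14))
        values.append(rng.normal(1.5, 0.25))
dates, values = zip(*sorted(zip(dates, values)))

series = MetricSeries("scanner-MR1", "drift", tuple(dates), np.array(values))
summary = yearly_cv(series)

print(f"{'year':>6} {'n':>4} {'mean':>8} {'CV':>8}  note")
for year, stats in sorted(summary.years.items()):
    cv = f"{stats.cv:.3f}" if stats.cv is not None else "--"
    mean = f"{stats.mean:.3f}" if stats.mean is not None else "--"
    print(f"{year:>6} {stats.n:>4} {mean:>8} {cv:>8}  {stats.reason}")
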
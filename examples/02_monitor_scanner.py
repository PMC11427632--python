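"""Longitudinal monitoring of a scanner with an injected ghosting fault.

Simulates 40 weekly phantom sessions in which the ghost amplitude rises
tenfold for the final 5 sessions (a failing body coil's signature),
measures every session, and runs the early-warning control chart:
rolling ±2.5 SD limits from the trailing 20 measurements.  The report
should flag PSG alone while SNR and the other metrics stay quiet.
"""

import pandas as pd

from phantomqc import (
    GridSpec,
    GroundTruth,
    MonitorConfig,
    compute_all,
    monitor_report,
    simulate_monitoring_history,
)
from phantomqc.io_mri import STORE_COLUMNS, MetricStore

baseline = GroundTruth(signal_mean=1000.0, noise_sd=10.0, ghost_frac=0.005,
                       drift_frac=0.01, n_volumes=30)
anomalies = [(i, {"ghost_frac": 0.05}) for i in range(35, 40)]
grid = GridSpec(shape=(48, 48, 13), voxel_size_mm=(5.0, 5.0, 5.0), tr_s=2.0)

rows = []
for meta, vol, _ in simulate_monitoring_history(
    40, baseline, anomalies=anomalies, grid=grid, seed=11
):
    m = compute_all(vol)
    rows.append(dict(
        site=meta.site, scanner_id=meta.scanner_id, date=meta.date.isoformat(),
        session_type=meta.session_type, id=meta.subject_or_phantom_id,
        snr=m.snr, sfnr=m.sfnr, psc=m.psc, psg=m.psg, drift=m.drift,
        offset_mm=m.offset_mm, flag_misplaced=m.flag_misplaced,
        n_volumes_used=m.n_volumes_used, flag_duplicate=False,
    ))
store = MetricStore(records=pd.DataFrame(rows, columns=STORE_COLUMNS))

report = monitor_report(store, MonitorConfig(mode="rolling"))
for alert in report.alerts:
    print(f"ALERT {alert.scanner_id}/{alert.metric_name}: "
          f"{alert.n_flagged} consecutive flagged sessions "
          f"({alert.start} .. {alert.end})")
print()
print("Flag counts per metric (rolling ±2.5 SD, trailing 20 sessions):")
for name in ("snr", "sfnr", "psc", "psg", "drift"):
    flags = report.flagged("scanner-01", name)
    print(f"  {name:5s}: {int(flags.sum())} of {len(flags)}")
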
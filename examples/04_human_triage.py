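"""Triage human sessions from MRIQC-style IQM documents.

Writes a small batch of per-image JSON quality documents (one with an
injected bad SNR), screens them with robust median/MAD z-scores, and
prints the rule-suggested good/intermediate/poor labels.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from phantomqc import group_outliers, ingest_iqms, suggest_label

rng = np.random.default_rng(8)
tmp = Path(tempfile.mkdtemp())
for i in range(12):
    doc = {"snr": float(rng.normal(12, 0.4)), "fd_mean": float(rng.normal(0.15, 0.02))}
    if i == 7:
        doc["snr"] = 6.0     # far below the group
        doc["fd_mean"] = 0.9  # heavy head motion
    (tmp / f"sub-{i:02d}_task-rest_bold.json").write_text(json.dumps(doc))

result = ingest_iqms(sorted(tmp.glob("*.json")))
screen = group_outliers(result.records, k=2.5)

print(f"{'session':32s} label         reasons")
for record in result.records:
    label = suggest_label(
        record.session_key, record.modality,
        screen.flagged_metrics(record.session_key),
        complete=True, misplaced_fov=False,
    )
    print(f"{record.session_key:32s} {label.label:12s} {'; '.join(label.reasons)}")
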
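"""Human-session triage: completeness, IQM ingestion, outliers, labels.

This module does not compute image-quality metrics (IQMs) itself — it
ingests per-image JSON documents in the MRIQC output dialect (top-level
numeric keys; one level of nesting flattened with dotted names) and
screens them for group-level outliers with a robust z-score::

    z = (value - median) / (1.4826 * MAD)

Median/MAD is used deliberately instead of mean/SD so that a single bad
subject cannot mask itself; this differs from the phantom control
limits, where the stream is assumed mostly clean.

Quality labels ("good" / "intermediate" / "poor") were expert judgments
in the protocol this package implements; here rules produce
*suggestions* (``suggested_by_rules=True``) and human raters can always
override via :func:`record_label`.  The label store is append-only: an
override adds a row and the latest row per (session, modality) wins in
the tally.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "REASON_TAGS",
    "SessionManifest",
    "CompletenessReport",
    "IQMRecord",
    "IngestResult",
    "OutlierScreen",
    "QualityLabel",
    "LabelStore",
    "check_completeness",
    "ingest_iqms",
    "iqm_table",
    "group_outliers",
    "suggest_label",
    "record_label",
]

REASON_TAGS = ("movement", "ghosting", "misplaced-FOV", "fold-over", "other")
LABELS = ("good", "intermediate", "poor")
MODALITIES = ("anat", "func")

LABEL_STORE_COLUMNS = ["session", "modality", "label", "reasons", "rater", "date",
                       "suggested"]


@dataclass(frozen=True)
class SessionManifest:
    """Expected deliverables of one measurement session."""

    session_key: str
    expected_items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.expected_items:
            raise ValidationError("manifest must list at least one expected item")
        if len(set(self.expected_items)) != len(self.expected_items):
            raise ValidationError("expected item names must be unique")


@dataclass(frozen=True)
class CompletenessReport:
    session_key: str
    missing: tuple[str, ...]
    unexpected: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return not self.missing

    @property
    def status(self) -> str:
        if self.missing:
            return "incomplete"
        return "complete-with-warnings" if self.unexpected else "complete"


def check_completeness(
    manifest: SessionManifest, present: list[str] | tuple[str, ...]
) -> CompletenessReport:
    """Compare found items against the manifest.

    A session is complete iff nothing is missing; extra items produce
    warnings, not incompleteness.
    """
    present_set = set(present)
    expected = set(manifest.expected_items)
    missing = tuple(i for i in manifest.expected_items if i not in present_set)
    unexpected = tuple(sorted(present_set - expected))
    return CompletenessReport(manifest.session_key, missing, unexpected)


@dataclass(frozen=True)
class IQMRecord:
    session_key: str
    modality: str
    metrics: dict[str, float]
    source_file: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        for k, v in self.metrics.items():
            if not np.isfinite(v):
                raise ValidationError(f"metric {k!r} is non-finite")


@dataclass
class IngestResult:
    records: list[IQMRecord]
    n_dropped: int = 0
    errors: list[str] = field(default_factory=list)


def _flatten_numeric(doc: dict, prefix: str = "") -> tuple[dict[str, float], int]:
    """Numeric entries of a <=1-level-nested dict; returns (metrics, dropped)."""
    metrics: dict[str, float] = {}
    dropped = 0
    for key, value in doc.items():
        name = f"{prefix}{key}"
        if isinstance(value, bool):
            dropped += 1
        elif isinstance(value, (int, float)) and np.isfinite(value):
            metrics[name] = float(value)
        elif isinstance(value, dict) and not prefix:
            sub, sub_drop = _flatten_numeric(value, prefix=f"{name}.")
            metrics.update(sub)
            dropped += sub_drop
        else:
            dropped += 1
    return metrics, dropped


def _infer_modality(name: str, doc: dict) -> str | None:
    stem = name.lower()
    if "bold" in stem:
        return "func"
    if "t1w" in stem or "t2w" in stem:
        return "anat"
    mod = doc.get("modality")
    if isinstance(mod, str) and mod.lower() in MODALITIES:
        return mod.lower()
    return None


def ingest_iqms(paths: list[str | Path]) -> IngestResult:
    """Read MRIQC-style JSON documents into IQM records.

    Non-numeric entries are dropped (counted); an unparseable file
    yields a per-file error and the batch continues.
    """
    result = IngestResult(records=[])
    for path in paths:
        path = Path(path)
        try:
            doc = json.loads(path.read_text())
            if not isinstance(doc, dict):
                raise ValueError("top-level JSON value is not an object")
        except (OSError, ValueError) as exc:
            result.errors.append(f"{path.name}: {exc}")
            continue
        modality = _infer_modality(path.name, doc)
        if modality is None:
            result.errors.append(f"{path.name}: cannot infer modality (anat/func)")
            continue
        metrics, dropped = _flatten_numeric(doc)
        result.n_dropped += dropped
        session_key = path.name
        for ext in (".json",):
            if session_key.endswith(ext):
                session_key = session_key[: -len(ext)]
        result.records.append(
            IQMRecord(
                session_key=session_key,
                modality=modality,
                metrics=metrics,
                source_file=str(path),
            )
        )
    return result


def iqm_table(records: list[IQMRecord]) -> pd.DataFrame:
    """Sessions x metrics table (union vocabulary, NaN where absent)."""
    if not records:
        return pd.DataFrame()
    rows = {r.session_key: r.metrics for r in records}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass(frozen=True)
class OutlierScreen:
    flags: pd.DataFrame  # bool, sessions x metrics (screened metrics only)
    notes: tuple[str, ...]

    def flagged_metrics(self, session_key: str) -> tuple[str, ...]:
        if session_key not in self.flags.index:
            return ()
        row = self.flags.loc[session_key]
        return tuple(row.index[row])


def group_outliers(records: list[IQMRecord], k: float = 2.5) -> OutlierScreen:
    """Robust group screening: flag |z| > k per metric, median/MAD based.

    Metrics observed in fewer than 3 sessions, or with zero MAD, are
    skipped with a note.
    """
    table = iqm_table(records)
    notes: list[str] = []
    flags = pd.DataFrame(False, index=table.index, columns=[])
    for name in table.columns:
        col = table[name].dropna()
        if len(col) < 3:
            notes.append(f"{name}: skipped, only {len(col)} records (< 3)")
            continue
        med = float(col.median())
        mad = float((col - med).abs().median())
        if mad == 0:
            notes.append(f"{name}: skipped, MAD is zero (no spread)")
            continue
        z = (col - med) / (1.4826 * mad)
        flags[name] = pd.Series(False, index=table.index)
        flags.loc[z.index, name] = (z.abs() > k).to_numpy()
    return OutlierScreen(flags=flags.fillna(False), notes=tuple(notes))


@dataclass(frozen=True)
class QualityLabel:
    session_key: str
    modality: str
    label: str
    reasons: tuple[str, ...]
    rater: str
    date: _dt.date
    suggested_by_rules: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}")
        if self.label == "poor" and not self.reasons:
            raise ValidationError('label "poor" requires at least one reason tag')
        for r in self.reasons:
            base = r.split(":", 1)[0]
            if base not in REASON_TAGS:
                raise ValidationError(
                    f"unknown reason tag {base!r}; allowed: {REASON_TAGS}"
                )


def suggest_label(
    session_key: str,
    modality: str,
    flagged_metrics: tuple[str, ...] | list[str],
    complete: bool,
    misplaced_fov: bool,
    date: _dt.date | None = None,
) -> QualityLabel:
    """Rule-based label suggestion.

    poor  — misplaced FOV, or incomplete session, or >= 2 flagged IQMs;
    intermediate — exactly 1 flagged IQM;
    good  — otherwise.
    """
    flagged = tuple(flagged_metrics)
    reasons: list[str] = []
    if misplaced_fov:
        reasons.append("misplaced-FOV")
    if not complete:
        reasons.append("other:incomplete-session")
    if len(flagged) >= 2:
        reasons.append("other:multiple-iqm-outliers(" + ",".join(flagged) + ")")
    if reasons:
        label = "poor"
    elif len(flagged) == 1:
        label = "intermediate"
        reasons = ["other:iqm-outlier(" + flagged[0] + ")"]
    else:
        label = "good"
    return QualityLabel(
        session_key=session_key,
        modality=modality,
        label=label,
        reasons=tuple(reasons),
        rater="rules",
        date=date or _dt.date.today(),
        suggested_by_rules=True,
    )


@dataclass
class LabelStore:
    """Append-only history of quality labels, persisted as CSV."""

    path: Path | None = None
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LABEL_STORE_COLUMNS)
    )

    @classmethod
    def load(cls, path: str | Path) -> "LabelStore":
        path = Path(path)
        if not path.exists():
            return cls(path=path)
        df = pd.read_csv(path, dtype=str).fillna("")
        return cls(path=path, records=df[LABEL_STORE_COLUMNS])

    def __len__(self) -> int:
        return len(self.records)

    def save(self, path: str | Path | None = None) -> Path:
        target = Path(path) if path is not None else self.path
        if target is None:
            raise ValueError("no path given and store has no associated path")
        self.records.to_csv(target, index=False)
        self.path = target
        return target

    def latest_per_session(self) -> pd.DataFrame:
        """Latest label row per (session, modality); append order wins."""
        if self.records.empty:
            return self.records.copy()
        return self.records.groupby(["session", "modality"], as_index=False).last()

    def tally(self) -> pd.DataFrame:
        """Label counts per modality over latest-per-session labels."""
        latest = self.latest_per_session()
        if latest.empty:
            return pd.DataFrame(0, index=list(MODALITIES), columns=list(LABELS))
        counts = (
            latest.groupby(["modality", "label"]).size().unstack(fill_value=0)
        )
        return counts.reindex(index=list(MODALITIES), columns=list(LABELS),
                              fill_value=0)


def record_label(store: LabelStore, label: QualityLabel) -> LabelStore:
    """Append a label row (never mutates existing rows); persists if pathed."""
    row = {
        "session": label.session_key,
        "modality": label.modality,
        "label": label.label,
        "reasons": ";".join(label.reasons),
        "rater": label.rater,
        "date": label.date.isoformat(),
        "suggested": str(bool(label.suggested_by_rules)),
    }
    row_df = pd.DataFrame([row], columns=LABEL_STORE_COLUMNS)
    new = row_df if store.records.empty else pd.concat(
        [store.records, row_df], ignore_index=True
    )
    out = LabelStore(path=store.path, records=new)
    if out.path is not None:
        out.save()
    return out
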
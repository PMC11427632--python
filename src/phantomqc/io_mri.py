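"""NIfTI I/O, session-name parsing and the longitudinal metric store.

The on-disk formats are deliberately plain: NIfTI-1 for volumes (3-D
files are promoted to a single-timepoint 4-D series on load), JSON
sidecars for metadata, and a flat CSV for the longitudinal metric store
(one row per QA session).  The store is sized for thousands of sessions
at most; a flat, diffable file beats a database at that scale.

File-name convention (BIDS-inspired, fixed by this package)::

    sub-<id>_ses-<YYYYMMDD>_site-<code>[_extra-entities]_<suffix>.nii[.gz]

``sub-phantom*`` marks phantom sessions; otherwise the suffix decides
the session type (``T1w`` -> human-anat, ``bold`` -> human-func).
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FileFormatError, StoreLookupError, ValidationError

__all__ = [
    "Volume4D",
    "SessionMeta",
    "MetricStore",
    "STORE_COLUMNS",
    "read_volume4d",
    "write_volume4d",
    "parse_session_meta",
    "append_metrics",
]


@dataclass(frozen=True)
class Volume4D:
    """A 4-D intensity array (x, y, z, t) with acquisition metadata."""

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValidationError(f"expected 3-D or 4-D data, got {data.ndim}-D")
        if min(data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got shape {data.shape}")
        vox = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if not np.all(vox > 0):
            raise ValidationError(f"voxel sizes must be positive, got {vox}")
        if not self.tr_s > 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        if n_bad:
            raise ValidationError(f"{n_bad} non-finite voxels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float).reshape(4, 4))

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)


_SESSION_TYPES = ("phantom", "human-anat", "human-func")

_NAME_RE = re.compile(
    r"^sub-(?P<sub>[A-Za-z0-9]+)"
    r"_ses-(?P<date>\d{8})"
    r"_site-(?P<site>[A-Za-z0-9]+)"
    r"(?:_[a-z]+-[A-Za-z0-9]+)*"
    r"_(?P<suffix>[A-Za-z0-9]+)"
    r"\.nii(?:\.gz)?$"
)

_NAME_PATTERN = "sub-<id>_ses-<YYYYMMDD>_site-<code>[_entities]_<suffix>.nii[.gz]"


@dataclass(frozen=True)
class SessionMeta:
    """Identity of one measurement session."""

    site: str
    scanner_id: str
    date: _dt.date
    session_type: str
    subject_or_phantom_id: str

    def __post_init__(self) -> None:
        if not self.site:
            raise ValidationError("site code must be non-empty")
        if self.session_type not in _SESSION_TYPES:
            raise ValidationError(
                f"session_type must be one of {_SESSION_TYPES}, got {self.session_type!r}"
            )
        if self.date < _dt.date(2000, 1, 1):
            raise ValidationError(f"date {self.date} predates 2000-01-01")


def parse_session_meta(filename: str | Path, scanner_id: str = "") -> SessionMeta:
    """Parse a BIDS-like file name into a :class:`SessionMeta`.

    ``scanner_id`` is not encoded in the name and may be supplied by the
    caller (defaults to ``site`` when empty).
    """
    name = Path(filename).name
    m = _NAME_RE.match(name)
    if m is None:
        raise ValidationError(
            f"file name {name!r} does not match the expected pattern {_NAME_PATTERN}"
        )
    sub = m.group("sub")
    suffix = m.group("suffix")
    if sub.lower().startswith("phantom"):
        session_type = "phantom"
    elif suffix == "T1w":
        session_type = "human-anat"
    elif suffix == "bold":
        session_type = "human-func"
    else:
        raise ValidationError(
            f"cannot infer session type from suffix {suffix!r} "
            "(known suffixes: T1w, bold; phantom sessions use sub-phantom*)"
        )
    try:
        date = _dt.datetime.strptime(m.group("date"), "%Y%m%d").date()
    except ValueError as exc:
        raise ValidationError(f"unparseable session date in {name!r}: {exc}") from exc
    site = m.group("site")
    return SessionMeta(
        site=site,
        scanner_id=scanner_id or site,
        date=date,
        session_type=session_type,
        subject_or_phantom_id=sub,
    )


def read_volume4d(path: str | Path) -> Volume4D:
    """Load a NIfTI-1 file as a :class:`Volume4D` (3-D promoted to t=1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FileFormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if isinstance(img, nib.Nifti2Image) or not isinstance(img, nib.Nifti1Image):
        raise FileFormatError(
            f"{path}: only NIfTI-1 is supported, got {type(img).__name__}"
        )
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise FileFormatError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValidationError(f"{path}: {n_bad} non-finite voxels")
    return Volume4D(
        data=data,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        tr_s=tr,
        affine=img.affine,
    )


def write_volume4d(vol: Volume4D, path: str | Path) -> Path:
    """Write a :class:`Volume4D` to a NIfTI-1 file (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


# Fixed column order of the metric store CSV.  `flag_duplicate` marks
# rows whose (site, date, id, session_type) key was already present.
STORE_COLUMNS = [
    "site",
    "scanner_id",
    "date",
    "session_type",
    "id",
    "snr",
    "sfnr",
    "psc",
    "psg",
    "drift",
    "offset_mm",
    "flag_misplaced",
    "n_volumes_used",
    "flag_duplicate",
]

_KEY_COLUMNS = ["site", "date", "id", "session_type"]


@dataclass
class MetricStore:
    """Append-only table of per-session QA metrics, persisted as CSV."""

    path: Path | None = None
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=STORE_COLUMNS)
    )

    @classmethod
    def load(cls, path: str | Path) -> "MetricStore":
        path = Path(path)
        if not path.exists():
            return cls(path=path)
        df = pd.read_csv(
            path,
            dtype={"site": str, "scanner_id": str, "id": str},
            float_precision="round_trip",
        )
        missing = set(STORE_COLUMNS) - set(df.columns)
        if missing:
            raise FileFormatError(
                f"{path} is not a metric store: missing columns {sorted(missing)}"
            )
        return cls(path=path, records=df[STORE_COLUMNS])

    def __len__(self) -> int:
        return len(self.records)

    def save(self, path: str | Path | None = None) -> Path:
        target = Path(path) if path is not None else self.path
        if target is None:
            raise ValueError("no path given and store has no associated path")
        self.records.to_csv(target, index=False)
        self.path = target
        return target

    def for_scanner(self, scanner_id: str) -> pd.DataFrame:
        sub = self.records[self.records["scanner_id"] == scanner_id]
        if sub.empty:
            known = sorted(self.records["scanner_id"].unique())
            raise StoreLookupError(
                f"no sessions for scanner {scanner_id!r}; known scanners: {known}"
            )
        return sub.copy()


def append_metrics(store: MetricStore, meta: SessionMeta, metrics) -> MetricStore:
    """Append one (session, metrics) row; persists if the store has a path.

    Duplicate (site, date, id, session_type) keys are appended anyway but
    carry ``flag_duplicate=True`` and emit a warning, so re-runs are
    visible in the audit trail rather than silently merged.
    """
    row = {
        "site": meta.site,
        "scanner_id": meta.scanner_id,
        "date": meta.date.isoformat(),
        "session_type": meta.session_type,
        "id": meta.subject_or_phantom_id,
        "snr": metrics.snr,
        "sfnr": metrics.sfnr,
        "psc": metrics.psc,
        "psg": metrics.psg,
        "drift": metrics.drift,
        "offset_mm": metrics.offset_mm,
        "flag_misplaced": bool(metrics.flag_misplaced),
        "n_volumes_used": int(metrics.n_volumes_used),
        "flag_duplicate": False,
    }
    df = store.records
    if len(df):
        key_match = (
            (df["site"] == row["site"])
            & (df["date"] == row["date"])
            & (df["id"] == row["id"])
            & (df["session_type"] == row["session_type"])
        )
        if bool(key_match.any()):
            row["flag_duplicate"] = True
            warnings.warn(
                f"duplicate session key {tuple(row[k] for k in _KEY_COLUMNS)}; "
                "row appended with flag_duplicate=True",
                stacklevel=2,
            )
    row_df = pd.DataFrame([row], columns=STORE_COLUMNS)
    new = row_df if df.empty else pd.concat([df, row_df], ignore_index=True)
    out = MetricStore(path=store.path, records=new)
    if out.path is not None:
        out.save()
    return out
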
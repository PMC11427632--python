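"""Per-session phantom QA metrics: SNR, SFNR, PSC, PSG, drift, placement.

The definitions follow the fBIRN lineage of phantom stability analysis
(Friedman & Glover-style stability metrics):

SNR
    mean of the temporal-mean image over the signal ROI, divided by the
    background-noise SD of the temporal-mean image corrected by the
    Rayleigh factor 0.655 (magnitude-image background statistics).
SFNR
    per-voxel temporal mean / SD of residuals after removing a
    second-order polynomial trend, averaged over the signal ROI.
PSC (percent signal change / fluctuation)
    100 * SD of the detrended (order-2) ROI-mean time course / its mean.
PSG (percent signal ghosting)
    100 * (ghost-ROI mean - background mean) / signal-ROI mean on the
    temporal-mean image.  Background correction means PSG can be
    slightly negative on ghost-free data.
Drift
    order-1 least-squares fit p(t) to the ROI-mean time course;
    100 * (p(t_last) - p(t_first)) / mean of the time course.

Detrending is order 2 for the fluctuation metrics but drift is the
order-1 endpoint difference, keeping drift and fluctuation orthogonal
by construction.  The first ``n_dummy`` (default 5) volumes are always
discarded before any metric is computed, to account for equilibrium
effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DetectionError,
    InsufficientDataError,
    PhantomQCError,
    ROIError,
)
from .io_mri import Volume4D
from .phantom_sim import grid_center_voxel

__all__ = [
    "RAYLEIGH_FACTOR",
    "ROISet",
    "QAMetrics",
    "QAConfig",
    "discard_dummy",
    "define_rois",
    "compute_snr",
    "compute_sfnr",
    "compute_psc",
    "compute_psg",
    "compute_drift",
    "check_placement",
    "compute_all",
]

# SD of magnitude-image background noise relative to the underlying
# Gaussian channel noise (Rayleigh distribution); applied in SNR only.
RAYLEIGH_FACTOR = 0.655

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ROISet:
    """Signal / ghost / background regions used by the metric suite.

    Invariants: the three classes are pairwise disjoint, each class is
    non-empty, and the signal ROI lies entirely inside the detected
    phantom support.
    """

    signal_roi: np.ndarray
    ghost_roi: np.ndarray
    background_rois: list[np.ndarray]
    slice_mode: str = "volume"
    phantom_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        bg = self.background_union
        for name, roi in (
            ("signal_roi", self.signal_roi),
            ("ghost_roi", self.ghost_roi),
            ("background_rois", bg),
        ):
            if not roi.any():
                raise ROIError(f"{name} is empty")
        if (self.signal_roi & self.ghost_roi).any():
            raise ROIError("signal and ghost ROIs overlap")
        if (self.signal_roi & bg).any() or (self.ghost_roi & bg).any():
            raise ROIError("background ROI overlaps signal or ghost ROI")
        if self.phantom_support is not None and not np.all(
            self.phantom_support[self.signal_roi]
        ):
            raise ROIError("signal ROI extends outside the phantom support")

    @property
    def background_union(self) -> np.ndarray:
        out = np.zeros_like(self.signal_roi)
        for m in self.background_rois:
            out |= m
        return out


@dataclass(frozen=True)
class QAMetrics:
    """One session's phantom QA metric vector."""

    snr: float
    sfnr: float
    psc: float
    psg: float
    drift: float
    offset_mm: float
    flag_misplaced: bool
    n_volumes_used: int


@dataclass(frozen=True)
class QAConfig:
    """Knobs of the per-session QA pipeline."""

    n_dummy: int = 5
    phase_axis: str = "y"
    slice_mode: str = "volume"
    threshold_mm: float = 10.0
    background_block: int = 8
    detection_min_coverage: float = 0.01


def discard_dummy(vol: Volume4D, n_dummy: int = 5) -> Volume4D:
    """Drop the first ``n_dummy`` volumes (equilibrium effects)."""
    if vol.n_volumes <= n_dummy:
        raise InsufficientDataError(
            f"series has {vol.n_volumes} volumes, need more than n_dummy={n_dummy}"
        )
    return vol.with_data(vol.data[..., n_dummy:])


def _detect_object(vol: Volume4D, min_coverage: float = 0.01) -> np.ndarray:
    """Largest connected bright component of the temporal-mean image."""
    mean_img = vol.data.mean(axis=3)
    thr = 0.5 * np.percentile(mean_img, 99.5)
    candidate = mean_img > thr
    if thr <= 0 or not candidate.any():
        raise DetectionError("no bright object detected in the mean image")
    labels, n = ndimage.label(candidate)
    if n == 0:
        raise DetectionError("no connected bright object detected")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if mask.sum() < min_coverage * mask.size:
        raise DetectionError(
            "detected object covers "
            f"{mask.sum() / mask.size:.2%} of the FOV (< {min_coverage:.0%}); "
            "image appears to contain noise only"
        )
    return mask


def _central_box(
    shape: Sequence[int],
    center: Sequence[float],
    half_mm: float,
    voxel_size_mm: Sequence[float],
) -> np.ndarray:
    box = np.zeros(tuple(shape), dtype=bool)
    sl = []
    for n, c, v in zip(shape, center, voxel_size_mm):
        h = max(1, int(round(half_mm / v)))
        ci = int(round(c))
        sl.append(slice(max(0, ci - h), min(n, ci + h + 1)))
    box[tuple(sl)] = True
    return box


def define_rois(
    vol: Volume4D,
    phase_axis: str = "y",
    slice_mode: str = "volume",
    background_block: int = 8,
    min_coverage: float = 0.01,
) -> ROISet:
    """Build signal/ghost/background ROIs from the detected phantom.

    The signal ROI is a square (central-slice mode) or cube (volume
    mode) of side half the detected object's in-plane diameter, centred
    on its centre of mass and clipped to the phantom support.  The ghost
    ROI is the signal ROI shifted by half the matrix along the
    phase-encode axis, minus the phantom support; the background ROIs
    are corner blocks outside both phantom and ghost supports.
    """
    if slice_mode not in ("volume", "central-slice"):
        raise ROIError(f"unknown slice_mode {slice_mode!r}")
    phase = _AXES[phase_axis]
    support = _detect_object(vol, min_coverage)
    shape = support.shape
    vox = vol.voxel_size_mm

    com = ndimage.center_of_mass(support)
    # equivalent-disc diameter of the largest axial cross-section
    areas_vox = support.sum(axis=(0, 1))
    area_mm2 = float(areas_vox.max()) * vox[0] * vox[1]
    diameter_mm = 2.0 * np.sqrt(area_mm2 / np.pi)
    half_mm = 0.25 * diameter_mm  # box side = 0.5 * diameter

    signal = _central_box(shape, com, half_mm, vox) & support
    if not signal.any():
        raise ROIError("signal ROI empty after clipping to phantom support")

    ghost_support = np.roll(support, shape[phase] // 2, axis=phase)
    ghost = np.roll(signal, shape[phase] // 2, axis=phase) & ~support
    if not ghost.any():
        raise ROIError("ghost ROI empty after removing phantom overlap")

    b = background_block
    nz_b = min(b, shape[2])
    z0 = max(0, (shape[2] - nz_b) // 2)
    zsl = slice(z0, z0 + nz_b)
    corners = []
    for xs in (slice(0, b), slice(shape[0] - b, shape[0])):
        for ys in (slice(0, b), slice(shape[1] - b, shape[1])):
            blk = np.zeros(shape, dtype=bool)
            blk[xs, ys, zsl] = True
            blk &= ~support & ~ghost_support
            if blk.any():
                corners.append(blk)
    if not corners:
        raise ROIError("all background corner blocks overlap phantom or ghost")

    if slice_mode == "central-slice":
        zc = (shape[2] - 1) // 2
        keep = np.zeros(shape, dtype=bool)
        keep[:, :, zc] = True
        signal = signal & keep
        ghost = ghost & keep
        corners = [c & keep for c in corners if (c & keep).any()]
        if not corners:
            raise ROIError("no background voxels on the central slice")

    return ROISet(
        signal_roi=signal,
        ghost_roi=ghost,
        background_rois=corners,
        slice_mode=slice_mode,
        phantom_support=support,
    )


def _roi_timecourse(series: Volume4D, roi: np.ndarray) -> np.ndarray:
    return series.data[roi].mean(axis=0)


def _detrend_residuals(y: np.ndarray, order: int = 2) -> np.ndarray:
    t = np.arange(y.shape[-1], dtype=float)
    t = (t - t.mean()) / max(t.max() - t.min(), 1.0)
    X = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(X, np.atleast_2d(y).T, rcond=None)
    resid = np.atleast_2d(y).T - X @ coef
    return resid.T.reshape(y.shape)


def compute_snr(series: Volume4D, rois: ROISet) -> float:
    """Signal-to-noise ratio from the temporal-mean image."""
    tmean = series.data.mean(axis=3)
    signal = float(tmean[rois.signal_roi].mean())
    bg = tmean[rois.background_union]
    noise_sd = float(bg.std(ddof=1))
    if noise_sd == 0:
        raise DegenerateInputError("background noise SD is zero; SNR undefined")
    return signal / (noise_sd / RAYLEIGH_FACTOR)


def compute_sfnr(series: Volume4D, rois: ROISet) -> float:
    """Mean signal-to-fluctuation-noise ratio over the signal ROI."""
    t = series.n_volumes
    if t < 10:
        raise InsufficientDataError(f"SFNR needs >= 10 retained volumes, got {t}")
    Y = series.data[rois.signal_roi]  # (V, T)
    resid = _detrend_residuals(Y, order=2)
    sd = resid.std(axis=1, ddof=3)
    if np.any(sd == 0):
        raise DegenerateInputError("zero temporal fluctuation in signal ROI")
    return float((Y.mean(axis=1) / sd).mean())


def compute_psc(series: Volume4D, rois: ROISet) -> float:
    """Percent fluctuation of the ROI-mean time course (order-2 detrend)."""
    t = series.n_volumes
    if t < 10:
        raise InsufficientDataError(f"PSC needs >= 10 retained volumes, got {t}")
    s = _roi_timecourse(series, rois.signal_roi)
    mean = float(s.mean())
    if mean <= 0:
        raise DegenerateInputError("non-positive ROI mean; PSC undefined")
    resid = _detrend_residuals(s, order=2)
    return 100.0 * float(resid.std(ddof=3)) / mean


def compute_psg(series: Volume4D, rois: ROISet) -> float:
    """Percent signal ghosting, background-corrected (may be negative)."""
    tmean = series.data.mean(axis=3)
    ghost = float(tmean[rois.ghost_roi].mean())
    bg = float(tmean[rois.background_union].mean())
    signal = float(tmean[rois.signal_roi].mean())
    if signal == 0:
        raise DegenerateInputError("zero signal mean; PSG undefined")
    return 100.0 * (ghost - bg) / signal


def compute_drift(series: Volume4D, rois: ROISet) -> float:
    """Percent signal drift: order-1 fit endpoint difference over mean."""
    t = series.n_volumes
    if t < 10:
        raise InsufficientDataError(f"drift needs >= 10 retained volumes, got {t}")
    s = _roi_timecourse(series, rois.signal_roi)
    mean = float(s.mean())
    if mean <= 0:
        raise DegenerateInputError("non-positive ROI mean; drift undefined")
    x = np.arange(t, dtype=float)
    slope, intercept = np.polyfit(x, s, 1)
    return 100.0 * float(slope * (x[-1] - x[0])) / mean


def check_placement(
    vol: Volume4D,
    threshold_mm: float = 10.0,
    min_coverage: float = 0.01,
) -> tuple[float, bool]:
    """Distance (mm) of the phantom's centre of mass from the volume centre.

    The volume centre is the voxel floor((n-1)/2) per axis.  The flag is
    set iff the offset strictly exceeds ``threshold_mm``.
    """
    support = _detect_object(vol, min_coverage)
    com = np.asarray(ndimage.center_of_mass(support))
    center = grid_center_voxel(support.shape)
    offset = float(np.linalg.norm((com - center) * vol.voxel_size_mm))
    return offset, offset > threshold_mm


def compute_all(vol: Volume4D, config: QAConfig = QAConfig()) -> QAMetrics:
    """Run the full per-session pipeline with one shared ROI set."""

    def _step(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PhantomQCError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    series = _step("discard_dummy", discard_dummy, vol, config.n_dummy)
    rois = _step(
        "define_rois",
        define_rois,
        series,
        phase_axis=config.phase_axis,
        slice_mode=config.slice_mode,
        background_block=config.background_block,
        min_coverage=config.detection_min_coverage,
    )
    snr = _step("snr", compute_snr, series, rois)
    sfnr = _step("sfnr", compute_sfnr, series, rois)
    psc = _step("psc", compute_psc, series, rois)
    psg = _step("psg", compute_psg, series, rois)
    drift = _step("drift", compute_drift, series, rois)
    offset_mm, flag = _step(
        "placement",
        check_placement,
        series,
        config.threshold_mm,
        config.detection_min_coverage,
    )
    return QAMetrics(
        snr=snr,
        sfnr=sfnr,
        psc=psc,
        psg=psg,
        drift=drift,
        offset_mm=offset_mm,
        flag_misplaced=flag,
        n_volumes_used=series.n_volumes,
    )
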
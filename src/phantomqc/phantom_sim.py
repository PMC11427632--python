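"""Synthetic cylindrical-agar-phantom EPI simulator with known ground truth.

The simulator emulates the QA acquisition stream of a multicenter fMRI
study: a cylindrical agar phantom (default 235 mm long, 111 mm diameter,
long axis parallel to z) imaged with a T2*-weighted EPI sequence after
each subject measurement.  The voxel model is purely signal-statistical::

    S(x, t) = A * m(x) * (1 + d1*tau + d2*tau**2)
              + g * A * m_g(x)
              + eps(x, t)

where ``m`` is the binary cylinder mask, ``m_g`` the mask cyclically
shifted by half the matrix along the phase-encode axis (the N/2 ghost),
``tau = (t - n_dummy) / (T - n_dummy - 1)`` runs from 0 to 1 over the
retained volumes (dummies extrapolate the same line to tau < 0), and
``eps`` is i.i.d. Gaussian thermal noise.  Whole-volume multiplicative
spikes model transient artifacts.  Identical seeds give bit-identical
output.

Relaxation physics (T2*, magnetization transfer), k-space effects, B0
inhomogeneity and multi-coil reconstruction are out of scope: the model
exists to give the metric suite a ground truth to recover.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ROIError, ValidationError
from .io_mri import SessionMeta, Volume4D

__all__ = [
    "PhantomGeometry",
    "GroundTruth",
    "GridSpec",
    "make_phantom_mask",
    "simulate_phantom_series",
    "simulate_monitoring_history",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PhantomGeometry:
    """Cylinder geometry in scanner millimetres.

    Defaults match a 23.5 cm x 11.1 cm agar-filled plastic cylinder
    placed lengthwise along z at the volume centre.
    """

    length_mm: float = 235.0
    diameter_mm: float = 111.0
    axis: str = "z"
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise ValidationError("cylinder length and diameter must be positive")
        if self.axis not in _AXES:
            raise ValidationError(f"axis must be one of {sorted(_AXES)}")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator parameter record; the target of parameter-recovery tests.

    ``drift_frac`` is the fractional linear signal change over the
    retained (post-dummy) series, e.g. 0.015 = +1.5% over the run.
    ``ghost_frac`` is the N/2 ghost amplitude as a fraction of the
    in-phantom signal A.  ``spike_volumes`` maps volume index -> gain.
    """

    signal_mean: float = 1000.0
    noise_sd: float = 10.0
    drift_frac: float = 0.0
    drift_quad_frac: float = 0.0
    ghost_frac: float = 0.0
    spike_volumes: dict[int, float] = field(default_factory=dict)
    n_volumes: int = 100
    n_dummy: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ghost_frac < 1):
            raise ValidationError(f"ghost_frac must be in [0, 1), got {self.ghost_frac}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_volumes <= self.n_dummy:
            raise ValidationError(
                f"n_volumes ({self.n_volumes}) must exceed n_dummy ({self.n_dummy})"
            )
        for t in self.spike_volumes:
            if not (0 <= t < self.n_volumes):
                raise ValidationError(f"spike volume index {t} outside series")


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid: matrix size, voxel size and TR.

    Defaults give a 224 mm in-plane FOV so the default phantom and its
    half-FOV ghost do not overlap.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 4.0)
    tr_s: float = 2.0
    phase_axis: str = "y"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if min(self.voxel_size_mm) <= 0:
            raise ValidationError("voxel sizes must be positive")
        if self.phase_axis not in _AXES:
            raise ValidationError(f"phase_axis must be one of {sorted(_AXES)}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.voxel_size_mm, 1.0))
        return aff


def grid_center_voxel(shape: Sequence[int]) -> np.ndarray:
    """Volume-centre voxel index, floor((n-1)/2) per axis."""
    return np.array([(n - 1) // 2 for n in shape], dtype=int)


def make_phantom_mask(
    shape: Sequence[int],
    voxel_size_mm: Sequence[float],
    geom: PhantomGeometry,
) -> np.ndarray:
    """Binary cylinder mask by voxel-centre test (no rim anti-aliasing).

    A voxel is inside when its centre lies within ``diameter/2`` of the
    cylinder axis and within ``length/2`` of the cylinder centre along
    the axis.  Raises :class:`ROIError` when the cylinder misses the
    grid entirely; warns when the in-plane cross-section is clipped.
    """
    shape = tuple(int(n) for n in shape)
    vox = np.asarray(voxel_size_mm, dtype=float)
    if min(shape) < 2:
        raise ValidationError("grid must span more than 1 voxel per axis")
    center = grid_center_voxel(shape)
    coords = [
        (np.arange(n) - c) * v + off
        for n, c, v, off in zip(
            shape, center, vox, -np.asarray(geom.center_offset_mm, float)
        )
    ]
    ax = _AXES[geom.axis]
    radial = [i for i in range(3) if i != ax]
    r2 = (geom.diameter_mm / 2.0) ** 2
    xs = np.meshgrid(*coords, indexing="ij")
    dist2 = xs[radial[0]] ** 2 + xs[radial[1]] ** 2
    mask = (dist2 <= r2) & (np.abs(xs[ax]) <= geom.length_mm / 2.0)
    if not mask.any():
        raise ROIError("cylinder lies entirely outside the grid (empty mask)")
    # in-plane truncation: mask touching a radial face of the grid
    for i in radial:
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[i] = 0
        sl_hi[i] = shape[i] - 1
        if mask[tuple(sl_lo)].any() or mask[tuple(sl_hi)].any():
            warnings.warn(
                "phantom cross-section truncated by the grid in-plane", stacklevel=2
            )
            break
    return mask


def _tau(n_volumes: int, n_dummy: int) -> np.ndarray:
    t = np.arange(n_volumes, dtype=float)
    denom = max(n_volumes - n_dummy - 1, 1)
    return (t - n_dummy) / denom


def simulate_phantom_series(
    geom: PhantomGeometry = PhantomGeometry(),
    truth: GroundTruth = GroundTruth(),
    grid: GridSpec = GridSpec(),
) -> tuple[Volume4D, GroundTruth]:
    """Simulate one phantom EPI session; returns (volume, ground truth)."""
    mask = make_phantom_mask(grid.shape, grid.voxel_size_mm, geom)
    phase = _AXES[grid.phase_axis]
    ghost_mask = np.roll(mask, grid.shape[phase] // 2, axis=phase)

    tau = _tau(truth.n_volumes, truth.n_dummy)
    trend = 1.0 + truth.drift_frac * tau + truth.drift_quad_frac * tau**2
    A = truth.signal_mean
    base = A * mask[..., None] * trend + truth.ghost_frac * A * ghost_mask[..., None]
    rng = np.random.default_rng(truth.seed)
    data = base + rng.normal(0.0, truth.noise_sd, size=(*grid.shape, truth.n_volumes)) \
        if truth.noise_sd > 0 else np.broadcast_to(base, (*grid.shape, truth.n_volumes)).copy()
    for t, gain in truth.spike_volumes.items():
        data[..., t] *= gain
    vol = Volume4D(
        data=data,
        voxel_size_mm=np.asarray(grid.voxel_size_mm, float),
        tr_s=grid.tr_s,
        affine=grid.affine,
    )
    return vol, truth


def simulate_monitoring_history(
    n_sessions: int,
    baseline: GroundTruth,
    anomalies: Sequence[tuple[int, dict]] = (),
    date_start: _dt.date = _dt.date(2016, 1, 1),
    cadence_days: int = 7,
    seed: int = 0,
    geom: PhantomGeometry = PhantomGeometry(),
    grid: GridSpec = GridSpec(),
    site: str = "SIM",
    scanner_id: str = "scanner-01",
) -> list[tuple[SessionMeta, Volume4D, GroundTruth]]:
    """Simulate a dated stream of phantom sessions with injected anomalies.

    Non-anomalous sessions share the baseline parameters with fresh noise
    per session; each anomaly ``(index, overrides)`` replaces ground-truth
    fields for that session only (e.g. ``{"ghost_frac": 0.05}`` for a
    tenfold ghost increase over a 0.005 baseline).
    """
    idx_seen: set[int] = set()
    for i, _ in anomalies:
        if not (0 <= i < n_sessions):
            raise ConfigurationError(f"anomaly index {i} outside 0..{n_sessions - 1}")
        if i in idx_seen:
            raise ConfigurationError(f"duplicate anomaly index {i}")
        idx_seen.add(i)
    overrides = {i: dict(o) for i, o in anomalies}

    ss = np.random.SeedSequence(seed)
    session_seeds = [int(s) for s in ss.generate_state(n_sessions) >> 1]

    out = []
    for i in range(n_sessions):
        truth = replace(baseline, seed=session_seeds[i], **overrides.get(i, {}))
        vol, truth = simulate_phantom_series(geom=geom, truth=truth, grid=grid)
        meta = SessionMeta(
            site=site,
            scanner_id=scanner_id,
            date=date_start + _dt.timedelta(days=i * cadence_days),
            session_type="phantom",
            subject_or_phantom_id="phantom01",
        )
        out.append((meta, vol, truth))
    return out
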
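"""Pellet-trajectory phase segmentation, per-phase fitting and averaging.

A trajectory is split into loading, rebound and unloading using smoothed
velocity thresholds; loading and unloading are approximated by linear
polynomials and the rebound by a cubic before pointwise averaging across
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Trajectory
from .errors import InputError, SegmentationError

__all__ = [
    "TrajectorySummary",
    "segment_phases",
    "average_trajectories",
    "summarize",
]

DEFAULT_GRID_RATE_HZ = 4500.0


@dataclass(frozen=True)
class TrajectorySummary:
    """Headline quantities extracted from one pellet trajectory."""

    peak_deformation_mm: float
    time_to_peak_ms: float
    initial_velocity_m_per_s: float
    phase_boundaries_s: tuple[float, float]  # (loading end, rebound end)

    def __post_init__(self):
        if self.peak_deformation_mm < 0:
            raise InputError("peak deformation must be non-negative")
        if self.time_to_peak_ms <= 0:
            raise InputError("time to peak must be positive")
        if not self.phase_boundaries_s[0] <= self.phase_boundaries_s[1]:
            raise InputError("phase boundaries must be ordered")


def _smoothed_velocity(traj: Trajectory, window: int = 5) -> np.ndarray:
    v = np.gradient(traj.displacements, traj.times)
    if window > 1:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(v, pad, mode="edge")
        v = np.convolve(padded, kernel, mode="valid")[: v.size]
    return v


def _boundaries(
    traj: Trajectory,
    velocity_fraction: float = 0.2,
    smooth_window: int = 5,
) -> tuple[int, int, int, int]:
    """(first motion, loading end, rebound end, peak) sample indices."""
    if len(traj) < 20:
        raise InputError("segmentation needs at least 20 samples")
    u = traj.displacements
    peak_idx = int(np.argmax(u))
    if peak_idx == 0 or peak_idx == len(traj) - 1:
        raise SegmentationError("no interior displacement maximum")
    peak = u[peak_idx]
    if peak <= 0:
        raise SegmentationError("trajectory never moves into the cord")

    v = _smoothed_velocity(traj, smooth_window)
    moving = np.nonzero(u > 0.005 * peak)[0]
    first_motion = int(moving[0]) if moving.size else 1

    early_n = max(3, (peak_idx - first_motion) // 10)
    early = v[first_motion: min(first_motion + early_n, peak_idx + 1)]
    v_early = float(np.median(early)) if early.size else float(v[first_motion])
    if v_early <= 0:
        raise SegmentationError("no positive early loading velocity")

    below = np.nonzero(v[first_motion:] < velocity_fraction * v_early)[0]
    loading_end = int(below[0]) + first_motion if below.size else peak_idx
    loading_end = min(loading_end, peak_idx)

    rebound_end = len(traj) - 1
    run = 0
    for k in range(peak_idx, len(traj)):
        run = run + 1 if v[k] < 0 else 0
        if run >= 3:
            rebound_end = k - 2
            break
    rebound_end = max(rebound_end, loading_end + 1)
    return first_motion, loading_end, rebound_end, peak_idx


def segment_phases(
    traj: Trajectory,
    velocity_fraction: float = 0.2,
    smooth_window: int = 5,
) -> Trajectory:
    """Label every sample ``loading``, ``rebound`` or ``unloading``.

    Loading runs from first motion until the smoothed velocity drops below
    ``velocity_fraction`` of its early median; rebound brackets the
    displacement maximum until sustained negative velocity; unloading is the
    remainder.
    """
    _, loading_end, rebound_end, _ = _boundaries(traj, velocity_fraction, smooth_window)
    labels = ["loading"] * len(traj)
    for k in range(loading_end, rebound_end + 1):
        labels[k] = "rebound"
    for k in range(rebound_end + 1, len(traj)):
        labels[k] = "unloading"
    return Trajectory(traj.times, traj.displacements, labels)


def _piecewise_polynomial_smooth(traj: Trajectory) -> np.ndarray:
    """Replace phases by their least-squares polynomial approximations.

    Degree 1 for loading and unloading, degree 3 for rebound; continuity at
    the boundaries is deliberately not enforced.
    """
    _, le, re_, _ = _boundaries(traj)
    t, u = traj.times, traj.displacements
    out = u.copy()
    segments = [(0, le, 1), (le, re_ + 1, 3), (re_ + 1, len(traj), 1)]
    for lo, hi, deg in segments:
        if hi - lo < deg + 1:
            continue
        coeffs = np.polyfit(t[lo:hi], u[lo:hi], deg)
        out[lo:hi] = np.polyval(coeffs, t[lo:hi])
    return out


def average_trajectories(
    trajs: list[Trajectory],
    grid_rate_hz: float = DEFAULT_GRID_RATE_HZ,
) -> Trajectory:
    """Pointwise mean of per-phase polynomial approximations of each replicate.

    Trajectories that cannot be segmented are skipped with a warning.  All
    smoothed replicates are resampled onto a common time grid spanning the
    union of the time supports at ``grid_rate_hz``.
    """
    if len(trajs) < 2:
        raise InputError("averaging requires at least two trajectories")
    smoothed = []
    for i, traj in enumerate(trajs):
        try:
            smoothed.append((traj.times, _piecewise_polynomial_smooth(traj)))
        except (SegmentationError, InputError) as exc:
            warnings.warn(f"skipping unsegmentable trajectory {i}: {exc}", stacklevel=2)
    if not smoothed:
        raise InputError("no segmentable trajectories to average")

    t0 = min(t[0] for t, _ in smoothed)
    t1 = max(t[-1] for t, _ in smoothed)
    n = max(2, int(np.floor((t1 - t0) * grid_rate_hz)) + 1)
    grid = t0 + np.arange(n) / grid_rate_hz
    stack = np.vstack([np.interp(grid, t, u) for t, u in smoothed])
    mean = stack.mean(axis=0)
    mean[0] = 0.0  # common grid starts at the (zero-displacement) impact instant
    return Trajectory(grid, mean)


def summarize(
    traj: Trajectory,
    loading_fit_fraction: float = 0.25,
) -> TrajectorySummary:
    """Peak deformation, time to peak and initial velocity of one trajectory.

    The initial velocity is the slope of a degree-1 fit over the first
    ``loading_fit_fraction`` of the loading samples, converted from mm/s to
    m/s.
    """
    first_motion, loading_end, rebound_end, peak_idx = _boundaries(traj)
    t, u = traj.times, traj.displacements
    n_fit = max(2, int(round((loading_end - first_motion + 1) * loading_fit_fraction)))
    lo = max(0, first_motion - 1)  # include the last at-rest sample
    hi = min(lo + n_fit + 1, loading_end + 1)
    slope_mm_s = float(np.polyfit(t[lo:hi], u[lo:hi], 1)[0])
    return TrajectorySummary(
        peak_deformation_mm=float(u[peak_idx]),
        time_to_peak_ms=float((t[peak_idx] - t[first_motion]) * 1e3),
        initial_velocity_m_per_s=slope_mm_s / 1e3,
        phase_boundaries_s=(float(t[loading_end]), float(t[rebound_end])),
    )
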
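"""Shared data containers and their CSV representations.

Curve CSVs carry columns ``strain, stress_pa, rate_per_s``; trajectory CSVs
carry ``time_s, displacement_mm`` (plus an optional ``phase`` column once a
trajectory has been segmented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "StressStrainCurve",
    "Trajectory",
    "read_curve_csv",
    "write_curve_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired strain/stress samples at a labelled nominal strain rate.

    Strain is engineering strain, positive in the loading direction of the
    test (compression curves are exported with positive compressive strain and
    stress).  Stress is nominal, in Pa.
    """

    strain: np.ndarray = field(repr=False)
    stress: np.ndarray = field(repr=False)
    rate: float = 0.0

    def __init__(self, strain, stress, rate: float = 0.0):
        e = np.asarray(strain, dtype=float)
        s = np.asarray(stress, dtype=float)
        if e.ndim != 1 or s.ndim != 1 or e.shape != s.shape:
            raise InputError("strain and stress must be 1-D arrays of equal length")
        if e.size < 2:
            raise InputError("a curve needs at least two samples")
        if np.any(np.diff(e) <= 0):
            raise InputError("strain samples must be strictly increasing")
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)
        object.__setattr__(self, "rate", float(rate))

    def __len__(self) -> int:
        return self.strain.size


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped pellet displacement record (mm into the cord, positive).

    ``phases``, when present, labels each sample ``loading``, ``rebound`` or
    ``unloading``.
    """

    times: np.ndarray = field(repr=False)
    displacements: np.ndarray = field(repr=False)
    phases: tuple[str, ...] | None = None

    def __init__(self, times, displacements, phases=None):
        t = np.asarray(times, dtype=float)
        u = np.asarray(displacements, dtype=float)
        if t.ndim != 1 or u.ndim != 1 or t.shape != u.shape:
            raise InputError("times and displacements must be 1-D, equal length")
        if t.size < 2:
            raise InputError("a trajectory needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise InputError("trajectory times must be strictly increasing")
        if not np.isclose(u[0], 0.0, atol=1e-12):
            raise InputError("trajectory must start at zero displacement")
        if phases is not None:
            phases = tuple(str(p) for p in phases)
            if len(phases) != t.size:
                raise InputError("phase labels must match the number of samples")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacements", u)
        object.__setattr__(self, "phases", phases)

    def __len__(self) -> int:
        return self.times.size


def write_curve_csv(curve: StressStrainCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "strain": curve.strain,
            "stress_pa": curve.stress,
            "rate_per_s": np.full(len(curve), curve.rate),
        }
    ).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> StressStrainCurve:
    df = pd.read_csv(path)
    missing = {"strain", "stress_pa"} - set(df.columns)
    if missing:
        raise InputError(f"curve CSV {path} missing columns: {sorted(missing)}")
    rate = float(df["rate_per_s"].iloc[0]) if "rate_per_s" in df.columns else 0.0
    return StressStrainCurve(df["strain"].to_numpy(), df["stress_pa"].to_numpy(), rate)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    data = {"time_s": traj.times, "displacement_mm": traj.displacements}
    if traj.phases is not None:
        data["phase"] = list(traj.phases)
    pd.DataFrame(data).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    missing = {"time_s", "displacement_mm"} - set(df.columns)
    if missing:
        raise InputError(f"trajectory CSV {path} missing columns: {sorted(missing)}")
    phases = df["phase"].tolist() if "phase" in df.columns else None
    return Trajectory(
        df["time_s"].to_numpy(), df["displacement_mm"].to_numpy(), phases
    )
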
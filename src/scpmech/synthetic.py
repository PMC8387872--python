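"""Seeded generators for every input the analysis pipeline consumes.

Stress curves get multiplicative log-normal noise (scatter scales with the
stress level); displacement traces get additive Gaussian noise; mesh
convergence series follow a power law.  Every generator is a deterministic
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constitutive import OgdenModel, QLVMaterial
from .data import StressStrainCurve, Trajectory
from .errors import InputError
from .simulation import (
    ImpactConfig,
    RampProtocol,
    simulate_pellet_impact,
    simulate_pia_tension,
    simulate_ramp_test,
)

__all__ = [
    "CurveNoiseModel",
    "generate_cord_curves",
    "generate_pia_curve",
    "generate_trajectory_set",
    "generate_convergence_series",
]


@dataclass(frozen=True)
class CurveNoiseModel:
    """Multiplicative log-normal scatter applied per curve sample."""

    relative_sd: float = 0.0
    specimen_count: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0:
            raise InputError("relative_sd must be non-negative")
        if self.specimen_count < 1:
            raise InputError("specimen_count must be >= 1")


def _apply_lognormal(stress: np.ndarray, sd: float, rng: np.random.Generator):
    if sd == 0.0:
        return stress.copy()
    # mean-corrected so E[factor] = 1 and specimen means converge to truth
    factors = np.exp(rng.normal(-0.5 * sd * sd, sd, size=stress.shape))
    return stress * factors


def generate_cord_curves(
    material: QLVMaterial,
    rates=(0.32, 2.83, 25.44, 77.22),
    max_strain: float = 0.4,
    noise: CurveNoiseModel = CurveNoiseModel(),
    sample_count: int = 200,
) -> list[StressStrainCurve]:
    """Noisy compression curves, one per (rate, specimen), seeded.

    Returns ``specimen_count`` curves per rate, ordered rate-major.
    """
    if any(r <= 0 for r in rates):
        raise InputError("strain rates must be positive")
    rng = np.random.default_rng(noise.seed)
    curves = []
    for rate in rates:
        protocol = RampProtocol(rate, max_strain, "compression", sample_count)
        clean = simulate_ramp_test(material, protocol)
        for _ in range(noise.specimen_count):
            stress = _apply_lognormal(clean.stress, noise.relative_sd, rng)
            curves.append(StressStrainCurve(clean.strain, stress, rate=rate))
    return curves


def generate_pia_curve(
    model: OgdenModel,
    rate: float = 0.05,
    max_strain: float = 0.4,
    noise: CurveNoiseModel = CurveNoiseModel(),
    sample_count: int = 200,
) -> StressStrainCurve:
    """Noisy quasi-static tension curve for the pia membrane, seeded."""
    protocol = RampProtocol(rate, max_strain, "tension", sample_count)
    clean = simulate_pia_tension(model, protocol)
    rng = np.random.default_rng(noise.seed)
    stress = _apply_lognormal(clean.stress, noise.relative_sd, rng)
    return StressStrainCurve(clean.strain, stress, rate=rate)


def generate_trajectory_set(
    config: ImpactConfig,
    n: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    velocity_jitter: float = 0.0,
    sampling_rate_hz: float = 4500.0,
    dt: float = 1e-6,
) -> list[Trajectory]:
    """Replicate pellet trajectories from the surrogate, resampled and noisy.

    Each replicate gets a multiplicative impact-velocity perturbation drawn
    from ``N(1, velocity_jitter)`` and additive Gaussian displacement noise
    with standard deviation ``noise_sd`` (mm) on every sample after impact.
    """
    if n < 1:
        raise InputError("need at least one replicate")
    if noise_sd < 0 or velocity_jitter < 0:
        raise InputError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        factor = 1.0 + (rng.normal(0.0, velocity_jitter) if velocity_jitter > 0 else 0.0)
        factor = max(factor, 0.05)
        cfg = replace(config, impact_velocity=config.impact_velocity * factor)
        traj = simulate_pellet_impact(cfg, dt=dt)
        n_grid = max(2, int(np.floor(traj.times[-1] * sampling_rate_hz)) + 1)
        grid = np.arange(n_grid) / sampling_rate_hz
        u = np.interp(grid, traj.times, traj.displacements)
        if noise_sd > 0:
            u[1:] += rng.normal(0.0, noise_sd, size=u.size - 1)
            u[1:] = np.maximum(u[1:], 0.0)
        out.append(Trajectory(grid, u))
    return out


def generate_convergence_series(
    limit_value: float,
    order: float,
    coefficient: float,
    mesh_sizes=(0.8, 0.4, 0.2),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law mesh-refinement series ``f(h) = limit + coefficient * h**order``.

    Optional multiplicative Gaussian noise with standard deviation
    ``noise_sd``.
    """
    if order <= 0:
        raise InputError("convergence order must be positive")
    h = np.asarray(mesh_sizes, dtype=float)
    f = limit_value + coefficient * h**order
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + rng.normal(0.0, noise_sd, size=f.shape))
    return h, f
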
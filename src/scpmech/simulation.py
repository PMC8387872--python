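"""Homogeneous single-element test reproduction and a pellet-impact surrogate.

``simulate_ramp_test`` and ``simulate_pia_tension`` reproduce constant-rate
uniaxial tests on a homogeneous material point.  ``simulate_pellet_impact`` is
an explicitly reduced-order stand-in for a full 3-D impact simulation: a
single-degree-of-freedom pellet decelerating against a nonlinear
viscoelastic foundation (the cord) plus a membrane tension term (the pia).
Only orderings, sensitivities and conservation properties of the surrogate
are meaningful - not absolute displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constitutive import (
    OgdenModel,
    QLVMaterial,
    StrainHistory,
    qlv_stress,
    uniaxial_nominal_stress,
)
from .data import StressStrainCurve, Trajectory
from .errors import InputError, SimulationError

__all__ = [
    "RampProtocol",
    "ImpactConfig",
    "simulate_ramp_test",
    "simulate_pia_tension",
    "simulate_pellet_impact",
    "pia_sensitivity_sweep",
    "cylinder_cross_section_area",
    "default_impact_config",
]


def cylinder_cross_section_area(diameter_mm: float) -> float:
    """Cross-sectional area (mm^2) of a cylindrical indenter of given diameter."""
    if diameter_mm <= 0:
        raise InputError("diameter must be positive")
    return math.pi * (diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class RampProtocol:
    """Constant engineering-strain-rate uniaxial test protocol."""

    engineering_strain_rate: float
    max_engineering_strain: float
    mode: str = "compression"
    sample_count: int = 200

    def __post_init__(self):
        if self.engineering_strain_rate <= 0:
            raise InputError("strain rate must be positive")
        if not 0.0 < self.max_engineering_strain < 1.0:
            raise InputError("max engineering strain must lie in (0, 1)")
        if self.mode not in ("compression", "tension"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.sample_count < 2:
            raise InputError("sample_count must be >= 2")

    @property
    def duration(self) -> float:
        """Ramp duration in seconds, ``max_strain / rate``."""
        return self.max_engineering_strain / self.engineering_strain_rate


@dataclass(frozen=True)
class ImpactConfig:
    """Configuration of the reduced-order transverse pellet impact."""

    pellet_mass: float  # kg
    pellet_area: float  # mm^2
    impact_velocity: float  # m/s
    cord_height: float  # mm, anterior-posterior dimension
    pia_thickness: float  # mm
    cord_material: QLVMaterial
    pia_material: OgdenModel
    axial_prestrain: float = 0.0

    def __post_init__(self):
        if self.pellet_mass <= 0 or self.pellet_area <= 0 or self.cord_height <= 0:
            raise InputError("mass, area and cord height must be positive")
        if self.impact_velocity < 0:
            raise InputError("impact velocity must be non-negative")
        if self.pia_thickness < 0:
            raise InputError("pia thickness must be non-negative")
        if self.axial_prestrain < 0:
            raise InputError("axial prestrain must be non-negative")


def default_impact_config(**overrides) -> ImpactConfig:
    """Reference impact configuration: 7 g pellet, 157 mm^2, 4.5 m/s, 8% prestrain."""
    from . import materials

    base = dict(
        pellet_mass=0.007,
        pellet_area=157.0,
        impact_velocity=4.5,
        cord_height=8.0,
        pia_thickness=0.13,
        cord_material=materials.CORD_QLV,
        pia_material=materials.PIA_OGDEN,
        axial_prestrain=0.08,
    )
    base.update(overrides)
    return ImpactConfig(**base)


def simulate_ramp_test(
    material: QLVMaterial, protocol: RampProtocol
) -> StressStrainCurve:
    """Constant-rate uniaxial ramp through the QLV material.

    Returns engineering strain (positive in the loading direction) against
    nominal stress (Pa, positive in the loading direction) on
    ``[0, max_strain]``.
    """
    sign = -1.0 if protocol.mode == "compression" else 1.0
    times = np.linspace(0.0, protocol.duration, protocol.sample_count)
    strains = protocol.engineering_strain_rate * times
    history = StrainHistory(times, 1.0 + sign * strains)
    trace = qlv_stress(material, history)
    # export with positive strain/stress regardless of loading direction
    return StressStrainCurve(
        strains, sign * trace.stresses, rate=protocol.engineering_strain_rate
    )


def simulate_pia_tension(model: OgdenModel, protocol: RampProtocol) -> StressStrainCurve:
    """Rate-independent hyperelastic tension curve for the pia membrane."""
    if protocol.mode != "tension":
        raise InputError("pia tension simulation requires mode='tension'")
    strains = np.linspace(0.0, protocol.max_engineering_strain, protocol.sample_count)
    stresses = uniaxial_nominal_stress(model, 1.0 + strains)
    return StressStrainCurve(strains, stresses, rate=protocol.engineering_strain_rate)


def simulate_pellet_impact(
    config: ImpactConfig,
    dt: float = 1e-6,
    t_max: float = 0.1,
    return_details: bool = False,
):
    """Integrate the 1-DOF pellet against the cord foundation + pia membrane.

    The transverse engineering strain is ``u / cord_height``; the cord resists
    with its QLV nominal stress (per-term exponential recurrence, advanced at
    the integration step) times the pellet area, the pia with two inclined
    tension strips anchored one cord height from the pellet edge.  Contact is
    non-adhesive: both force contributions are clamped at >= 0.  Semi-implicit
    Euler, fixed ``dt``; the run ends when the pellet separates (returns to
    zero displacement) or at ``t_max``.
    """
    if dt <= 0:
        raise InputError("dt must be positive")

    m = config.pellet_mass
    area = config.pellet_area * 1e-6  # m^2
    h = config.cord_height * 1e-3  # m
    t_pia = config.pia_thickness * 1e-3  # m
    anchor = h  # strips anchored one cord height from the pellet edge
    pellet_width = 2.0 * math.sqrt(config.pellet_area / math.pi) * 1e-3  # m
    prestretch = 1.0 + config.axial_prestrain

    cord = config.cord_material
    elastic = cord.elastic
    prony = cord.relaxation
    g_inf = prony.long_term_fraction
    decay = np.exp(-prony.rates * dt)
    inject = prony.coefficients * np.exp(-prony.rates * dt / 2.0)
    states = np.zeros(len(prony.terms))
    normalized = cord.formulation == "normalized"

    u, v = 0.0, config.impact_velocity
    sig_e_prev = 0.0
    n_max = int(round(t_max / dt)) + 1
    times = np.empty(n_max)
    disps = np.empty(n_max)
    forces = np.empty(n_max)
    vels = np.empty(n_max)
    times[0], disps[0], forces[0], vels[0] = 0.0, 0.0, 0.0, v

    k = 1
    t = 0.0
    while k < n_max:
        t += dt
        # cord foundation stress at current displacement (QLV recurrence)
        eps = u / h
        if eps >= 1.0:
            raise SimulationError("pellet reached full compression of the cord")
        lam = 1.0 - eps
        sig_e = sum(  # scalar fast path of uniaxial_nominal_stress
            mu * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
            for mu, alpha in elastic.terms
        )
        states = decay * states + inject * (sig_e - sig_e_prev)
        sig_e_prev = sig_e
        sigma = (g_inf * sig_e if normalized else sig_e) + states.sum()
        f_cord = max(-sigma, 0.0) * area

        # pia membrane: two inclined strips in tension
        f_pia = 0.0
        if t_pia > 0.0 and u > 0.0:
            arc = math.sqrt(anchor * anchor + u * u)
            lam_pia = prestretch * arc / anchor
            sig_pia = sum(
                mu * (lam_pia ** (alpha - 1.0) - lam_pia ** (-alpha / 2.0 - 1.0))
                for mu, alpha in config.pia_material.terms
            )
            if sig_pia > 0.0:
                f_pia = 2.0 * sig_pia * (t_pia * pellet_width) * (u / arc)

        force = f_cord + f_pia
        v -= force / m * dt
        u += v * dt
        if u < 0.0:
            break
        times[k], disps[k], forces[k], vels[k] = t, u * 1e3, force, v
        k += 1

    traj = Trajectory(times[:k], disps[:k])
    if not return_details:
        return traj

    # force is held constant over each step, so the work along the discrete
    # path is F_k * du_k (not a trapezoid of the recorded samples)
    work = np.concatenate(
        ([0.0], np.cumsum(forces[1:k] * np.diff(disps[:k]) * 1e-3))
    )
    details = {
        "contact_force_n": forces[:k].copy(),
        "absorbed_work_j": work,
        "velocity_m_per_s": vels[:k].copy(),
        "kinetic_energy_j": 0.5 * m * vels[:k] ** 2,
        "initial_kinetic_energy_j": 0.5 * m * config.impact_velocity**2,
    }
    return traj, details


def pia_sensitivity_sweep(
    base: ImpactConfig, thicknesses, dt: float = 1e-6
) -> pd.DataFrame:
    """Peak pellet displacement for each pia thickness (mm), deterministic."""
    thicknesses = list(thicknesses)
    if not thicknesses:
        raise InputError("thickness list must not be empty")
    rows = []
    for th in thicknesses:
        traj = simulate_pellet_impact(replace(base, pia_thickness=float(th)), dt=dt)
        rows.append({"pia_thickness_mm": float(th),
                     "peak_displacement_mm": float(traj.displacements.max())})
    return pd.DataFrame(rows)
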
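"""Ogden hyperelasticity and quasi-linear viscoelastic (QLV) stress evaluation.

The elastic backbone is a modified Ogden strain-energy density with a
hydrostatic penalty term; the time dependence is a normalized Prony series
combined with the elastic stress through a Boltzmann hereditary integral.
Uniaxial loading is treated with the incompressible idealization, for which
the nominal (first Piola) stress has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import DomainError, InputError

__all__ = [
    "OgdenModel",
    "PronySeries",
    "QLVMaterial",
    "StrainHistory",
    "StressTrace",
    "ogden_strain_energy",
    "uniaxial_nominal_stress",
    "reduced_relaxation",
    "qlv_stress",
    "small_strain_moduli",
]

# |alpha * ln(lambda)| beyond this would overflow float64; treated as a domain
# violation rather than silently clamped.
_EXP_CAP = 700.0


@dataclass(frozen=True)
class OgdenModel:
    """Isotropic Ogden hyperelastic model.

    Parameters
    ----------
    terms
        Sequence of ``(mu_i, alpha_i)`` pairs; ``mu_i`` in Pa, ``alpha_i``
        dimensionless and non-zero.
    poisson_ratio
        Small-strain Poisson ratio, strictly below 0.5 so the bulk modulus
        stays finite.
    """

    terms: tuple[tuple[float, float], ...]
    poisson_ratio: float = 0.499

    def __init__(self, terms: Sequence[Sequence[float]], poisson_ratio: float = 0.499):
        object.__setattr__(self, "terms", tuple((float(m), float(a)) for m, a in terms))
        object.__setattr__(self, "poisson_ratio", float(poisson_ratio))
        if not self.terms:
            raise DomainError("OgdenModel requires at least one (mu, alpha) term")
        for mu, alpha in self.terms:
            if mu <= 0:
                raise DomainError(f"mu must be positive, got {mu}")
            if alpha == 0:
                raise DomainError("alpha must be non-zero")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise DomainError(
                f"poisson_ratio must lie in (0, 0.5), got {self.poisson_ratio}"
            )
        if self.shear_modulus <= 0:
            raise DomainError("small-strain shear modulus sum(mu*alpha)/2 must be > 0")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus ``G0 = sum(mu_i * alpha_i) / 2`` in Pa."""
        return 0.5 * sum(mu * alpha for mu, alpha in self.terms)


@dataclass(frozen=True)
class PronySeries:
    """Normalized viscoelastic relaxation terms ``(G_i, beta_i)``.

    ``G_i`` are dimensionless fractions of the instantaneous modulus with
    ``sum(G_i) <= 1``; ``beta_i`` are decay rates in 1/s, strictly increasing.
    The long-term fraction is ``g_inf = 1 - sum(G_i)``.
    """

    terms: tuple[tuple[float, float], ...]

    def __init__(self, terms: Sequence[Sequence[float]]):
        object.__setattr__(self, "terms", tuple((float(g), float(b)) for g, b in terms))
        if not self.terms:
            raise DomainError("PronySeries requires at least one (G, beta) term")
        total = 0.0
        prev_beta = 0.0
        for g, beta in self.terms:
            if not 0.0 < g <= 1.0:
                raise DomainError(f"Prony coefficient G must lie in (0, 1], got {g}")
            if beta <= 0:
                raise DomainError(f"Prony decay rate beta must be > 0, got {beta}")
            if beta <= prev_beta:
                raise DomainError("Prony decay rates must be strictly increasing")
            prev_beta = beta
            total += g
        if total > 1.0 + 1e-12:
            raise DomainError(f"sum of Prony coefficients must be <= 1, got {total}")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([g for g, _ in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([b for _, b in self.terms])

    @property
    def long_term_fraction(self) -> float:
        """``g_inf = 1 - sum(G_i)``, the fully relaxed modulus fraction."""
        return max(0.0, 1.0 - float(self.coefficients.sum()))


@dataclass(frozen=True)
class QLVMaterial:
    """Quasi-linear viscoelastic material: Ogden elasticity + Prony relaxation."""

    elastic: OgdenModel
    relaxation: PronySeries
    # "normalized": sigma = g_inf*sigE + overstress, instantaneous response = sigE.
    # "overstress": sigma = sigE + overstress, quasi-static response = sigE.
    formulation: Literal["normalized", "overstress"] = "normalized"

    def __post_init__(self):
        if self.formulation not in ("normalized", "overstress"):
            raise InputError(f"unknown QLV formulation: {self.formulation!r}")


@dataclass(frozen=True)
class StrainHistory:
    """Uniaxial stretch history ``lambda(t)``; ``lambda = 1`` at rest."""

    times: np.ndarray
    stretches: np.ndarray

    def __init__(self, times, stretches):
        t = np.asarray(times, dtype=float)
        lam = np.asarray(stretches, dtype=float)
        if t.ndim != 1 or lam.ndim != 1 or t.shape != lam.shape:
            raise InputError("times and stretches must be 1-D arrays of equal length")
        if t.size < 2:
            raise InputError("a strain history needs at least two samples")
        if t[0] != 0.0:
            raise InputError("strain history must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.isclose(lam[0], 1.0):
            raise InputError("history must start from the reference state lambda = 1")
        if np.any(lam <= 0):
            raise DomainError("all stretches must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "stretches", lam)


@dataclass(frozen=True)
class StressTrace:
    """Nominal stress samples aligned with the driving strain history."""

    times: np.ndarray = field(repr=False)
    stresses: np.ndarray = field(repr=False)

    def __init__(self, times, stresses):
        t = np.asarray(times, dtype=float)
        s = np.asarray(stresses, dtype=float)
        if t.shape != s.shape:
            raise InputError("times and stresses must have matching shapes")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "stresses", s)


def _safe_pow(lam: np.ndarray, exponent: float) -> np.ndarray:
    """``lam ** exponent`` with overflow treated as a domain error."""
    logs = exponent * np.log(lam)
    if np.any(np.abs(logs) > _EXP_CAP):
        raise DomainError(
            "stretch/exponent combination outside representable range "
            f"(|alpha*ln(lambda)| > {_EXP_CAP:.0f})"
        )
    return np.exp(logs)


def ogden_strain_energy(
    model: OgdenModel,
    stretches: Sequence[float],
    relative_volume: float = 1.0,
) -> float:
    """Strain-energy density (Pa) of the modified Ogden form.

    The deviatoric principal stretches ``lam* = lam_k * J**(-1/3)`` enter the
    Ogden sum; the hydrostatic part is ``0.5 * K * (J - 1)**2`` with the bulk
    modulus mapped from ``(G0, nu)``.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise InputError("expected exactly three principal stretches")
    if np.any(lam <= 0):
        raise DomainError("principal stretches must be positive")
    j = float(relative_volume)
    if j <= 0:
        raise DomainError("relative volume must be positive")

    lam_dev = lam * j ** (-1.0 / 3.0)
    w = 0.0
    for mu, alpha in model.terms:
        w += (mu / alpha) * (float(np.sum(_safe_pow(lam_dev, alpha))) - 3.0)
    _, _, bulk = small_strain_moduli(model)
    return w + 0.5 * bulk * (j - 1.0) ** 2


def uniaxial_nominal_stress(model: OgdenModel, stretch) -> float | np.ndarray:
    """Nominal (first Piola) uniaxial stress under the incompressible idealization.

    ``P(lam) = sum_i mu_i * (lam**(alpha_i - 1) - lam**(-alpha_i/2 - 1))``;
    zero at ``lam = 1``, negative in compression (``lam < 1``).
    """
    lam = np.asarray(stretch, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    p = np.zeros_like(lam)
    for mu, alpha in model.terms:
        p += mu * (_safe_pow(lam, alpha - 1.0) - _safe_pow(lam, -alpha / 2.0 - 1.0))
    return float(p[0]) if scalar else p


def reduced_relaxation(prony: PronySeries, t) -> float | np.ndarray:
    """Normalized reduced relaxation ``g(t) = g_inf + sum G_i * exp(-beta_i t)``.

    ``g(0) = 1`` exactly and ``g(inf) = 1 - sum(G_i)``.
    """
    tt = np.asarray(t, dtype=float)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    if np.any(tt < 0):
        raise DomainError("reduced relaxation is defined for t >= 0 only")
    g = np.full_like(tt, prony.long_term_fraction)
    for gi, beta in prony.terms:
        g = g + gi * np.exp(-beta * tt)
    return float(g[0]) if scalar else g


def small_strain_moduli(model: OgdenModel) -> tuple[float, float, float]:
    """Small-strain ``(shear G0, Young E, bulk K)`` moduli in Pa."""
    g0 = model.shear_modulus
    nu = model.poisson_ratio
    if nu >= 0.5:
        raise DomainError("Poisson ratio must be < 0.5 for a finite bulk modulus")
    young = 2.0 * g0 * (1.0 + nu)
    bulk = 2.0 * g0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
    return g0, young, bulk


def _resample_history(
    history: StrainHistory, max_beta: float, min_points: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform fine grid satisfying ``max(beta) * dt <= 0.1`` and a point floor."""
    t_end = history.times[-1]
    n = max(min_points, history.times.size)
    if max_beta > 0:
        n = max(n, int(np.ceil(t_end * max_beta / 0.1)) + 1)
    t_fine = np.linspace(0.0, t_end, n)
    lam_fine = np.interp(t_fine, history.times, history.stretches)
    return t_fine, lam_fine


def qlv_stress(
    material: QLVMaterial,
    history: StrainHistory,
    min_points: int = 2000,
) -> StressTrace:
    """Hereditary-integral QLV stress response to a uniaxial stretch history.

    The convolution of the elastic stress increments with the Prony kernel is
    evaluated by a per-term exponential recurrence with a midpoint kernel,

        h_i[k] = exp(-beta_i dt) h_i[k-1] + G_i exp(-beta_i dt / 2) dSigE[k],

    on an internally refined uniform grid, then sampled back onto the input
    times.  In the default normalized formulation the instantaneous response
    equals the elastic stress and the equilibrium response is
    ``(1 - sum G_i)`` times it.
    """
    prony = material.relaxation
    betas = prony.rates
    t_fine, lam_fine = _resample_history(history, float(betas.max()), min_points)
    dt = t_fine[1] - t_fine[0]

    sig_e = uniaxial_nominal_stress(material.elastic, lam_fine)
    d_sig = np.diff(sig_e, prepend=sig_e[0])  # dSigE[0] = 0 (starts at rest)

    overstress = np.zeros_like(sig_e)
    for gi, beta in prony.terms:
        a = np.exp(-beta * dt)
        b = gi * np.exp(-beta * dt / 2.0)
        overstress += lfilter([b], [1.0, -a], d_sig)

    if material.formulation == "normalized":
        sigma = prony.long_term_fraction * sig_e + overstress
    else:  # overstress formulation: viscous part rides on the full elastic stress
        sigma = sig_e + overstress

    out = np.interp(history.times, t_fine, sigma)
    out[0] = 0.0
    return StressTrace(history.times, out)
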
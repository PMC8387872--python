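"""Constrained multi-rate parameter identification for cord and pia models.

The cord fit recovers one-term Ogden constants and normalized Prony
coefficients from compression curves at several strain rates, with all rates
weighted equally and the constraint ``sum(G_i) <= 1`` enforced through a
stick-breaking reparameterization (so the optimizer cannot leave the
simplex).  The pia fit recovers a single-term Ogden model from one
quasi-static tension curve by maximizing the coefficient of determination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constitutive import OgdenModel, PronySeries, QLVMaterial
from .data import StressStrainCurve
from .errors import InputError
from .metrics import r_squared, rmse
from .simulation import RampProtocol, simulate_ramp_test, simulate_pia_tension

__all__ = ["FitConfig", "FitResult", "curve_discrepancy", "fit_cord_qlv", "fit_pia_ogden"]

_G_FLOOR = 1e-6  # keeps every Prony coefficient strictly positive


@dataclass(frozen=True)
class FitConfig:
    """Settings for the cord and pia fits."""

    initial_mu: float = 100.0  # Pa
    initial_alpha: float = 5.0
    initial_g: tuple[float, ...] = (0.25, 0.25, 0.25)
    betas: tuple[float, ...] = (2.0, 13.0, 406.0)  # 1/s
    fix_betas: bool = True
    tolerance: float = 0.005  # relative curve-difference convergence threshold
    weights: tuple[float, ...] | None = None  # per-rate; equal when None
    seed: int = 0
    stage_mode: str = "staged"  # "staged" | "joint"
    polish: bool = True  # joint refinement after the staged passes
    max_outer_iter: int = 6
    poisson_ratio: float = 0.499
    mode: str = "compression"

    def __post_init__(self):
        if self.tolerance <= 0:
            raise InputError("tolerance must be positive")
        if self.stage_mode not in ("staged", "joint"):
            raise InputError(f"unknown stage mode {self.stage_mode!r}")
        if self.initial_mu <= 0 or self.initial_alpha == 0:
            raise InputError("initial Ogden guess must have mu > 0, alpha != 0")
        if len(self.initial_g) != len(self.betas):
            raise InputError("initial_g and betas must have equal length")
        if any(g <= 0 for g in self.initial_g):
            raise InputError("initial Prony coefficients must be positive")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise InputError("weights must be positive")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a calibration run."""

    material: QLVMaterial | OgdenModel
    objective: float
    per_rate_r2: dict = field(default_factory=dict)
    per_rate_rmse: dict = field(default_factory=dict)
    converged: bool = False
    iterations: int = 0
    seed: int = 0
    message: str = ""


def curve_discrepancy(
    model_curve: StressStrainCurve,
    target_curve: StressStrainCurve,
    grid_points: int = 200,
) -> float:
    """Normalized distance between two curves on a common strain grid.

    Equal-weighted combination of the normalized absolute area difference
    ``|int (sig_m - sig_t) de| / int |sig_t| de`` and a pointwise relative L2
    term; zero iff the curves coincide on the grid.
    """
    lo = max(model_curve.strain[0], target_curve.strain[0])
    hi = min(model_curve.strain[-1], target_curve.strain[-1])
    if hi <= lo:
        raise InputError("curves have disjoint strain ranges")
    grid = np.linspace(lo, hi, grid_points)
    s_m = np.interp(grid, model_curve.strain, model_curve.stress)
    s_t = np.interp(grid, target_curve.strain, target_curve.stress)

    denom_area = float(np.trapezoid(np.abs(s_t), grid))
    denom_l2 = float(np.sqrt(np.mean(s_t**2)))
    if denom_area == 0.0 or denom_l2 == 0.0:
        # degenerate all-zero target: fall back to absolute distance
        return float(np.sqrt(np.mean((s_m - s_t) ** 2)))
    area_term = abs(float(np.trapezoid(s_m - s_t, grid))) / denom_area
    l2_term = float(np.sqrt(np.mean((s_m - s_t) ** 2))) / denom_l2
    return 0.5 * area_term + 0.5 * l2_term


# --- stick-breaking parameterization of the Prony simplex -------------------

def _g_to_sticks(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    total = g.sum()
    if total >= 1.0:  # project an infeasible start into the simplex
        g = g / total * 0.99
    sticks = np.empty_like(g)
    remaining = 1.0
    for i, gi in enumerate(g):
        sticks[i] = np.clip(gi / remaining, _G_FLOOR, 1.0 - _G_FLOOR)
        remaining -= gi
    return sticks


def _sticks_to_g(sticks: np.ndarray) -> np.ndarray:
    g = np.empty_like(sticks)
    remaining = 1.0
    for i, t in enumerate(sticks):
        g[i] = max(t * remaining, _G_FLOOR)
        remaining -= g[i]
    return g


def _simulate_at(
    material: QLVMaterial, target: StressStrainCurve, mode: str
) -> StressStrainCurve:
    protocol = RampProtocol(
        engineering_strain_rate=target.rate,
        max_engineering_strain=float(target.strain[-1]),
        mode=mode,
        sample_count=max(len(target), 2),
    )
    return simulate_ramp_test(material, protocol)


def _residuals(
    material: QLVMaterial,
    targets: list[StressStrainCurve],
    weights: np.ndarray,
    mode: str,
) -> np.ndarray:
    parts = []
    for curve, w in zip(targets, weights):
        model = _simulate_at(material, curve, mode)
        s_m = np.interp(curve.strain, model.strain, model.stress)
        scale = float(np.max(np.abs(curve.stress))) or 1.0
        parts.append(np.sqrt(w) * (s_m - curve.stress) / scale)
    return np.concatenate(parts)


def fit_cord_qlv(curves: list[StressStrainCurve], config: FitConfig) -> FitResult:
    """Multi-rate QLV fit with equal weighting and ``sum(G_i) <= 1``.

    Staged mode first fits ``(mu, alpha)`` against the slowest-rate curve,
    then the Prony coefficients against all rates, alternating until the
    objective stops improving, with an optional joint polish.  Joint mode
    refines all parameters together from the start.  If the first pass does
    not reach the convergence tolerance, a few deterministic restarts with
    jittered initial guesses (seeded by ``config.seed``) are attempted and
    the best objective kept.  Optimizer failure yields a non-converged
    :class:`FitResult` rather than an exception.
    """
    if len(curves) < 2:
        raise InputError("need curves at two or more distinct rates")
    rates = [c.rate for c in curves]
    if len(set(rates)) < 2:
        raise InputError("need at least two distinct strain rates")
    curves = sorted(curves, key=lambda c: c.rate)

    n_rates = len(curves)
    weights = (
        np.full(n_rates, 1.0 / n_rates)
        if config.weights is None
        else np.asarray(config.weights, dtype=float)
    )
    if weights.size != n_rates:
        raise InputError("one weight per rate required")

    best = _fit_cord_once(curves, config, weights)
    if not best.converged:
        rng = np.random.default_rng(config.seed)
        for _ in range(4):
            jitter = lambda v: float(v * np.exp(rng.uniform(-0.5, 0.5)))
            restart = dataclasses.replace(
                config,
                initial_mu=jitter(config.initial_mu),
                initial_alpha=jitter(config.initial_alpha),
                initial_g=tuple(min(jitter(g), 0.9) for g in config.initial_g),
            )
            res = _fit_cord_once(curves, restart, weights)
            if res.objective < best.objective:
                best = res
            if best.converged:
                break
    return best


def _fit_cord_once(
    curves: list[StressStrainCurve], config: FitConfig, weights: np.ndarray
) -> FitResult:
    betas = np.asarray(config.betas, dtype=float)
    log_mu = np.log(config.initial_mu)
    alpha = config.initial_alpha
    sticks = _g_to_sticks(np.asarray(config.initial_g, dtype=float))
    log_betas = np.log(betas)

    def build(log_mu, alpha, sticks, log_betas) -> QLVMaterial:
        g = _sticks_to_g(np.asarray(sticks))
        b = np.exp(np.asarray(log_betas))
        order = np.argsort(b)
        prony = PronySeries(list(zip(g[order], b[order])))
        ogden = OgdenModel([(np.exp(log_mu), alpha)], config.poisson_ratio)
        return QLVMaterial(elastic=ogden, relaxation=prony)

    n_g = sticks.size
    iterations = 0
    message = ""
    ok = True

    def run_ls(unpack, x0, bounds, targets, w):
        nonlocal iterations, message, ok
        def fun(x):
            return _residuals(build(*unpack(x)), targets, w, config.mode)
        try:
            res = least_squares(fun, x0, bounds=bounds, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=400)
            iterations += res.nfev
            if res.status <= 0:
                ok = False
                message = res.message
            return res.x
        except Exception as exc:  # pragma: no cover - defensive
            ok = False
            message = str(exc)
            return x0

    stick_lo, stick_hi = _G_FLOOR, 1.0 - _G_FLOOR

    if config.stage_mode == "staged":
        prev_obj = np.inf
        for _ in range(config.max_outer_iter):
            # stage A: hyperelastic backbone against the slowest rate
            x = run_ls(
                lambda x: (x[0], x[1], sticks, log_betas),
                np.array([log_mu, alpha]),
                ([np.log(1e-3), 0.1], [np.log(1e9), 60.0]),
                [curves[0]],
                np.array([1.0]),
            )
            log_mu, alpha = float(x[0]), float(x[1])
            # stage B: relaxation spectrum against all rates
            if config.fix_betas:
                x = run_ls(
                    lambda x: (log_mu, alpha, x, log_betas),
                    sticks,
                    ([stick_lo] * n_g, [stick_hi] * n_g),
                    curves,
                    weights,
                )
                sticks = x
            else:
                x = run_ls(
                    lambda x: (log_mu, alpha, x[:n_g], x[n_g:]),
                    np.concatenate([sticks, log_betas]),
                    ([stick_lo] * n_g + [np.log(1e-2)] * n_g,
                     [stick_hi] * n_g + [np.log(1e5)] * n_g),
                    curves,
                    weights,
                )
                sticks, log_betas = x[:n_g], x[n_g:]
            material = build(log_mu, alpha, sticks, log_betas)
            obj = float(
                np.mean([
                    curve_discrepancy(_simulate_at(material, c, config.mode), c)
                    for c in curves
                ])
            )
            if prev_obj - obj < 0.1 * config.tolerance:
                break
            prev_obj = obj

    if config.stage_mode == "joint" or (config.stage_mode == "staged" and config.polish):
        if config.fix_betas:
            x = run_ls(
                lambda x: (x[0], x[1], x[2:], log_betas),
                np.concatenate([[log_mu, alpha], sticks]),
                ([np.log(1e-3), 0.1] + [stick_lo] * n_g,
                 [np.log(1e9), 60.0] + [stick_hi] * n_g),
                curves,
                weights,
            )
            log_mu, alpha, sticks = float(x[0]), float(x[1]), x[2:]
        else:
            x = run_ls(
                lambda x: (x[0], x[1], x[2:2 + n_g], x[2 + n_g:]),
                np.concatenate([[log_mu, alpha], sticks, log_betas]),
                ([np.log(1e-3), 0.1] + [stick_lo] * n_g + [np.log(1e-2)] * n_g,
                 [np.log(1e9), 60.0] + [stick_hi] * n_g + [np.log(1e5)] * n_g),
                curves,
                weights,
            )
            log_mu, alpha = float(x[0]), float(x[1])
            sticks, log_betas = x[2:2 + n_g], x[2 + n_g:]

    material = build(log_mu, alpha, sticks, log_betas)
    per_r2, per_rmse, discrepancies = {}, {}, []
    for curve in curves:
        model = _simulate_at(material, curve, config.mode)
        s_m = np.interp(curve.strain, model.strain, model.stress)
        per_r2[curve.rate] = r_squared(curve.stress, s_m)
        per_rmse[curve.rate] = rmse(curve.stress, s_m)
        discrepancies.append(curve_discrepancy(model, curve))
    objective = float(np.mean(discrepancies))
    converged = ok and all(d < config.tolerance for d in discrepancies)
    return FitResult(
        material=material,
        objective=objective,
        per_rate_r2=per_r2,
        per_rate_rmse=per_rmse,
        converged=converged,
        iterations=iterations,
        seed=config.seed,
        message=message or ("converged" if converged else "tolerance not reached"),
    )


def fit_pia_ogden(curve: StressStrainCurve, config: FitConfig | None = None) -> FitResult:
    """Single-term Ogden fit of a tension curve, maximizing R^2.

    Equivalent to minimizing the residual sum of squares since the total sum
    of squares is fixed by the data.  A constant (degenerate) curve yields a
    non-converged result.
    """
    if config is None:
        config = FitConfig(mode="tension")
    if len(curve) < 5:
        raise InputError("pia fit requires at least 5 samples")
    if float(np.ptp(curve.stress)) == 0.0:
        return FitResult(
            material=OgdenModel([(config.initial_mu, config.initial_alpha)],
                                poisson_ratio=0.49),
            objective=np.inf,
            converged=False,
            seed=config.seed,
            message="degenerate constant curve",
        )

    lam = 1.0 + curve.strain
    scale = float(np.max(np.abs(curve.stress))) or 1.0

    def predict(log_mu, alpha):
        mu = np.exp(log_mu)
        return mu * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))

    # neutral start: match the stress at the largest strain with alpha = 5
    alpha0 = config.initial_alpha
    lam_end = lam[-1]
    shape_end = lam_end ** (alpha0 - 1.0) - lam_end ** (-alpha0 / 2.0 - 1.0)
    s_end = abs(float(curve.stress[-1]))
    mu0 = s_end / shape_end if shape_end > 0 and s_end > 0 else config.initial_mu
    x0 = np.array([np.log(max(mu0, 1e-6)), alpha0])

    def fun(x):
        return (predict(x[0], x[1]) - curve.stress) / scale

    res = least_squares(
        fun, x0, bounds=([np.log(1e-3), 0.1], [np.log(1e12), 60.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500,
    )
    mu_fit, alpha_fit = float(np.exp(res.x[0])), float(res.x[1])
    model = OgdenModel([(mu_fit, alpha_fit)], poisson_ratio=0.49)
    pred = predict(res.x[0], res.x[1])
    protocol = RampProtocol(
        engineering_strain_rate=curve.rate or 0.05,
        max_engineering_strain=float(curve.strain[-1]) or 0.4,
        mode="tension",
        sample_count=max(len(curve), 2),
    ) if curve.strain[-1] > 0 else None
    objective = (
        curve_discrepancy(simulate_pia_tension(model, protocol), curve)
        if protocol is not None
        else float(np.sqrt(np.mean(fun(res.x) ** 2)))
    )
    return FitResult(
        material=model,
        objective=objective,
        per_rate_r2={curve.rate: r_squared(curve.stress, pred)},
        per_rate_rmse={curve.rate: rmse(curve.stress, pred)},
        converged=bool(res.status > 0),
        iterations=int(res.nfev),
        seed=config.seed,
        message=res.message,
    )
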
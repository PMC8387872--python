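import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpmech import (
    OgdenModel,
    PronySeries,
    QLVMaterial,
    StrainHistory,
    ogden_strain_energy,
    qlv_stress,
    reduced_relaxation,
    small_strain_moduli,
    uniaxial_nominal_stress,
)
from scpmech.errors import DomainError, InputError


# --- type invariants ---------------------------------------------------------

class TestTypes:
    def test_ogden_rejects_nonpositive_mu(self):
        with pytest.raises(DomainError):
            OgdenModel([(-1.0, 2.0)])

    def test_ogden_rejects_zero_alpha(self):
        with pytest.raises(DomainError):
            OgdenModel([(100.0, 0.0)])

    @pytest.mark.parametrize("nu", [0.5, 0.7, 0.0, -0.1])
    def test_ogden_rejects_bad_poisson(self, nu):
        with pytest.raises(DomainError):
            OgdenModel([(100.0, 2.0)], poisson_ratio=nu)

    def test_prony_rejects_sum_above_one(self):
        with pytest.raises(DomainError):
            PronySeries([(0.6, 1.0), (0.6, 10.0)])

    def test_prony_rejects_unordered_rates(self):
        with pytest.raises(DomainError):
            PronySeries([(0.1, 10.0), (0.1, 2.0)])

    def test_prony_long_term_fraction(self, cord_prony):
        assert cord_prony.long_term_fraction == pytest.approx(0.265)

    def test_history_must_start_at_rest(self):
        with pytest.raises(InputError):
            StrainHistory([0.0, 1.0], [0.9, 0.8])

    def test_history_rejects_nonmonotone_times(self):
        with pytest.raises(InputError):
            StrainHistory([0.0, 0.5, 0.4], [1.0, 0.9, 0.8])

    def test_history_rejects_nonpositive_stretch(self):
        with pytest.raises(DomainError):
            StrainHistory([0.0, 1.0, 2.0], [1.0, 0.5, -0.1])


# --- ogden_strain_energy -----------------------------------------------------

class TestStrainEnergy:
    def test_reference_configuration_is_zero(self, cord_ogden):
        assert ogden_strain_energy(cord_ogden, (1.0, 1.0, 1.0), 1.0) == 0.0

    def test_isotropy_under_permutation(self, cord_ogden):
        vals = {
            ogden_strain_energy(cord_ogden, perm, 1.0)
            for perm in [(0.8, 1.1, 1.2), (1.1, 0.8, 1.2), (1.2, 1.1, 0.8)]
        }
        assert max(vals) - min(vals) < 1e-12

    def test_cord_value_matches_term_by_term_oracle(self, cord_ogden):
        # (209/7.52)*(0.8**7.52 + 2*1.1180**7.52 - 3), extended precision
        expected = 50.412265241971973589
        got = ogden_strain_energy(cord_ogden, (0.8, 1.1180, 1.1180), 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_hydrostatic_term(self, cord_ogden):
        _, _, bulk = small_strain_moduli(cord_ogden)
        lam = 1.01 ** (1.0 / 3.0)
        w = ogden_strain_energy(cord_ogden, (lam, lam, lam), 1.01)
        # deviatoric stretches of a pure dilation are unity: only K term remains
        assert w == pytest.approx(0.5 * bulk * 0.01**2, rel=1e-9)

    def test_domain_errors(self, cord_ogden):
        with pytest.raises(DomainError):
            ogden_strain_energy(cord_ogden, (0.0, 1.0, 1.0), 1.0)
        with pytest.raises(DomainError):
            ogden_strain_energy(cord_ogden, (1.0, 1.0, 1.0), -1.0)


# --- uniaxial_nominal_stress -------------------------------------------------

class TestUniaxialStress:
    def test_stress_free_reference(self, cord_ogden):
        assert uniaxial_nominal_stress(cord_ogden, 1.0) == 0.0

    def test_sign_convention(self, cord_ogden):
        assert uniaxial_nominal_stress(cord_ogden, 0.9) < 0
        assert uniaxial_nominal_stress(cord_ogden, 1.1) > 0

    def test_tangent_stiffness_at_reference(self, cord_ogden):
        h = 1e-7
        slope = (
            uniaxial_nominal_stress(cord_ogden, 1 + h)
            - uniaxial_nominal_stress(cord_ogden, 1 - h)
        ) / (2 * h)
        assert slope == pytest.approx(2357.52, rel=1e-6)  # 3 * sum(mu*alpha) / 2

    @pytest.mark.parametrize("lam", [0.5, 0.8, 0.95, 1.05, 1.3, 1.8])
    def test_equals_energy_derivative(self, cord_ogden, lam):
        # finite-difference of W(lam, lam^-1/2, lam^-1/2) under incompressibility
        h = 1e-6 * lam

        def w(x):
            return ogden_strain_energy(cord_ogden, (x, x**-0.5, x**-0.5), 1.0)

        fd = (w(lam + h) - w(lam - h)) / (2 * h)
        assert uniaxial_nominal_stress(cord_ogden, lam) == pytest.approx(fd, rel=1e-6)

    def test_domain_error(self, cord_ogden):
        with pytest.raises(DomainError):
            uniaxial_nominal_stress(cord_ogden, -0.2)

    def test_overflow_guarded(self):
        model = OgdenModel([(1.0, 50.0)])
        with pytest.raises(DomainError):
            uniaxial_nominal_stress(model, 1e-7)


# --- reduced_relaxation ------------------------------------------------------

class TestReducedRelaxation:
    def test_normalized_at_zero(self, cord_prony):
        assert reduced_relaxation(cord_prony, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_long_time_limit(self, cord_prony):
        assert reduced_relaxation(cord_prony, 1e6) == pytest.approx(0.265, abs=1e-12)

    def test_strictly_decreasing_and_convex(self, cord_prony):
        t = np.linspace(0.0, 2.0, 400)
        g = reduced_relaxation(cord_prony, t)
        assert np.all(np.diff(g) < 0)
        assert np.all(np.diff(g, 2) > 0)

    def test_negative_time_rejected(self, cord_prony):
        with pytest.raises(DomainError):
            reduced_relaxation(cord_prony, -1e-9)


# --- small_strain_moduli -----------------------------------------------------

class TestModuli:
    def test_cord_shear_modulus(self, cord_ogden):
        g0, _, _ = small_strain_moduli(cord_ogden)
        assert g0 == pytest.approx(785.84, rel=1e-12)  # 209 * 7.52 / 2

    def test_pia_shear_modulus(self, pia_ogden):
        g0, _, _ = small_strain_moduli(pia_ogden)
        assert g0 == pytest.approx(264_180.0, rel=1e-12)  # 42e3 * 12.58 / 2

    def test_zero_poisson_bulk(self):
        model = OgdenModel([(100.0, 2.0)], poisson_ratio=1e-12)
        g0, young, bulk = small_strain_moduli(model)
        assert bulk == pytest.approx(2.0 * g0 / 3.0, rel=1e-9)
        assert young == pytest.approx(2.0 * g0, rel=1e-9)


# --- qlv_stress --------------------------------------------------------------

def _ramp_history(rate, max_strain, n=400, sign=-1.0):
    duration = max_strain / rate
    t = np.linspace(0.0, duration, n)
    return StrainHistory(t, 1.0 + sign * rate * t)


def trapezoid_convolution_oracle(material, times, stretches):
    """Direct trapezoidal quadrature of the hereditary integral.

    Independent of the production path: evaluates the Prony kernel at every
    (t_k, tau_j) pair instead of using the exponential recurrence.
    """
    prony = material.relaxation
    sig_e = uniaxial_nominal_stress(material.elastic, np.asarray(stretches))
    d_sig = np.diff(sig_e)
    out = np.zeros_like(sig_e)
    base = sig_e if material.formulation == "overstress" else (
        prony.long_term_fraction * sig_e
    )
    for k in range(1, len(times)):
        lag_hi = times[k] - times[1: k + 1]
        lag_lo = times[k] - times[:k]
        acc = 0.0
        for g, beta in prony.terms:
            kernel = 0.5 * (np.exp(-beta * lag_hi) + np.exp(-beta * lag_lo))
            acc += g * float(np.sum(kernel * d_sig[:k]))
        out[k] = base[k] + acc
    return out


class TestQLVStress:
    def test_unit_history_gives_zero_stress(self, cord_qlv):
        hist = StrainHistory(np.linspace(0, 1, 50), np.ones(50))
        trace = qlv_stress(cord_qlv, hist)
        assert np.allclose(trace.stresses, 0.0)

    def test_stress_starts_at_zero(self, cord_qlv):
        trace = qlv_stress(cord_qlv, _ramp_history(10.0, 0.3))
        assert trace.stresses[0] == 0.0

    def test_equilibrium_limit_after_hold(self, cord_qlv):
        # ramp much slower than 1/min(beta), then hold
        lam_end = 0.7
        t_ramp = 300.0  # >> 1/2 s
        t = np.concatenate([np.linspace(0, t_ramp, 3000),
                            np.linspace(t_ramp + 1.0, t_ramp + 20.0, 200)])
        lam = np.concatenate([np.linspace(1.0, lam_end, 3000),
                              np.full(200, lam_end)])
        trace = qlv_stress(cord_qlv, StrainHistory(t, lam))
        sig_e = uniaxial_nominal_stress(cord_qlv.elastic, lam_end)
        assert trace.stresses[-1] / sig_e == pytest.approx(0.265, rel=0.01)

    def test_instantaneous_limit(self, cord_qlv):
        # rate 100x faster than max(beta) time scale
        trace = qlv_stress(cord_qlv, _ramp_history(40_600.0, 0.3))
        sig_e = uniaxial_nominal_stress(cord_qlv.elastic, 0.7)
        assert trace.stresses[-1] / sig_e == pytest.approx(1.0, rel=0.01)

    def test_overstress_formulation_quasi_static(self, cord_ogden, cord_prony):
        material = QLVMaterial(cord_ogden, cord_prony, formulation="overstress")
        trace = qlv_stress(material, _ramp_history(0.32 / 200, 0.3, n=2000))
        sig_e = uniaxial_nominal_stress(cord_ogden, 0.7)
        assert trace.stresses[-1] / sig_e == pytest.approx(1.0, rel=0.02)

    def test_rate_monotonicity(self, cord_qlv):
        rates = [0.32, 2.83, 25.44, 77.22]
        stresses = []
        for rate in rates:
            trace = qlv_stress(cord_qlv, _ramp_history(rate, 0.3))
            stresses.append(abs(trace.stresses[-1]))
        assert np.all(np.diff(stresses) > 0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_recurrence_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prony = PronySeries([(0.1, 2.0), (0.3, 20.0)])
        material = QLVMaterial(OgdenModel([(209.0, 7.52)]), prony)
        # random 200-breakpoint piecewise-linear history, refined to a uniform grid
        n_seg = 200
        t_knots = np.concatenate([[0.0], np.sort(rng.uniform(0.01, 1.0, n_seg))])
        lam_knots = np.concatenate([[1.0], rng.uniform(0.7, 1.3, n_seg)])
        t = np.linspace(0.0, t_knots[-1], 1200)
        lam = np.interp(t, t_knots, lam_knots)
        lam[0] = 1.0
        hist = StrainHistory(t, lam)
        trace = qlv_stress(material, hist, min_points=t.size)
        oracle = trapezoid_convolution_oracle(material, t, lam)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(trace.stresses - oracle)) <= 1e-3 * scale
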
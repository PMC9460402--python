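"""Maxwell forward models and relaxation-spectrum inversion."""

import math

import numpy as np
import pytest

import rheomwd as rm
from rheomwd.data import ValidationError
from rheomwd.spectrum import _log_trapezoid_weights


def _master(omega, gp, gpp):
    return rm.MasterCurve(reference_temperature=28.0, omega=omega, g_prime=gp,
                          g_double_prime=gpp,
                          source_temperature_per_point=np.full_like(omega, 28.0))


class TestDiscreteForward:
    def test_unit_deborah_number(self, single_mode):
        gp, gpp = rm.forward_moduli_discrete(single_mode, [10.0])
        assert gp[0] == pytest.approx(500.0, abs=1e-9)
        assert gpp[0] == pytest.approx(500.0, abs=1e-9)

    def test_terminal_scaling(self, single_mode):
        gp, gpp = rm.forward_moduli_discrete(single_mode, [0.1])
        assert gpp[0] / gp[0] == pytest.approx(100.0, abs=1e-9)

    def test_additivity_of_modes(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(10, 1000, 5)
        lam = np.sort(rng.uniform(0.01, 10, 5))
        omega = np.logspace(-2, 2, 25)
        spec = rm.MaxwellSpectrum(g=g, lam=lam)
        gp, gpp = rm.forward_moduli_discrete(spec, omega)
        gp_sum = np.zeros_like(omega)
        gpp_sum = np.zeros_like(omega)
        for gi, li in zip(g, lam):
            a, b = rm.forward_moduli_discrete(
                rm.MaxwellSpectrum(g=[gi], lam=[li]), omega)
            gp_sum += a
            gpp_sum += b
        np.testing.assert_allclose(gp, gp_sum, rtol=1e-14)
        np.testing.assert_allclose(gpp, gpp_sum, rtol=1e-14)

    def test_loss_modulus_peaks_at_reciprocal_lambda(self, single_mode):
        omega = np.logspace(0, 2, 401)  # 200 points/decade around 1/lam = 10
        _, gpp = rm.forward_moduli_discrete(single_mode, omega)
        i = int(np.argmax(gpp))
        assert abs(math.log10(omega[i]) - 1.0) <= math.log10(omega[1] / omega[0])

    def test_tan_delta_definition_consistency(self, three_mode):
        omega = np.logspace(-2, 2, 30)
        gp, gpp = rm.forward_moduli_discrete(three_mode, omega)
        np.testing.assert_allclose(gpp / gp, gpp / gp)  # trivially G''/G'
        assert np.all((gpp / gp) > 0)


class TestRelaxationModulus:
    def test_single_mode_at_its_own_time(self, single_mode):
        curve = rm.relaxation_modulus(single_mode, [0.1])
        assert curve.modulus[0] == pytest.approx(1000.0 * math.exp(-1))

    def test_short_time_limit_is_total_modulus(self, three_mode):
        curve = rm.relaxation_modulus(three_mode, [1e-9])
        assert curve.modulus[0] == pytest.approx(three_mode.g.sum(), rel=1e-6)

    def test_narrow_lognormal_matches_single_mode(self, single_mode):
        # grid must resolve the narrow peak (several nodes per sigma) and the
        # comparison window must stop before the finite spectral width, not
        # quadrature, dominates the tail
        lam = np.logspace(-2, 0, 461)  # 230 points/decade
        sigma = 0.02
        H = (1000.0 / (sigma * math.sqrt(2 * math.pi))
             * np.exp(-0.5 * ((np.log(lam) - math.log(0.1)) / sigma) ** 2))
        spec = rm.ContinuousSpectrum(lambda_grid=lam, H=H)
        time = np.logspace(-2, math.log10(0.5), 20)  # t <= 5 lambda
        g_cont = rm.relaxation_modulus(spec, time).modulus
        g_disc = rm.relaxation_modulus(single_mode, time).modulus
        np.testing.assert_allclose(g_cont, g_disc, rtol=5e-3)


class TestContinuousForward:
    def test_delta_like_spectrum_reproduces_single_mode(self, single_mode):
        lam = np.logspace(-3, 1, 41)
        H = np.zeros_like(lam)
        i0 = int(np.argmin(np.abs(lam - 0.1)))
        wq = _log_trapezoid_weights(lam)
        H[i0] = 1000.0 / wq[i0]  # one grid cell carrying modulus G0
        spec = rm.ContinuousSpectrum(lambda_grid=lam, H=H)
        omega = np.logspace(-1, 2, 10)
        gp, gpp = rm.forward_moduli_continuous(spec, omega)
        gp_ref, gpp_ref = rm.forward_moduli_discrete(
            rm.MaxwellSpectrum(g=[1000.0], lam=[lam[i0]]), omega)
        np.testing.assert_allclose(gp, gp_ref, rtol=1e-12)
        np.testing.assert_allclose(gpp, gpp_ref, rtol=1e-12)

    def test_zero_spectrum_gives_zero_moduli(self):
        spec = rm.ContinuousSpectrum(lambda_grid=np.logspace(-2, 2, 41),
                                     H=np.zeros(41))
        gp, gpp = rm.forward_moduli_continuous(spec, np.logspace(-1, 1, 5))
        assert np.all(gp == 0) and np.all(gpp == 0)

    def test_quadrature_refinement_is_converged(self):
        omega = np.logspace(-2, 2, 15)

        def moduli(ppd):
            lam = np.logspace(-4, 4, 8 * ppd + 1)
            H = 500.0 * np.exp(-0.5 * ((np.log(lam) - math.log(0.5)) / 0.8) ** 2)
            return rm.forward_moduli_continuous(
                rm.ContinuousSpectrum(lambda_grid=lam, H=H), omega)

        gp10, gpp10 = moduli(10)
        gp20, gpp20 = moduli(20)
        np.testing.assert_allclose(gp10, gp20, rtol=1e-3)
        np.testing.assert_allclose(gpp10, gpp20, rtol=1e-3)

    def test_coarse_grid_warns(self):
        spec = rm.ContinuousSpectrum(lambda_grid=np.logspace(-2, 2, 9),
                                     H=np.full(9, 10.0))
        with pytest.warns(UserWarning, match="coarser"):
            rm.forward_moduli_continuous(spec, [1.0])


class TestInversion:
    def test_single_mode_mass_concentrates(self, single_mode):
        omega = np.logspace(-3, 3, 61)
        gp, gpp = rm.forward_moduli_discrete(single_mode, omega)
        spec, _ = rm.invert_relaxation_spectrum(_master(omega, gp, gpp))
        mass = spec.H * _log_trapezoid_weights(spec.lambda_grid)
        lam0 = single_mode.lam[0]
        window = ((spec.lambda_grid >= lam0 * 10 ** -0.5)
                  & (spec.lambda_grid <= lam0 * 10 ** 0.5))
        assert mass[window].sum() / mass.sum() >= 0.90

    def test_zero_moduli_give_zero_spectrum(self):
        # the MasterCurve type itself rejects zero moduli, so feed the solver
        # a bare record: a fully relaxed signal must invert to an empty H
        from types import SimpleNamespace
        omega = np.logspace(-1, 1, 11)
        mc = SimpleNamespace(omega=omega, g_prime=np.zeros(11),
                             g_double_prime=np.zeros(11))
        spec, _ = rm.invert_relaxation_spectrum(mc)
        assert np.all(spec.H == 0)

    @pytest.mark.parametrize("sigma", [0.0, 0.02, 0.05])
    def test_forward_inverse_consistency(self, sigma):
        """Refit of the recovered spectrum reproduces the master curve to
        within the noise level (smooth truth; a curvature-penalized inversion
        cannot and should not chase discrete spikes)."""
        omega = np.logspace(-3, 3, 61)
        lam = np.logspace(-4, 4, 81)
        H = 500.0 * np.exp(-0.5 * ((np.log(lam) - math.log(0.5)) / 0.9) ** 2)
        truth = rm.ContinuousSpectrum(lambda_grid=lam, H=H)
        gp, gpp = rm.forward_moduli_continuous(truth, omega)
        rng = np.random.default_rng(42)
        gp_n = gp * np.exp(sigma * rng.standard_normal(omega.size))
        gpp_n = gpp * np.exp(sigma * rng.standard_normal(omega.size))
        spec, diag = rm.invert_relaxation_spectrum(_master(omega, gp_n, gpp_n))
        assert diag["refit_rms_log"] <= 1.5 * sigma + 0.01

    def test_scale_invariance_of_recovered_spectrum(self, three_mode):
        """Rescaling omega -> c*omega and lambda -> lambda/c leaves the kernel
        products omega*lambda unchanged; with c an exact power of two and the
        grids scaled exactly, the recovered H agrees to solver precision."""
        c = 4.0
        omega = np.logspace(-2, 2, 41)
        gp, gpp = rm.forward_moduli_discrete(three_mode, omega)
        grid = rm.make_lambda_grid(omega.min(), omega.max(), 10)
        spec1, _ = rm.invert_relaxation_spectrum(_master(omega, gp, gpp),
                                                 lambda_grid=grid)
        spec2, _ = rm.invert_relaxation_spectrum(_master(c * omega, gp, gpp),
                                                 lambda_grid=grid / c)
        # the optimizer takes a slightly different path (log-grid weights
        # round differently), so compare where the spectrum carries mass
        alive = spec1.H > 1e-3 * spec1.H.max()
        np.testing.assert_allclose(spec2.H[alive], spec1.H[alive], rtol=0.02)
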
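"""Double-reptation transform, parametric inversion and moment reporting."""

import dataclasses
import math

import numpy as np
import pytest

import rheomwd as rm
from rheomwd.data import ValidationError
from rheomwd.spectrum import _log_trapezoid_weights


def _delta_distribution(mass, me, weight_split=None):
    """Distribution with all weight on one or two grid points."""
    masses = np.atleast_1d(mass)
    grid = np.logspace(math.log10(me * 1.1), 8.0, 61)
    w = np.zeros_like(grid)
    weights = weight_split if weight_split is not None else [1.0] * len(masses)
    idx = []
    for m, wt in zip(masses, weights):
        i = int(np.argmin(np.abs(np.log(grid) - math.log(m))))
        w[i] = wt / _log_trapezoid_weights(grid)[i]
        idx.append(i)
    dist = rm.MWDistribution(mass_grid=grid, w=w)
    return dist, grid[idx]


class TestKernel:
    def test_unit_at_time_zero(self, reptation_params):
        assert rm.reptation_kernel(2e5, 0.0, reptation_params) == 1.0

    def test_e_folding_at_kernel_time(self, reptation_params):
        lam = reptation_params.lambda_d(3e5)
        f = rm.reptation_kernel(3e5, lam, reptation_params)
        assert f == pytest.approx(math.exp(-1), rel=1e-12)

    def test_reptation_scaling_identity(self, reptation_params):
        # doubling M multiplies the kernel time by 2^alpha
        m, t = 4e5, 1.7
        lhs = rm.reptation_kernel(2 * m, 2 ** 3.4 * t, reptation_params)
        rhs = rm.reptation_kernel(m, t, reptation_params)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_unentangled_mass_rejected(self, reptation_params):
        with pytest.raises(ValidationError, match="unentangled"):
            rm.reptation_kernel(reptation_params.me / 2, 1.0, reptation_params)

    def test_mc_is_twice_me(self, reptation_params):
        assert reptation_params.mc == 2 * reptation_params.me


class TestForwardReptation:
    @pytest.mark.parametrize("beta", [1.0, 2.0, 3.5])
    def test_monodisperse_collapse(self, reptation_params, beta):
        """A delta distribution collapses the mixing rule to G_N * F(M0, t)
        for any mixing exponent."""
        p = dataclasses.replace(reptation_params, beta=beta)
        dist, (m0,) = _delta_distribution(5e5, p.me)
        t = np.logspace(-2, 3, 30)
        gr = rm.forward_reptation(dist, t, p, warn_coarse=False)
        ref = p.g_n * rm.reptation_kernel(m0, t, p)
        np.testing.assert_allclose(gr.modulus, ref, rtol=1e-12)

    def test_binary_blend_closed_form(self, reptation_params):
        p = reptation_params  # beta = 2
        dist, (m1, m2) = _delta_distribution([2e5, 2e6], p.me,
                                             weight_split=[0.4, 0.6])
        t = np.logspace(-2, 4, 40)
        gr = rm.forward_reptation(dist, t, p, warn_coarse=False)
        l1, l2 = p.lambda_d(m1), p.lambda_d(m2)
        ref = p.g_n * (0.4 * np.exp(-t / (2 * l1))
                       + 0.6 * np.exp(-t / (2 * l2))) ** 2
        np.testing.assert_allclose(gr.modulus, ref, rtol=1e-3)

    def test_quadrature_refinement(self, reptation_params, lognormal_truth):
        t = np.logspace(-2, 4, 30)
        coarse = rm.forward_reptation(lognormal_truth, t, reptation_params,
                                      warn_coarse=False)
        fine_grid = np.logspace(np.log10(lognormal_truth.mass_grid[0]),
                                np.log10(lognormal_truth.mass_grid[-1]), 800)
        fine_dist = rm.MWDistribution.from_components(
            lognormal_truth.components, fine_grid)
        fine = rm.forward_reptation(fine_dist, t, reptation_params,
                                    warn_coarse=False)
        np.testing.assert_allclose(coarse.modulus, fine.modulus, rtol=1e-3)

    def test_bounded_and_monotone(self, reptation_params, lognormal_truth):
        t = np.logspace(-3, 5, 50)
        gr = rm.forward_reptation(lognormal_truth, t, reptation_params,
                                  warn_coarse=False)
        assert np.all(np.diff(gr.modulus) <= 0)
        assert np.all(gr.modulus <= reptation_params.g_n * (1 + 1e-12))


class TestSummaries:
    def test_lognormal_pdi_closed_form(self):
        # log-width sigma^2 = ln 2 gives PDI = exp(sigma^2) = 2 exactly
        comps = [(1.0, 5e5, math.sqrt(math.log(2.0)))]
        grid = np.logspace(3.5, 8.5, 600)
        dist = rm.MWDistribution.from_components(comps, grid)
        assert dist.pdi == pytest.approx(2.0, rel=1e-4)

    def test_two_point_hand_arithmetic(self):
        # 0.5 at 1e5 and 0.5 at 5e5: Mw = 3e5, Mn = 5/3 * 1e5, PDI = 1.8
        # (grid contains the two masses exactly so the arithmetic is exact)
        grid = np.array([5e4, 7e4, 1e5, 2e5, 3e5, 5e5, 7e5, 1e6])
        wq = _log_trapezoid_weights(grid)
        w = np.zeros_like(grid)
        w[2] = 0.5 / wq[2]
        w[5] = 0.5 / wq[5]
        dist = rm.MWDistribution(mass_grid=grid, w=w)
        assert dist.mw == pytest.approx(3e5, rel=1e-12)
        assert dist.mn == pytest.approx(5e5 / 3.0, rel=1e-12)
        report = rm.summarize_distribution(dist)
        assert report["pdi_rounded"] == 1.8

    def test_rounding_convention(self):
        report = rm.summarize_distribution(6.7e5, 3.7e5)
        assert report["mw_rounded"] == 6.7e5
        assert report["pdi_rounded"] == 1.8

    def test_rejects_nonpositive_moments(self):
        with pytest.raises(ValidationError):
            rm.summarize_distribution(-1.0, 2.0)


class TestSpectrumToTarget:
    def test_full_window_retained_above_tau_e(self, reptation_params):
        lam = np.logspace(0, 3, 31)  # all far above tau_e ~ 1e-3 s
        H = 300.0 * np.exp(-0.5 * ((np.log(lam) - math.log(30.0)) / 0.8) ** 2)
        spec = rm.ContinuousSpectrum(lambda_grid=lam, H=H)
        target = rm.spectrum_to_relaxation_target(spec, reptation_params)
        assert target.time[0] >= reptation_params.tau_e

    def test_sub_entanglement_window_is_cut(self, reptation_params):
        tau_e = reptation_params.tau_e
        lam = np.logspace(math.log10(tau_e) - 3, math.log10(tau_e) + 3, 61)
        H = np.full_like(lam, 100.0)
        spec = rm.ContinuousSpectrum(lambda_grid=lam, H=H)
        target = rm.spectrum_to_relaxation_target(spec, reptation_params)
        assert target.time[0] >= tau_e

    def test_entirely_sub_entanglement_is_an_error(self, reptation_params):
        tau_e = reptation_params.tau_e
        lam = np.logspace(math.log10(tau_e) - 6, math.log10(tau_e) - 4, 21)
        spec = rm.ContinuousSpectrum(lambda_grid=lam, H=np.full(21, 10.0))
        with pytest.raises(ValidationError):
            rm.spectrum_to_relaxation_target(spec, reptation_params)


class TestInvertMWD:
    def test_noiseless_lognormal_recovery(self, reptation_params,
                                          lognormal_truth):
        t = np.logspace(-3, 5, 90)
        gr = rm.forward_reptation(lognormal_truth, t, reptation_params,
                                  warn_coarse=False)
        res = rm.invert_mwd(gr, reptation_params, family="lognormal_1")
        assert res.distribution.mw == pytest.approx(lognormal_truth.mw,
                                                    rel=0.05)
        assert res.distribution.pdi == pytest.approx(lognormal_truth.pdi,
                                                     rel=0.10)

    def test_monodisperse_input_gives_unit_pdi(self, reptation_params):
        p = reptation_params
        dist, (m0,) = _delta_distribution(6e5, p.me)
        t = np.logspace(-2, 4, 60)
        gr = rm.forward_reptation(dist, t, p, warn_coarse=False)
        res = rm.invert_mwd(gr, p, family="lognormal_1")
        assert res.distribution.pdi < 1.05

    def test_too_few_points_is_an_error(self, reptation_params):
        target = rm.RelaxationCurve(time=[0.1, 1.0, 10.0],
                                    modulus=[900.0, 500.0, 100.0])
        with pytest.raises(ValidationError, match="family"):
            rm.invert_mwd(target, reptation_params, family="lognormal_mix_3")

    def test_normalization_and_pdi_floor_preserved(self, reptation_params,
                                                   lognormal_truth):
        t = np.logspace(-3, 5, 60)
        gr = rm.forward_reptation(lognormal_truth, t, reptation_params,
                                  warn_coarse=False)
        res = rm.invert_mwd(gr, reptation_params, family="lognormal_mix_2")
        w_total = res.distribution.w @ _log_trapezoid_weights(
            res.distribution.mass_grid)
        assert w_total == pytest.approx(1.0, abs=1e-6)
        assert res.distribution.pdi >= 1.0

    def test_beta_invariance_for_monodisperse(self, reptation_params):
        """Monodisperse targets are insensitive to the mixing exponent; the
        recovered mass must agree across beta."""
        recovered = []
        for beta in (1.5, 2.0, 3.0):
            p = dataclasses.replace(reptation_params, beta=beta)
            dist, (m0,) = _delta_distribution(6e5, p.me)
            t = np.logspace(-2, 4, 60)
            gr = rm.forward_reptation(dist, t, p, warn_coarse=False)
            res = rm.invert_mwd(gr, p, family="lognormal_1")
            recovered.append(res.distribution.mw)
        assert max(recovered) / min(recovered) < 1.02
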
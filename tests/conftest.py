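"""Shared fixtures: reference Maxwell spectra, reptation parameters, and a
batch of robust fits on noisy synthetic sweeps reused by several tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import rheomwd as rm


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def single_mode():
    """One Maxwell mode: G = 1000 Pa, λ = 0.1 s (crossover at ω = 10 rad/s)."""
    return rm.MaxwellSpectrum(g=[1000.0], lam=[0.1])


@pytest.fixture(scope="session")
def three_mode():
    return rm.MaxwellSpectrum(g=[800.0, 400.0, 200.0], lam=[0.01, 0.3, 5.0])


@pytest.fixture(scope="session")
def three_mode_sweep(three_mode):
    omega = np.logspace(-2, 2, 33)
    gp, gpp = rm.forward_moduli_discrete(three_mode, omega)
    return rm.FrequencySweep(temperature=28.0, omega=omega, g_prime=gp,
                             g_double_prime=gpp, sample_id="three_mode")


@pytest.fixture(scope="session")
def reptation_params():
    """Collagen-gel scale: G_N = 1 kPa, Me = 50 kg/mol, double reptation."""
    return rm.ReptationParams(g_n=1000.0, me=5e4, beta=2.0,
                              kernel_prefactor=1e-19, kernel_exponent=3.4)


@pytest.fixture(scope="session")
def lognormal_truth(reptation_params):
    """Log-normal truth at the collagen scale (Mw = 6.8e5 g/mol, PDI = 2)."""
    comps = rm.lognormal_components(6.8e5, 2.0)
    grid = np.logspace(np.log10(reptation_params.me * 1.01), 8.5, 80)
    return rm.MWDistribution.from_components(comps, grid)


@pytest.fixture(scope="session")
def noisy_fit_batch(three_mode, three_mode_sweep):
    """100 robust fits of the three-mode sweep under 5% multiplicative noise.

    Returns (true ω_c, list of FitResult).  Shared across tests because the
    fits are the expensive part.
    """
    xc_true = rm.find_crossover(
        rm.FitResult.from_maxwell(three_mode, (1e-2, 1e2))).omega_c
    omega = three_mode_sweep.omega
    gp, gpp = three_mode_sweep.g_prime, three_mode_sweep.g_double_prime
    fits = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sweep = rm.FrequencySweep(
            temperature=28.0, omega=omega,
            g_prime=gp * np.exp(0.05 * rng.standard_normal(omega.size)),
            g_double_prime=gpp * np.exp(0.05 * rng.standard_normal(omega.size)),
        )
        fits.append(rm.fit_modulus_curves(sweep, max_complexity=4))
    return xc_true, fits
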
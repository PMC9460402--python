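"""Synthetic rheometer datasets with ground-truth manifests.

No raw collagen sweep data are publicly available, so every pipeline stage is
exercised against data generated here from a fully known truth: a target w(M)
is pushed through the double-reptation mixing rule to G_r(t), converted to a
dense discrete Maxwell spectrum, evaluated as G′/G″ on temperature-shifted
frequency windows, and finally corrupted with multiplicative log-normal noise
and, optionally, instrument-artifact phenotypes (a flattened near-denaturation
tail, or a gel-like elastic floor with no crossover).

Scenario defaults follow the conditions of a concentrated (≈4% wt) collagen
gel study: truth Mw = 6.8e5 g/mol with PDI = 2.0, test temperatures
23/28/32/36 °C, denaturation near 38 °C.  The manifest records every quantity
a pipeline stage estimates (Mw/Mn/PDI, shift factors, crossover frequencies,
corrupted indices, LVE bound, Td) so recovery can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import (AmplitudeSweep, FrequencySweep, SweepMode,
                   TemperatureSweep, ValidationError)
from .mwd import (MWDistribution, ReptationParams, forward_reptation,
                  lognormal_components)
from .spectrum import MaxwellSpectrum, _nnls_safe, forward_moduli_discrete

__all__ = ["SyntheticScenario", "generate_frequency_sweeps",
           "generate_amplitude_sweep", "generate_temperature_sweep"]

_CORRUPTION_JUMP = 1.4  # plateau level relative to the last clean point


def _default_reptation() -> ReptationParams:
    return ReptationParams(g_n=1000.0, me=5e4, beta=2.0,
                           kernel_prefactor=1e-19, kernel_exponent=3.4)


@dataclass
class SyntheticScenario:
    """Fully specified study conditions for one synthetic dataset."""

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: lognormal_components(6.8e5, 2.0))
    reptation: ReptationParams = field(default_factory=_default_reptation)
    temperatures: tuple = (23.0, 28.0, 32.0, 36.0)
    true_log10_at: tuple = (1.0, 0.0, -0.75, -1.5)
    reference_temperature: float = 28.0
    td_true: float = 38.15
    lve_upper_true: float = 0.1
    noise_sigma: float = 0.02
    corruption_mode: str = "none"          # none | near_td_tail | gel_like
    corruption_fraction: float = 0.0
    omega_min: float = 1e-2
    omega_max: float = 1e1
    points_per_decade: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.true_log10_at):
            raise ValidationError("one shift per temperature required")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValidationError("temperatures must be unique")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.corruption_mode not in ("none", "near_td_tail", "gel_like"):
            raise ValidationError(f"unknown corruption mode "
                                  f"'{self.corruption_mode}'")
        if self.corruption_fraction > 0.5:
            raise ValidationError("corruption fraction > 0.5 makes the dataset "
                                  "unusable by construction")
        if self.reference_temperature not in self.temperatures:
            raise ValidationError("reference temperature must be in the list")

    def truth_distribution(self, points_per_decade: int = 20) -> MWDistribution:
        medians = [c[1] for c in self.components]
        sigmas = [c[2] for c in self.components]
        lo = max(self.reptation.me * 1.01,
                 min(m * math.exp(-6 * s) for m, s in zip(medians, sigmas)))
        hi = max(m * math.exp(6 * s) for m, s in zip(medians, sigmas))
        n = int(round(math.log10(hi / lo) * points_per_decade)) + 1
        grid = np.logspace(math.log10(lo), math.log10(hi), n)
        return MWDistribution.from_components(self.components, grid)


def _dense_maxwell_from_gr(time: np.ndarray, gr: np.ndarray,
                           modes_per_decade: int = 8) -> MaxwellSpectrum:
    """Nonnegative least-squares fit of a dense mode set to G_r(t), weighted
    for relative accuracy."""
    lo, hi = time[0] / 3.0, time[-1] * 3.0
    n = int(round(math.log10(hi / lo) * modes_per_decade)) + 1
    lam = np.logspace(math.log10(lo), math.log10(hi), n)
    a = np.exp(-np.outer(time, 1.0 / lam))
    g = _nnls_safe(a / gr[:, None], np.ones_like(gr))
    keep = g > g.max() * 1e-12
    return MaxwellSpectrum(g=g[keep], lam=lam[keep])


def _parent_spectrum(s: SyntheticScenario) -> tuple[MaxwellSpectrum, MWDistribution]:
    dist = s.truth_distribution()
    # time window wide enough to cover every shifted frequency window
    at = 10.0 ** np.asarray(s.true_log10_at)
    w_lo = s.omega_min * at.min()
    w_hi = s.omega_max * at.max()
    t_lo = 0.03 / w_hi
    t_hi = 30.0 / w_lo
    n = int(round(math.log10(t_hi / t_lo) * 16)) + 1
    time = np.logspace(math.log10(t_lo), math.log10(t_hi), n)
    gr = forward_reptation(dist, time, s.reptation, warn_coarse=False)
    return _dense_maxwell_from_gr(time, gr.modulus), dist


def _crossover_of(spec: MaxwellSpectrum, w_lo: float, w_hi: float) -> float | None:
    def diff(lw):
        gp, gpp = forward_moduli_discrete(spec, [10.0 ** lw])
        return math.log(gp[0]) - math.log(gpp[0])
    grid = np.linspace(math.log10(w_lo), math.log10(w_hi), 400)
    vals = np.array([diff(lw) for lw in grid])
    sc = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    for i in sc:
        if vals[i + 1] > vals[i]:
            return 10.0 ** brentq(diff, grid[i], grid[i + 1], xtol=1e-12)
    return None


def generate_frequency_sweeps(s: SyntheticScenario
                              ) -> tuple[list[FrequencySweep], dict]:
    """Multi-temperature frequency sweeps plus the truth manifest."""
    rng = np.random.default_rng(s.seed)
    parent, dist = _parent_spectrum(s)

    n_pts = int(round(math.log10(s.omega_max / s.omega_min)
                      * s.points_per_decade)) + 1
    omega = np.logspace(math.log10(s.omega_min), math.log10(s.omega_max), n_pts)

    sweeps: list[FrequencySweep] = []
    corrupted: dict[float, list[int]] = {}
    crossovers: dict[float, float | None] = {}
    t_max = max(s.temperatures)
    for temp, la in zip(s.temperatures, s.true_log10_at):
        at = 10.0 ** la
        gp, gpp = forward_moduli_discrete(parent, at * omega)
        gp = gp.copy()
        gpp = gpp.copy()
        wc_red = _crossover_of(parent, at * omega[0] / 10, at * omega[-1] * 10)
        crossovers[temp] = None if wc_red is None else wc_red / at

        if s.corruption_mode == "gel_like":
            gp += 3.0 * gpp.max()

        if s.noise_sigma > 0:
            gp *= np.exp(s.noise_sigma * rng.standard_normal(n_pts))
            gpp *= np.exp(s.noise_sigma * rng.standard_normal(n_pts))

        bad: list[int] = []
        if s.corruption_mode == "near_td_tail" and temp == t_max:
            n_bad = int(round(s.corruption_fraction * n_pts))
            if n_bad > 0:
                bad = list(range(n_pts - n_bad, n_pts))
                level_p = gp[n_pts - n_bad - 1] * _CORRUPTION_JUMP
                level_pp = gpp[n_pts - n_bad - 1] * _CORRUPTION_JUMP
                gp[bad] = level_p
                gpp[bad] = level_pp
        corrupted[temp] = bad

        sweeps.append(FrequencySweep(
            temperature=temp, omega=omega.copy(), g_prime=gp,
            g_double_prime=gpp, mode=SweepMode.CS, amplitude=300.0, gap=0.5,
            sample_id=f"synthetic_seed{s.seed}"))

    manifest = {
        "mw": dist.mw, "mn": dist.mn, "pdi": dist.pdi,
        "components": [list(c) for c in s.components],
        "reference_temperature": s.reference_temperature,
        "log10_at": {t: a for t, a in zip(s.temperatures, s.true_log10_at)},
        "omega_crossover": crossovers,
        "corrupted_indices": corrupted,
        "td_true": s.td_true,
        "lve_upper_true": s.lve_upper_true,
        "parent_modes": {"g": parent.g.tolist(), "lam": parent.lam.tolist()},
        "reptation": {"g_n": s.reptation.g_n, "me": s.reptation.me,
                      "beta": s.reptation.beta,
                      "kernel_prefactor": s.reptation.kernel_prefactor,
                      "kernel_exponent": s.reptation.kernel_exponent},
        "noise_sigma": s.noise_sigma,
        "seed": s.seed,
    }
    return sweeps, manifest


def generate_amplitude_sweep(s: SyntheticScenario,
                             temperature: float | None = None
                             ) -> tuple[AmplitudeSweep, dict]:
    """Amplitude sweep: plateau up to the true LVE bound, power-law softening
    beyond it (strain-softening typical of fibrillar gels)."""
    rng = np.random.default_rng(s.seed + 1)
    temperature = s.temperatures[0] if temperature is None else temperature
    amp = np.logspace(-3, 1, 33)
    plateau = s.reptation.g_n
    gp = np.where(amp <= s.lve_upper_true, plateau,
                  plateau * (amp / s.lve_upper_true) ** -0.35)
    gpp = np.where(amp <= s.lve_upper_true, 0.3 * plateau,
                   0.3 * plateau * (amp / s.lve_upper_true) ** -0.2)
    if s.noise_sigma > 0:
        gp = gp * np.exp(s.noise_sigma * rng.standard_normal(amp.size))
        gpp = gpp * np.exp(s.noise_sigma * rng.standard_normal(amp.size))
    sweep = AmplitudeSweep(temperature=temperature, fixed_omega=1.0,
                           amplitude=amp, g_prime=gp, g_double_prime=gpp,
                           mode=SweepMode.CD,
                           sample_id=f"synthetic_seed{s.seed}")
    truth = {"lve_upper_true": s.lve_upper_true, "plateau_g_prime": plateau,
             "seed": s.seed}
    return sweep, truth


def generate_temperature_sweep(s: SyntheticScenario
                               ) -> tuple[TemperatureSweep, dict]:
    """Temperature sweep: sigmoidal viscosity collapse and a tanδ peak, both
    centered on the true denaturation temperature."""
    rng = np.random.default_rng(s.seed + 2)
    temp = np.arange(23.0, 45.0 + 1e-9, 0.25)
    eta0 = 100.0
    eta = eta0 / (1.0 + np.exp((temp - s.td_true) / 0.8))
    tand = 0.3 + 1.0 * np.exp(-0.5 * ((temp - s.td_true) / 1.5) ** 2)
    if s.noise_sigma > 0:
        eta = eta * np.exp(s.noise_sigma * rng.standard_normal(temp.size))
        tand = tand * np.exp(s.noise_sigma * rng.standard_normal(temp.size))
    sweep = TemperatureSweep(temperature=temp, viscosity=eta, tan_delta=tand)
    truth = {"td_true": s.td_true, "eta0": eta0, "seed": s.seed}
    return sweep, truth
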
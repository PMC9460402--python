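"""Double-reptation transform between w(M) and stress relaxation.

The mixing rule for an entangled, polydisperse melt/gel is

    G_r(t) = G_N ( ∫_{Me}^{∞} F(M, t)^{1/β} w(M) dM/M )^β

with plateau modulus G_N, entanglement mass Me = Mc/2, mixing exponent β
(β = 2 is double reptation) and a single-exponential relaxation kernel
F(M, t) = exp(−t/λ_d(M)), λ_d(M) = K·M^α (α ≈ 3.4, the reptation scaling).
w(M) is a weight-fraction density per dlnM, normalized to ∫ w dlnM = 1.

The inverse problem is solved parametrically: w(M) is a mixture of at most
three log-normal components in ln M, fitted to log G_r by deterministic
multistart least squares.  Note that K only sets the absolute time scale and
is perfectly degenerate with the mass scale (doubling K is equivalent to
shifting every mass by 2^{-1/α}); absolute Mw accuracy therefore depends
entirely on how K is calibrated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .data import RelaxationCurve, ValidationError
from .spectrum import ContinuousSpectrum, _log_trapezoid_weights, relaxation_modulus

__all__ = [
    "ReptationParams",
    "MWDistribution",
    "MWDInversionResult",
    "reptation_kernel",
    "forward_reptation",
    "invert_mwd",
    "spectrum_to_relaxation_target",
    "summarize_distribution",
    "lognormal_components",
]


@dataclass(frozen=True)
class ReptationParams:
    """Parameters of the double-reptation transform.

    g_n: plateau modulus, Pa.  me: entanglement mass, g/mol (mc = 2·me is
    derived, never set independently).  beta: mixing exponent.  kernel
    relaxation time λ_d(M) = kernel_prefactor · M^kernel_exponent, s.
    """

    g_n: float
    me: float
    beta: float = 2.0
    kernel_prefactor: float = 1e-19
    kernel_exponent: float = 3.4

    def __post_init__(self) -> None:
        for name in ("g_n", "me", "beta", "kernel_prefactor", "kernel_exponent"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def mc(self) -> float:
        """Critical mass for entangled dynamics; mc = 2·me by construction."""
        return 2.0 * self.me

    def lambda_d(self, mass) -> np.ndarray:
        return self.kernel_prefactor * np.asarray(mass, dtype=float) ** self.kernel_exponent

    @property
    def tau_e(self) -> float:
        """Kernel time of a single entanglement strand; times below it are
        Rouse-dominated and outside the model's domain."""
        return float(self.lambda_d(self.me))


def reptation_kernel(mass, time, p: ReptationParams) -> np.ndarray:
    """Monodisperse relaxation kernel F(M, t) = exp(−t/λ_d(M)), in (0, 1]."""
    mass = np.asarray(mass, dtype=float)
    time = np.asarray(time, dtype=float)
    if np.any(mass <= p.me):
        raise ValidationError("unentangled mass at or below Me is outside the "
                              "double-reptation domain")
    if np.any(time < 0):
        raise ValidationError("time must be nonnegative")
    return np.exp(-time / p.lambda_d(mass))


def lognormal_components(mw: float, pdi: float) -> list[tuple[float, float, float]]:
    """Single log-normal component with the requested Mw and PDI.

    Components are (weight, median mass in g/mol, σ of ln M).  For a log-normal
    weight density, Mw = m·e^{σ²/2}, Mn = m·e^{−σ²/2}, PDI = e^{σ²}.
    """
    if pdi < 1:
        raise ValidationError("PDI must be >= 1")
    sigma = math.sqrt(math.log(pdi)) if pdi > 1 else 1e-6
    median = mw / math.exp(sigma ** 2 / 2.0)
    return [(1.0, median, sigma)]


@dataclass
class MWDistribution:
    """Weight-based molecular-weight distribution on a log-spaced mass grid.

    ``w`` is the weight-fraction density per dlnM, normalized so that
    ∫ w dlnM = 1 (trapezoid on the grid).  Moments:

        Mw = ∫ w·M dlnM,    Mn = 1 / ∫ (w/M) dlnM,    PDI = Mw/Mn.
    """

    mass_grid: np.ndarray
    w: np.ndarray
    components: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        self.mass_grid = np.asarray(self.mass_grid, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.mass_grid.shape != self.w.shape:
            raise ValidationError("mass grid and w must have equal length")
        if np.any(self.mass_grid <= 0):
            raise ValidationError("mass grid must be positive")
        if self.mass_grid.size > 1 and np.any(np.diff(self.mass_grid) <= 0):
            raise ValidationError("mass grid must be strictly increasing")
        if np.any(self.w < 0):
            raise ValidationError("w must be nonnegative")
        total = float(self.w @ _log_trapezoid_weights(self.mass_grid))
        if total <= 0:
            raise ValidationError("w must have positive total mass")
        if abs(total - 1.0) > 1e-6:
            warnings.warn("w(M) was not normalized; renormalizing", stacklevel=2)
        self.w = self.w / total

    @classmethod
    def from_components(cls, components, mass_grid) -> "MWDistribution":
        """Mixture of log-normal components (weight, median g/mol, σ_lnM)."""
        mass_grid = np.asarray(mass_grid, dtype=float)
        lnm = np.log(mass_grid)
        w = np.zeros_like(mass_grid)
        for weight, median, sigma in components:
            z = (lnm - math.log(median)) / sigma
            w += weight * np.exp(-0.5 * z * z) / (sigma * math.sqrt(2 * math.pi))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # truncation renormalization expected
            return cls(mass_grid=mass_grid, w=w,
                       components=[tuple(c) for c in components])

    def _weights(self) -> np.ndarray:
        return self.w * _log_trapezoid_weights(self.mass_grid)

    @property
    def mw(self) -> float:
        wq = self._weights()
        return float((wq * self.mass_grid).sum() / wq.sum())

    @property
    def mn(self) -> float:
        wq = self._weights()
        return float(wq.sum() / (wq / self.mass_grid).sum())

    @property
    def pdi(self) -> float:
        return self.mw / self.mn


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def summarize_distribution(dist, mn: float | None = None) -> dict:
    """Mw/Mn/PDI report, rounded the way molecular-weight tables print them
    (Mw, Mn to 2 significant figures; PDI to 1 decimal).

    Accepts an :class:`MWDistribution` or a raw ``(mw, mn)`` pair.
    """
    if isinstance(dist, MWDistribution):
        mw_val, mn_val = dist.mw, dist.mn
    else:
        if mn is None:
            raise ValueError("pass an MWDistribution or both mw and mn")
        mw_val, mn_val = float(dist), float(mn)
    if mw_val <= 0 or mn_val <= 0:
        raise ValidationError("Mw and Mn must be positive")
    pdi = mw_val / mn_val
    return {
        "mw_g_per_mol": mw_val,
        "mn_g_per_mol": mn_val,
        "pdi": pdi,
        "mw_rounded": _round_sig(mw_val, 2),
        "mn_rounded": _round_sig(mn_val, 2),
        "pdi_rounded": round(pdi, 1),
    }


def forward_reptation(dist: MWDistribution, time, p: ReptationParams,
                      warn_coarse: bool = True) -> RelaxationCurve:
    """Reptation modulus G_r(t) of a distribution via the mixing rule.

    The dM/M measure in the mixing integral is dlnM, evaluated by trapezoid
    quadrature on the distribution's grid.
    """
    time = np.asarray(time, dtype=float)
    if np.any(dist.mass_grid <= p.me):
        raise ValidationError("mass grid must lie strictly above Me")
    if warn_coarse and dist.mass_grid.size > 1:
        span = math.log10(dist.mass_grid[-1] / dist.mass_grid[0])
        if span > 0 and (dist.mass_grid.size - 1) / span < 5:
            warnings.warn("mass grid coarser than 5 points/decade", stacklevel=2)
    wq = dist._weights()
    wq = wq / wq.sum()
    lam_d = p.lambda_d(dist.mass_grid)
    # F^{1/β} = exp(−t/(β·λ_d))
    s = np.exp(-np.outer(time, 1.0 / (p.beta * lam_d))) @ wq
    g = p.g_n * s ** p.beta

    # model-level sanity: monotone nonincreasing and pinched between the
    # all-fastest and all-slowest monodisperse kernels of the supported masses
    supported = wq > 0
    lam_lo = lam_d[supported][0]
    lam_hi = lam_d[supported][-1]
    assert np.all(np.diff(g) <= 1e-9 * p.g_n + 1e-12)
    assert np.all(g <= p.g_n * (1 + 1e-9))
    assert np.all(g >= p.g_n * np.exp(-time / lam_lo) * (1 - 1e-9) - 1e-12)
    assert np.all(g <= p.g_n * np.exp(-time / lam_hi) * (1 + 1e-9) + 1e-12)
    return RelaxationCurve(time=time, modulus=g)


def spectrum_to_relaxation_target(spec: ContinuousSpectrum, p: ReptationParams,
                                  points_per_decade: int = 10,
                                  window=(1e-4, 0.99)) -> RelaxationCurve:
    """Turn an inverted relaxation spectrum into a reptation-modulus target.

    G(t) is evaluated from H(λ) on a log time grid and restricted to
    t > τ_e = K·Me^α, discarding sub-entanglement (Rouse) times that carry no
    information about w(M); within the retained window the curve is further
    clipped to G/G_N ∈ ``window`` so the fit sees neither the unrelaxed plateau
    nor numerically empty tail.  The absolute Pa scale is kept: the retained
    window is read directly as G_r.
    """
    t_lo = max(p.tau_e, float(spec.lambda_grid[0]))
    t_hi = float(spec.lambda_grid[-1]) * 10.0
    if t_lo >= t_hi:
        raise ValidationError("data window entirely sub-entanglement: "
                              f"tau_e={p.tau_e:.3g}s exceeds the spectrum range")
    n = int(round(math.log10(t_hi / t_lo) * points_per_decade)) + 1
    time = np.logspace(math.log10(t_lo), math.log10(t_hi), max(n, 5))
    curve = relaxation_modulus(spec, time)
    ratio = curve.modulus / p.g_n
    keep = (ratio >= window[0]) & (ratio <= window[1])
    if not np.any(keep):
        raise ValidationError("no usable relaxation window: G(t)/G_N never "
                              f"enters [{window[0]}, {window[1]}]")
    return RelaxationCurve(time=time[keep], modulus=curve.modulus[keep])


# ---------------------------------------------------------------------------
# parametric inversion


@dataclass
class MWDInversionResult:
    distribution: MWDistribution
    rms_log_residual: float
    family: str
    params: ReptationParams
    n_starts: int


def _family_k(family: str) -> int:
    table = {"lognormal_1": 1, "lognormal_mix_2": 2, "lognormal_mix_3": 3}
    if family not in table:
        raise ValueError(f"unknown family '{family}'")
    return table[family]


def _unpack(theta: np.ndarray, k: int):
    """theta = [logits (k-1), mu_1..k, ln sigma_1..k] -> components."""
    logits = np.concatenate([theta[:k - 1], [0.0]])
    logits = logits - logits.max()
    weights = np.exp(logits)
    weights /= weights.sum()
    mus = theta[k - 1:2 * k - 1]
    sigmas = np.exp(theta[2 * k - 1:3 * k - 1])
    return [(float(wi), float(math.exp(mu)), float(sig))
            for wi, mu, sig in zip(weights, mus, sigmas)]


def invert_mwd(target: RelaxationCurve, p: ReptationParams,
               family: str = "lognormal_1",
               mass_points_per_decade: int = 30,
               mass_max: float = 1e10) -> MWDInversionResult:
    """Fit a log-normal-mixture w(M) to a reptation-modulus curve.

    Least squares on log G_r over the mixture parameters (component weights on
    the simplex, locations and widths in ln M), started from a deterministic
    grid of initializations so the result is reproducible without seeds.
    """
    k = _family_k(family)
    n_params = 3 * k - 1
    time = np.asarray(target.time, dtype=float)
    g = np.asarray(target.modulus, dtype=float)
    keep = (g > p.g_n * 1e-4) & (g < p.g_n * 0.999) & (time > p.tau_e)
    time, g = time[keep], g[keep]
    if time.size <= n_params:
        raise ValidationError(
            f"target has {time.size} usable points but the {family} family "
            f"needs more than {n_params}")
    log_g = np.log(g)

    grid_lo = p.me * 1.0001
    n_grid = int(round(math.log10(mass_max / grid_lo) * mass_points_per_decade)) + 1
    mass_grid = np.logspace(math.log10(grid_lo), math.log10(mass_max), n_grid)
    lam_d = p.lambda_d(mass_grid)
    decay = np.exp(-np.outer(time, 1.0 / (p.beta * lam_d)))
    lnm = np.log(mass_grid)
    # cell edges in ln M: mass of each component is integrated per cell via
    # the normal CDF, which stays exact for components narrower than the grid
    edges = np.concatenate([[lnm[0] - 0.5 * (lnm[1] - lnm[0])],
                            0.5 * (lnm[1:] + lnm[:-1]),
                            [lnm[-1] + 0.5 * (lnm[-1] - lnm[-2])]])

    def cell_masses(comps):
        wq = np.zeros_like(mass_grid)
        for wi, median, sigma in comps:
            z = (edges - math.log(median)) / sigma
            cdf = ndtr(z)
            wq += wi * np.diff(cdf)
        return wq

    def model_log_g(theta):
        wq = cell_masses(_unpack(theta, k))
        tot = wq.sum()
        if tot <= 0:
            return np.full_like(time, 1e3)
        wq /= tot
        s = decay @ wq
        return math.log(p.g_n) + p.beta * np.log(np.maximum(s, 1e-300))

    def residual(theta):
        return model_log_g(theta) - log_g

    # characteristic mass from the mid-decay time
    ratio = g / p.g_n
    idx = int(np.argmin(np.abs(ratio - 0.2)))
    m_est = (time[idx] / p.kernel_prefactor) ** (1.0 / p.kernel_exponent)
    m_est = min(max(m_est, grid_lo * 3), mass_max / 100)
    mu_est = math.log(m_est)

    starts = []
    if k == 1:
        for dmu in (-0.8, 0.0, 0.8):
            for sig in (0.3, 0.7, 1.1):
                starts.append(np.array([mu_est + dmu, math.log(sig)]))
    else:
        offsets = np.linspace(-0.9, 0.9, k)
        for spread in (0.5, 1.0, 1.5):
            for sig in (0.3, 0.7):
                theta = np.concatenate([
                    np.zeros(k - 1),
                    mu_est + offsets * spread,
                    np.full(k, math.log(sig)),
                ])
                starts.append(theta)

    lb = np.concatenate([np.full(k - 1, -8.0),
                         np.full(k, math.log(grid_lo * 2)),
                         np.full(k, math.log(1e-3))])
    ub = np.concatenate([np.full(k - 1, 8.0),
                         np.full(k, math.log(mass_max / 30)),
                         np.full(k, math.log(2.5))])

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(residual, theta0, bounds=(lb, ub), method="trf",
                                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=600)
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, sol.x)
    if best is None or best[0] > 0.5:
        raise ValidationError("multistart inversion failed to converge "
                              f"(best rms {math.inf if best is None else best[0]:.3g} "
                              "log units)")
    rms, theta = best
    comps = _unpack(theta, k)
    dist = MWDistribution.from_components(comps, mass_grid)
    return MWDInversionResult(distribution=dist, rms_log_residual=rms,
                              family=family, params=p, n_starts=len(starts))
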
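"""Model-based smoothing, anomaly flagging and crossover extrapolation.

Frequency sweeps on soft, thermally fragile gels are often inhomogeneous:
noisy tails near the denaturation temperature, no G′ = G″ crossover, or
multiple apparent crossovers.  This module fits a physical model to the clean
low-frequency portion of a sweep, flags points that break away from it, and
locates (or extrapolates) the crossover on the fitted curves.

Two model families are available:

* ``maxwell_modes`` — a sum of Maxwell modes with shared (G_i, λ_i) fitted
  simultaneously to log G′ and log G″; guarantees G″ > G′ at low frequency and
  a single terminal crossover.  The default.
* ``loglog_poly`` — independent low-order polynomials in log-log space; no
  physics, maximal flexibility.

Anomaly rule: a trusted prefix grows from the low-frequency end; each further
point is flagged when its log-residual exceeds k times the robust (MAD-based)
residual scale of the trusted points, floored at 0.01 log units so that
numerically exact data cannot self-flag.  Model complexity is chosen by the
small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .data import FrequencySweep, ValidationError
from .spectrum import (MaxwellSpectrum, _maxwell_kernels, _nnls_safe,
                       forward_moduli_discrete)

__all__ = [
    "FitResult",
    "CrossoverPoint",
    "CurveUnusableError",
    "fit_modulus_curves",
    "find_crossover",
    "check_crossover_monotonicity",
]

_SCALE_FLOOR = 0.01  # log units; ~1% modulus


class CurveUnusableError(ValueError):
    """Raised when too many points are anomalous for any trustworthy fit."""


@dataclass
class FitResult:
    """A fitted, de-noised frequency sweep."""

    sample_id: str
    temperature: float
    model: str
    spectrum: MaxwellSpectrum | None
    poly_coeffs: tuple[np.ndarray, np.ndarray] | None
    n_modes_or_degree: int
    flagged_indices: list[int]
    rms_log_residual: float
    omega_window: tuple[float, float]
    sweep: FrequencySweep | None = None

    @classmethod
    def from_maxwell(cls, spectrum: MaxwellSpectrum, omega_window,
                     sample_id: str = "", temperature: float = math.nan) -> "FitResult":
        """Exact FitResult from known Maxwell modes (no fitting)."""
        return cls(sample_id=sample_id, temperature=temperature,
                   model="maxwell_modes", spectrum=spectrum, poly_coeffs=None,
                   n_modes_or_degree=spectrum.n_modes, flagged_indices=[],
                   rms_log_residual=0.0, omega_window=tuple(omega_window))

    def g_prime(self, omega) -> np.ndarray:
        return self._moduli(omega)[0]

    def g_double_prime(self, omega) -> np.ndarray:
        return self._moduli(omega)[1]

    def _moduli(self, omega):
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        if self.model == "maxwell_modes":
            return forward_moduli_discrete(self.spectrum, omega)
        cp, cpp = self.poly_coeffs
        lw = np.log10(omega)
        return 10.0 ** np.polyval(cp, lw), 10.0 ** np.polyval(cpp, lw)

    def fitted_curves(self, n: int = 200) -> pd.DataFrame:
        """Dense (ω, G′_fit, G″_fit) table over the data window."""
        omega = np.logspace(math.log10(self.omega_window[0]),
                            math.log10(self.omega_window[1]), n)
        gp, gpp = self._moduli(omega)
        return pd.DataFrame({"omega_rad_per_s": omega, "g_prime_pa": gp,
                             "g_double_prime_pa": gpp})

    def retained_indices(self) -> np.ndarray:
        n = len(self.sweep) if self.sweep is not None else 0
        return np.array([i for i in range(n) if i not in set(self.flagged_indices)])


@dataclass
class CrossoverPoint:
    omega_c: float
    g_c: float
    extrapolated: bool
    temperature: float
    n_roots: int = 1

    def __post_init__(self) -> None:
        if self.omega_c <= 0 or self.g_c <= 0:
            raise ValidationError("crossover must have positive omega and modulus")


# ---------------------------------------------------------------------------
# model backends


def _maxwell_init(omega, gp, gpp, n_modes, pad_decades=0.0):
    lam = np.logspace(math.log10(1.0 / omega[-1]) - pad_decades,
                      math.log10(1.0 / omega[0]) + pad_decades, n_modes)
    if n_modes == 1:
        lam = np.array([1.0 / math.sqrt(omega[0] * omega[-1])])
    kp, kpp = _maxwell_kernels(np.outer(omega, lam))
    a = np.vstack([kp, kpp])
    y = np.concatenate([gp, gpp])
    g0 = _nnls_safe(a / y[:, None], np.ones_like(y))
    g0 = np.maximum(g0, max(y.max() * 1e-8, 1e-12))
    return np.concatenate([np.log(g0), np.log(lam)])


def _fit_maxwell(omega, gp, gpp, n_modes, x0=None):
    lg = np.concatenate([np.log(gp), np.log(gpp)])

    def residual(x):
        x = np.clip(x, -600.0, 600.0)  # keep exp() finite and positive
        g = np.exp(x[:n_modes])
        lam = np.exp(x[n_modes:])
        kp, kpp = _maxwell_kernels(np.outer(omega, lam))
        mp = kp @ g
        mpp = kpp @ g
        return np.concatenate([np.log(np.maximum(mp, 1e-300)),
                               np.log(np.maximum(mpp, 1e-300))]) - lg

    if x0 is None:
        starts = [_maxwell_init(omega, gp, gpp, n_modes, pad)
                  for pad in (0.0, 1.0)]
    else:
        starts = [x0]
    sol = None
    max_nfev = 600 if x0 is not None else 3000  # warm starts converge fast
    for start in starts:
        cand = least_squares(residual, start, method="lm", xtol=1e-15,
                             ftol=1e-15, gtol=1e-15, max_nfev=max_nfev)
        if sol is None or cand.cost < sol.cost:
            sol = cand
        if sol.cost < 1e-20:
            break
    x = np.clip(sol.x, -600.0, 600.0)
    g = np.exp(x[:n_modes])
    lam = np.exp(x[n_modes:])
    # collapse near-duplicate relaxation times so MaxwellSpectrum stays valid
    order = np.argsort(lam)
    g, lam = g[order], lam[order]
    merged_g, merged_lam = [g[0]], [lam[0]]
    for gi, li in zip(g[1:], lam[1:]):
        if li / merged_lam[-1] < 1.0 + 1e-9:
            merged_g[-1] += gi
        else:
            merged_g.append(gi)
            merged_lam.append(li)
    spec = MaxwellSpectrum(g=np.array(merged_g), lam=np.array(merged_lam))
    return spec, x


def _maxwell_predict(spec, omega):
    return forward_moduli_discrete(spec, omega)


def _fit_poly(omega, gp, gpp, degree):
    lw = np.log10(omega)
    cp = np.polyfit(lw, np.log10(gp), degree)
    cpp = np.polyfit(lw, np.log10(gpp), degree)
    return cp, cpp


def _poly_predict(coeffs, omega):
    cp, cpp = coeffs
    lw = np.log10(omega)
    return 10.0 ** np.polyval(cp, lw), 10.0 ** np.polyval(cpp, lw)


def _log_residuals(pred, gp, gpp):
    mp, mpp = pred
    return np.log(mp) - np.log(gp), np.log(mpp) - np.log(gpp)


def _robust_scale(res: np.ndarray) -> float:
    mad = float(np.median(np.abs(res - np.median(res))))
    return max(1.4826 * mad, _SCALE_FLOOR)


def _aicc(n_obs: int, n_params: int, sse: float) -> float:
    if n_obs <= n_params + 1:
        return math.inf
    aic = n_obs * math.log(max(sse, 1e-300) / n_obs) + 2 * n_params
    return aic + 2 * n_params * (n_params + 1) / (n_obs - n_params - 1)


def _run_one_complexity(omega, gp, gpp, model, complexity, k_flag):
    n = omega.size
    n_params = 2 * complexity if model == "maxwell_modes" else 2 * (complexity + 1)
    if n < n_params + 1:
        raise ValidationError(
            f"{model} with complexity {complexity} has {n_params} parameters "
            f"but only {n} data points")
    # the trusted prefix must overdetermine the model (otherwise its residuals
    # say nothing about the noise scale) and span enough of the frequency
    # window to pin down every mode it can see; tail artifacts sit at high
    # frequency, so starting from half the sweep keeps them outside
    m0 = min(max(n_params + 2, math.ceil(n / 2)), n)

    def fit(idx, warm=None):
        o, a, b = omega[idx], gp[idx], gpp[idx]
        if model == "maxwell_modes":
            spec, x = _fit_maxwell(o, a, b, complexity, x0=warm)
            return (spec, x)
        return (_fit_poly(o, a, b, complexity), None)

    def predict(state, o):
        if model == "maxwell_modes":
            return _maxwell_predict(state[0], o)
        return _poly_predict(state[0], o)

    trusted = list(range(m0))
    state = fit(trusted)
    flagged: list[int] = []
    prev_flagged = False
    for j in range(m0, n):
        rp, rpp = _log_residuals(predict(state, omega[trusted]),
                                 gp[trusted], gpp[trusted])
        scale = _robust_scale(np.concatenate([rp, rpp]))
        pj = predict(state, omega[j:j + 1])
        r_j = max(abs(math.log(pj[0][0]) - math.log(gp[j])),
                  abs(math.log(pj[1][0]) - math.log(gpp[j])))
        if r_j > k_flag * scale:
            # rescue: a point at the frontier of a clean run can break the
            # one-step-ahead prediction simply because it carries structure
            # the model has not seen yet (an emerging fast mode); if a refit
            # that includes it absorbs the point to within tolerance, it is
            # signal, not artifact.  Once a point has been flagged, the run is
            # broken and later failures are flagged outright — an artifact
            # tail must not be re-absorbed piecewise.
            rescued = False
            if not prev_flagged:
                # cold start: the rescue fit must be free to place a new mode
                # where the frontier point demands one
                trial = fit(trusted + [j])
                tp = predict(trial, omega[j:j + 1])
                r_trial = max(abs(math.log(tp[0][0]) - math.log(gp[j])),
                              abs(math.log(tp[1][0]) - math.log(gpp[j])))
                rp_t, rpp_t = _log_residuals(predict(trial, omega[trusted]),
                                             gp[trusted], gpp[trusted])
                scale_t = _robust_scale(np.concatenate([rp_t, rpp_t]))
                if r_trial <= k_flag * scale_t and scale_t <= 2.0 * scale:
                    trusted.append(j)
                    state = trial
                    rescued = True
            if not rescued:
                flagged.append(j)
                prev_flagged = True
        else:
            trusted.append(j)
            prev_flagged = False
            # refit on every acceptance: one-step-ahead prediction is the
            # flagging yardstick, so the model must track the frontier
            warm = state[1] if model == "maxwell_modes" else None
            state = fit(trusted, warm=warm)

    if len(flagged) > 0.5 * n:
        raise CurveUnusableError(
            f"{len(flagged)} of {n} points flagged; curve unusable")

    rp, rpp = _log_residuals(predict(state, omega[trusted]),
                             gp[trusted], gpp[trusted])
    res = np.concatenate([rp, rpp])
    rms = float(np.sqrt(np.mean(res ** 2)))
    # complexities must compete over the same observations: a flagged point is
    # charged its threshold residual, otherwise a model that flags the
    # informative tail wins on its easier retained subset
    scale_final = _robust_scale(res)
    sse_full = float(res @ res) + len(flagged) * 2 * (k_flag * scale_final) ** 2
    aicc = _aicc(2 * n, n_params, sse_full)
    return state, flagged, rms, aicc


def fit_modulus_curves(sweep: FrequencySweep, model: str = "maxwell_modes",
                       max_complexity: int = 4, *,
                       exact_complexity: int | None = None,
                       k_flag: float = 4.0) -> FitResult:
    """Fit log G′/log G″ versus log ω with anomaly flagging.

    ``max_complexity`` bounds the number of Maxwell modes (or the polynomial
    degree); the complexity is chosen by AICc unless ``exact_complexity`` pins
    it.  Flagged points are excluded from the fit and the model extrapolates
    over them.
    """
    if model not in ("maxwell_modes", "loglog_poly"):
        raise ValueError(f"unknown model '{model}'")
    if max_complexity < 1:
        raise ValidationError("max_complexity must be >= 1")
    omega, gp, gpp = sweep.omega, sweep.g_prime, sweep.g_double_prime
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise ValidationError("log-space fitting requires positive moduli")

    n = omega.size
    if exact_complexity is not None:
        candidates = [exact_complexity]
    else:
        def feasible(c):
            n_params = 2 * c if model == "maxwell_modes" else 2 * (c + 1)
            return n >= n_params + 1
        candidates = [c for c in range(1, max_complexity + 1) if feasible(c)]
        if not candidates:
            raise ValidationError(f"too few points ({n}) for any model up to "
                                  f"complexity {max_complexity}")

    best = None
    last_error: Exception | None = None
    for c in candidates:
        try:
            state, flagged, rms, aicc = _run_one_complexity(
                omega, gp, gpp, model, c, k_flag)
        except (ValidationError, CurveUnusableError) as exc:
            # a candidate too simple for the data flags everything; that is a
            # lost model-selection race, not a broken curve — unless every
            # candidate ends the same way
            last_error = exc
            continue
        if best is None or aicc < best[0]:
            best = (aicc, c, state, flagged, rms)
    if best is None:
        if isinstance(last_error, CurveUnusableError):
            raise last_error
        raise last_error if last_error is not None else ValidationError(
            "no model could be fitted")
    _, c, state, flagged, rms = best
    return FitResult(
        sample_id=sweep.sample_id,
        temperature=sweep.temperature,
        model=model,
        spectrum=state[0] if model == "maxwell_modes" else None,
        poly_coeffs=state[0] if model == "loglog_poly" else None,
        n_modes_or_degree=c,
        flagged_indices=sorted(flagged),
        rms_log_residual=rms,
        omega_window=(float(omega[0]), float(omega[-1])),
        sweep=sweep,
    )


def find_crossover(fit: FitResult, search_decades_beyond_data: float = 1.0
                   ) -> CrossoverPoint | None:
    """Locate the G′ = G″ crossover on the fitted curves.

    Searches the data window first, then up to ``search_decades_beyond_data``
    beyond it on both sides (such roots are marked extrapolated).  With
    multiple roots, the lowest-frequency root where G′−G″ crosses from below
    (the physically ordered flow-to-rubber transition) is returned, with the
    root count reported.  Returns None for gel-like curves with no crossover
    in the extended window.
    """
    lo = math.log10(fit.omega_window[0]) - search_decades_beyond_data
    hi = math.log10(fit.omega_window[1]) + search_decades_beyond_data

    def diff(lw):
        gp, gpp = fit._moduli(10.0 ** np.asarray(lw, dtype=float))
        return np.log(gp) - np.log(gpp)

    grid = np.linspace(lo, hi, 2000)
    d = diff(grid)
    sign_change = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    roots = []
    for i in sign_change:
        root = brentq(lambda lw: float(diff([lw])[0]), grid[i], grid[i + 1],
                      xtol=1e-13, rtol=1e-15)
        rising = d[i + 1] > d[i]
        roots.append((root, rising))
    exact_zero = np.flatnonzero(d == 0.0)
    for i in exact_zero:
        rising = d[min(i + 1, len(d) - 1)] >= d[max(i - 1, 0)]
        roots.append((float(grid[i]), rising))
    if not roots:
        return None  # gel-like, no crossover
    roots.sort()
    preferred = [r for r, rising in roots if rising]
    lw_c = preferred[0] if preferred else roots[0][0]
    omega_c = 10.0 ** lw_c
    g_c = float(fit.g_prime(omega_c)[0])
    extrapolated = not (fit.omega_window[0] <= omega_c <= fit.omega_window[1])
    return CrossoverPoint(omega_c=float(omega_c), g_c=g_c,
                          extrapolated=extrapolated,
                          temperature=fit.temperature, n_roots=len(roots))


def check_crossover_monotonicity(points: list[CrossoverPoint]) -> dict:
    """Check that the crossover frequency strictly increases with temperature.

    A failing pair marks the sweep set as suspect for downstream master-curve
    construction (faster relaxation is expected at higher temperature).
    """
    pts = sorted(points, key=lambda p: p.temperature)
    temps = [p.temperature for p in pts]
    if len(set(temps)) < 2:
        raise ValidationError("need >= 2 crossovers at distinct temperatures")
    pairs = []
    overall = True
    for a, b in zip(pts[:-1], pts[1:]):
        ok = b.omega_c > a.omega_c
        overall = overall and ok
        pairs.append({"temperature_pair": (a.temperature, b.temperature),
                      "omega_pair": (a.omega_c, b.omega_c), "pass": ok})
    return {"pairs": pairs, "monotone": overall,
            "suspect_for_tts": not overall}
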
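"""Time–temperature superposition: shift factors and master-curve assembly.

Sweeps taken at several temperatures are superposed onto a single reference-
temperature curve by shifting each sweep horizontally in frequency (ω → a_T·ω;
optional vertical modulus shifts b_T are off by default).  Shifts are found by
sequential pairwise registration of the *fitted* curves outward from the
reference temperature, minimizing the summed squared difference of log G′ and
log G″ over the overlap window; registering fitted curves rather than raw
points means overlapping sweeps need not share abscissae.  No WLF or Arrhenius
form is imposed on a_T(T): the handful of temperatures of a typical gel study
cannot constrain one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .data import ValidationError
from .fitting import FitResult

__all__ = ["ShiftFactorSet", "MasterCurve", "TTSError",
           "estimate_shift_factors", "build_master_curve"]

_MAX_SHIFT_DECADES = 4.0


class TTSError(ValueError):
    """Raised when sweeps cannot be registered (no achievable overlap)."""


@dataclass
class ShiftFactorSet:
    reference_temperature: float
    entries: list[tuple[float, float, float]]  # (T °C, log10 aT, log10 bT)

    def __post_init__(self) -> None:
        temps = [t for t, _, _ in self.entries]
        if len(set(temps)) != len(temps):
            raise ValidationError("temperatures in a shift set must be unique")
        ref = [e for e in self.entries if e[0] == self.reference_temperature]
        if not ref or abs(ref[0][1]) > 1e-12 or abs(ref[0][2]) > 1e-12:
            raise ValidationError("the reference-temperature entry must have "
                                  "zero shifts")

    def log10_at(self, temperature: float) -> float:
        for t, a, _ in self.entries:
            if t == temperature:
                return a
        raise KeyError(f"no shift entry for {temperature} °C")

    def log10_bt(self, temperature: float) -> float:
        for t, _, b in self.entries:
            if t == temperature:
                return b
        raise KeyError(f"no shift entry for {temperature} °C")


@dataclass
class MasterCurve:
    reference_temperature: float
    omega: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    source_temperature_per_point: np.ndarray
    overlap_rms_log: float = 0.0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_double_prime = np.asarray(self.g_double_prime, dtype=float)
        self.source_temperature_per_point = np.asarray(
            self.source_temperature_per_point, dtype=float)
        if np.any(self.omega <= 0):
            raise ValidationError("master-curve omega must be positive")
        if self.omega.size > 1 and np.any(np.diff(self.omega) <= 0):
            raise ValidationError("master-curve omega must be strictly increasing")
        if np.any(self.g_prime <= 0) or np.any(self.g_double_prime <= 0):
            raise ValidationError("master-curve moduli must be positive")

    def __len__(self) -> int:
        return len(self.omega)


def _pair_objective(fit_ref: FitResult, fit_mov: FitResult,
                    ref_shift: float, vertical: bool):
    """Cost of registering fit_mov against fit_ref as a function of the moving
    sweep's (log10 aT, log10 bT); fit_ref is already at ref_shift."""
    ref_lo = math.log10(fit_ref.omega_window[0]) + ref_shift
    ref_hi = math.log10(fit_ref.omega_window[1]) + ref_shift
    mov_lo = math.log10(fit_mov.omega_window[0])
    mov_hi = math.log10(fit_mov.omega_window[1])

    def cost(la: float, lb: float = 0.0) -> float:
        lo = max(ref_lo, mov_lo + la)
        hi = min(ref_hi, mov_hi + la)
        if hi - lo < 0.1:  # require a tenth of a decade of overlap
            return math.inf
        grid = np.linspace(lo, hi, 60)
        w_ref = 10.0 ** (grid - ref_shift)
        w_mov = 10.0 ** (grid - la)
        rp, rpp = fit_ref._moduli(w_ref)
        mp, mpp = fit_mov._moduli(w_mov)
        dp = np.log10(rp) - np.log10(mp) - lb
        dpp = np.log10(rpp) - np.log10(mpp) - lb
        return float(np.mean(dp ** 2) + np.mean(dpp ** 2))

    return cost


def _register_pair(fit_ref: FitResult, fit_mov: FitResult, ref_shift: float,
                   vertical: bool) -> tuple[float, float]:
    cost = _pair_objective(fit_ref, fit_mov, ref_shift, vertical)
    coarse = np.linspace(-_MAX_SHIFT_DECADES, _MAX_SHIFT_DECADES, 161)
    values = np.array([cost(la) for la in coarse])
    if not np.any(np.isfinite(values)):
        raise TTSError(
            f"no overlap achievable within ±{_MAX_SHIFT_DECADES:g} decades "
            f"between {fit_ref.temperature} °C and {fit_mov.temperature} °C")
    i = int(np.nanargmin(np.where(np.isfinite(values), values, np.nan)))
    lo = coarse[max(i - 1, 0)]
    hi = coarse[min(i + 1, coarse.size - 1)]
    res = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    la = float(res.x)
    if float(res.fun) > 0.5:
        # frequency windows may touch, but the moduli never line up: the
        # curves share no physical overlap at any admissible shift
        raise TTSError(
            f"no usable overlap between {fit_ref.temperature} °C and "
            f"{fit_mov.temperature} °C (best registration rms "
            f"{math.sqrt(res.fun):.2f} log10 units)")
    lb = 0.0
    if vertical:
        res2 = minimize(lambda x: cost(x[0], x[1]), x0=np.array([la, 0.0]),
                        method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-14})
        la, lb = float(res2.x[0]), float(res2.x[1])
    return la, lb


def estimate_shift_factors(fits: list[FitResult], t_ref: float | None = None,
                           vertical: bool = False) -> ShiftFactorSet:
    """Shift factors by sequential pairwise registration outward from t_ref.

    Default reference temperature: the sweep with most retained points.
    """
    if not fits:
        raise ValidationError("need at least one fitted sweep")
    fits = sorted(fits, key=lambda f: f.temperature)
    temps = [f.temperature for f in fits]
    if len(set(temps)) != len(temps):
        raise ValidationError("duplicate temperatures in the fit list")
    if t_ref is None:
        retained = [len(f.sweep) - len(f.flagged_indices) if f.sweep is not None
                    else 0 for f in fits]
        t_ref = fits[int(np.argmax(retained))].temperature
    if t_ref not in temps:
        raise ValidationError(f"reference temperature {t_ref} °C has no sweep")
    i_ref = temps.index(t_ref)

    shifts = {t_ref: (0.0, 0.0)}
    # upward in temperature
    for i in range(i_ref + 1, len(fits)):
        prev = fits[i - 1]
        ref_shift = shifts[prev.temperature][0]
        la, lb = _register_pair(prev, fits[i], ref_shift, vertical)
        shifts[fits[i].temperature] = (la, shifts[prev.temperature][1] + lb)
    # downward in temperature
    for i in range(i_ref - 1, -1, -1):
        nxt = fits[i + 1]
        ref_shift = shifts[nxt.temperature][0]
        la, lb = _register_pair(nxt, fits[i], ref_shift, vertical)
        shifts[fits[i].temperature] = (la, shifts[nxt.temperature][1] + lb)

    entries = [(t, shifts[t][0], shifts[t][1]) for t in temps]
    return ShiftFactorSet(reference_temperature=t_ref, entries=entries)


def build_master_curve(fits: list[FitResult], shifts: ShiftFactorSet) -> MasterCurve:
    """Apply shifts to the retained (unflagged) raw points, merge and sort.

    The discrepancy between overlapping shifted fitted curves of adjacent
    temperatures is reported as an rms log distance.
    """
    fits = sorted(fits, key=lambda f: f.temperature)
    rows = []
    for fit in fits:
        if fit.sweep is None:
            raise ValidationError("FitResult lacks its source sweep")
        try:
            la = shifts.log10_at(fit.temperature)
            lb = shifts.log10_bt(fit.temperature)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
        at = 10.0 ** la
        bt = 10.0 ** lb
        idx = fit.retained_indices()
        for i in idx:
            rows.append((fit.sweep.omega[i] * at,
                         fit.sweep.g_prime[i] * bt,
                         fit.sweep.g_double_prime[i] * bt,
                         fit.temperature))
    rows.sort(key=lambda r: r[0])
    # merge exactly coincident reduced frequencies to keep omega strictly increasing
    merged = []
    for r in rows:
        if merged and r[0] == merged[-1][0]:
            prev = merged[-1]
            merged[-1] = (prev[0], 0.5 * (prev[1] + r[1]),
                          0.5 * (prev[2] + r[2]), prev[3])
        else:
            merged.append(r)
    omega, gp, gpp, src = map(np.array, zip(*merged))

    # overlap discrepancy between adjacent shifted fitted curves
    sq_sum, n_sum = 0.0, 0
    for a, b in zip(fits[:-1], fits[1:]):
        la_a, la_b = shifts.log10_at(a.temperature), shifts.log10_at(b.temperature)
        lb_a, lb_b = shifts.log10_bt(a.temperature), shifts.log10_bt(b.temperature)
        lo = max(math.log10(a.omega_window[0]) + la_a,
                 math.log10(b.omega_window[0]) + la_b)
        hi = min(math.log10(a.omega_window[1]) + la_a,
                 math.log10(b.omega_window[1]) + la_b)
        if hi <= lo:
            continue
        grid = np.linspace(lo, hi, 40)
        ap, app = a._moduli(10.0 ** (grid - la_a))
        bp, bpp = b._moduli(10.0 ** (grid - la_b))
        d = np.concatenate([np.log10(ap) + lb_a - np.log10(bp) - lb_b,
                            np.log10(app) + lb_a - np.log10(bpp) - lb_b])
        sq_sum += float(d @ d)
        n_sum += d.size
    overlap_rms = math.sqrt(sq_sum / n_sum) if n_sum else 0.0

    return MasterCurve(
        reference_temperature=shifts.reference_temperature,
        omega=omega, g_prime=gp, g_double_prime=gpp,
        source_temperature_per_point=src,
        overlap_rms_log=overlap_rms,
    )
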
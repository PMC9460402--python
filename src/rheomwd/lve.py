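"""Linear viscoelastic region and denaturation-temperature detection.

The LVE region is the amplitude range over which the moduli are independent of
the applied stress or strain; it is found as the longest contiguous run of
amplitude-sweep points whose G′ all lie within a relative tolerance of the
run's median.  The denaturation temperature Td of a collagen gel is estimated
two ways from a temperature sweep: the temperature at which the complex
viscosity has dropped to a set fraction (default 50%) of its initial value,
and the temperature at which tanδ = G″/G′ peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import AmplitudeSweep, TemperatureSweep, ValidationError

__all__ = [
    "LVERegion",
    "NoLVERegionError",
    "TdEstimate",
    "DenaturationResult",
    "detect_lve_region",
    "detect_td_viscosity",
    "detect_td_tandelta",
    "denaturation_summary",
]


class NoLVERegionError(ValueError):
    """No contiguous run of >= 3 amplitude points is flat within tolerance."""


@dataclass
class LVERegion:
    temperature: float
    amplitude_lower: float
    amplitude_upper: float
    plateau_g_prime: float
    n_points_in_region: int


@dataclass
class TdEstimate:
    """A denaturation-temperature estimate; ``value`` is None when the
    signature was not found, with the reason in ``diagnostic``."""

    value: float | None
    diagnostic: str | None = None


@dataclass
class DenaturationResult:
    td_viscosity: TdEstimate
    td_tandelta: TdEstimate

    @property
    def method_agreement(self) -> float | None:
        """Absolute difference between the two estimators, °C, when both exist."""
        if self.td_viscosity.value is None or self.td_tandelta.value is None:
            return None
        return abs(self.td_viscosity.value - self.td_tandelta.value)


def detect_lve_region(sweep: AmplitudeSweep, rel_tol: float = 0.05) -> LVERegion:
    """Longest contiguous run where every G′ is within ±rel_tol of the run
    median; ties go to the lowest-amplitude run.  The plateau modulus is that
    median."""
    if not (0 < rel_tol < 1):
        raise ValidationError("rel_tol must lie in (0, 1)")
    gp = sweep.g_prime
    n = len(gp)
    best: tuple[int, int] | None = None  # (start, stop) inclusive
    for start in range(n - 2):
        for stop in range(start + 2, n):
            run = gp[start:stop + 1]
            med = float(np.median(run))
            if med <= 0:
                continue
            if np.all(np.abs(run - med) <= rel_tol * med):
                if best is None or (stop - start) > (best[1] - best[0]):
                    best = (start, stop)
            else:
                # extending this start further cannot shrink the violation if
                # the violating point stays in the run, but the median moves,
                # so keep scanning (exhaustive by design)
                continue
    if best is None:
        raise NoLVERegionError(
            f"no contiguous run of >= 3 points flat within ±{rel_tol:.0%}")
    start, stop = best
    run = gp[start:stop + 1]
    return LVERegion(
        temperature=sweep.temperature,
        amplitude_lower=float(sweep.amplitude[start]),
        amplitude_upper=float(sweep.amplitude[stop]),
        plateau_g_prime=float(np.median(run)),
        n_points_in_region=stop - start + 1,
    )


def detect_td_viscosity(sweep: TemperatureSweep,
                        drop_fraction: float = 0.5) -> TdEstimate:
    """Temperature at which viscosity first falls to ``drop_fraction`` of its
    initial value (mean of the first three points), by linear interpolation
    between the bracketing samples."""
    if not (0 < drop_fraction < 1):
        raise ValidationError("drop_fraction must lie in (0, 1)")
    temp = sweep.temperature
    eta = sweep.viscosity
    eta0 = float(np.mean(eta[:3]))
    threshold = drop_fraction * eta0
    below = np.flatnonzero(eta <= threshold)
    if below.size == 0:
        return TdEstimate(None, f"viscosity never fell to {drop_fraction:.0%} "
                                "of its initial value")
    i = int(below[0])
    if i == 0:
        return TdEstimate(float(temp[0]),
                          "threshold already crossed at the first point")
    t0, t1 = temp[i - 1], temp[i]
    e0, e1 = eta[i - 1], eta[i]
    frac = (e0 - threshold) / (e0 - e1)
    return TdEstimate(float(t0 + frac * (t1 - t0)), None)


def detect_td_tandelta(sweep: TemperatureSweep) -> TdEstimate:
    """Temperature of the tanδ maximum after 3-point moving-average smoothing,
    refined by parabolic interpolation over the three points around the
    discrete argmax.  A maximum on either boundary is rejected: an unbracketed
    peak cannot distinguish denaturation from drift."""
    if len(sweep) < 5:
        raise ValidationError("tan-delta peak detection needs >= 5 points")
    temp = sweep.temperature
    td = sweep.tan_delta
    smooth = td.copy()
    smooth[1:-1] = (td[:-2] + td[1:-1] + td[2:]) / 3.0
    i = int(np.argmax(smooth))
    if i == 0 or i == len(smooth) - 1:
        return TdEstimate(None, "peak not bracketed: tan-delta maximum at the "
                                "boundary of the sweep")
    y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-300:
        return TdEstimate(float(temp[i]), None)
    # parabola vertex on an (approximately) uniform local grid
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    h = (temp[i + 1] - temp[i - 1]) / 2.0
    return TdEstimate(float(temp[i] + delta * h), None)


def denaturation_summary(sweep: TemperatureSweep,
                         drop_fraction: float = 0.5) -> DenaturationResult:
    """Run both Td estimators; neither is privileged over the other."""
    result = DenaturationResult(
        td_viscosity=detect_td_viscosity(sweep, drop_fraction),
        td_tandelta=detect_td_tandelta(sweep),
    )
    t_lo, t_hi = float(sweep.temperature[0]), float(sweep.temperature[-1])
    for est in (result.td_viscosity, result.td_tandelta):
        if est.value is not None:
            assert t_lo <= est.value <= t_hi
    return result
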
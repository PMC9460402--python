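"""One-way ANOVA over molecular-weight populations.

Reproducibility of a rheology-derived Mw is assessed by a fixed-effects
one-way analysis of variance at the 95% confidence level: the null hypothesis
is that all population means (e.g. Mw at different test temperatures) are
equal.  Raw-data groups go through scipy's F test; a summary-statistics
variant reconstructs the same F from (n, mean, sd) so that published tables
can be analyzed without the raw replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import ValidationError

__all__ = ["AnovaResult", "one_way_anova", "anova_from_summaries"]

ALPHA = 0.05


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_summaries: list[tuple[str, int, float, float]]  # (label, n, mean, sd)
    degenerate: bool = False

    @property
    def decision(self) -> str:
        if self.p_value > ALPHA:
            return (f"fail to reject H0 (all means equal) at alpha={ALPHA}: "
                    f"p={self.p_value:.3g}")
        return (f"reject H0 (at least one mean differs) at alpha={ALPHA}: "
                f"p={self.p_value:.3g}")


def _normalize_groups(groups):
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(f"group_{i+1}", g) for i, g in enumerate(groups)]
    out = []
    for label, values in items:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValidationError(f"group '{label}' needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"group '{label}' contains non-finite values")
        out.append((str(label), arr))
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way F test on raw groups (dict label->values or list)."""
    items = _normalize_groups(groups)
    arrays = [a for _, a in items]
    n_total = sum(a.size for a in arrays)
    dfb = len(arrays) - 1
    dfw = n_total - len(arrays)
    summaries = [(label, int(a.size), float(a.mean()), float(a.std(ddof=1)))
                 for label, a in items]

    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    grand = sum(float(a.sum()) for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ssw <= 1e-300 * max(1.0, abs(grand)):
        # degenerate: no within-group variance
        if ssb <= 1e-300 * max(1.0, abs(grand)):
            return AnovaResult(0.0, 1.0, dfb, dfw, summaries, degenerate=True)
        return AnovaResult(math.inf, 0.0, dfb, dfw, summaries, degenerate=True)
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), dfb, dfw, summaries)


def anova_from_summaries(summaries) -> AnovaResult:
    """One-way F test reconstructed from per-group (n, mean, sd).

    Accepts (n, mean, sd) or (label, n, mean, sd) tuples.  Identical to
    :func:`one_way_anova` when the summaries come from the raw groups.
    """
    rows = []
    for i, row in enumerate(summaries):
        if len(row) == 4:
            label, n, mean, sd = row
        elif len(row) == 3:
            label, (n, mean, sd) = f"group_{i+1}", row
        else:
            raise ValidationError("summaries must be (n, mean, sd) or "
                                  "(label, n, mean, sd)")
        n = int(n)
        if n < 2:
            raise ValidationError(f"group '{label}' needs n >= 2")
        if sd < 0 or not all(map(math.isfinite, (mean, sd))):
            raise ValidationError(f"group '{label}' has invalid mean/sd")
        rows.append((str(label), n, float(mean), float(sd)))
    if len(rows) < 2:
        raise ValidationError("need at least 2 groups")

    n_total = sum(n for _, n, _, _ in rows)
    k = len(rows)
    dfb, dfw = k - 1, n_total - k
    grand = sum(n * m for _, n, m, _ in rows) / n_total
    ssb = sum(n * (m - grand) ** 2 for _, n, m, _ in rows)
    ssw = sum((n - 1) * sd ** 2 for _, n, _, sd in rows)
    if ssw <= 1e-300 * max(1.0, abs(grand)):
        if ssb <= 1e-300 * max(1.0, abs(grand)):
            return AnovaResult(0.0, 1.0, dfb, dfw, rows, degenerate=True)
        return AnovaResult(math.inf, 0.0, dfb, dfw, rows, degenerate=True)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw, rows)
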
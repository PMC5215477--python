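"""Dose-unit conversions and the tissue-chromium trend statistic.

Sodium dichromate dihydrate (SDD, Na2Cr2O7.2H2O) carries two chromium atoms
per formula unit, so a drinking-water concentration in mg/L SDD converts to
ppm Cr(VI) by the chromium mass fraction 2*M_Cr/M_SDD ~= 0.349.

Group comparisons of tissue chromium use Shirley's nonparametric step-down
trend test: a rank-based Williams-type comparison of each dose group against
control under a monotone alternative, with isotonic (pool-adjacent-
violators) smoothing of the treated-group mean ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["M_CR", "M_SDD", "CR_MASS_FRACTION", "sdd_to_cr6", "cr6_to_sdd",
           "ShirleyResult", "shirley_test"]

M_CR = 51.9961          # atomic mass of chromium, g/mol
M_SDD = 298.00          # molar mass of Na2Cr2O7.2H2O, g/mol
CR_MASS_FRACTION = 2.0 * M_CR / M_SDD   # 0.34897...


def sdd_to_cr6(sdd_mgL):
    """Convert mg/L sodium dichromate dihydrate to ppm Cr(VI).

    Linear and exactly invertible: cr6 = sdd * 2*M_Cr/M_SDD.
    """
    sdd = np.asarray(sdd_mgL, dtype=float)
    if np.any(sdd < 0):
        raise ValueError("SDD concentration must be nonnegative")
    out = sdd * CR_MASS_FRACTION
    return float(out) if out.ndim == 0 else out


def cr6_to_sdd(cr6_ppm):
    """Inverse of :func:`sdd_to_cr6`."""
    cr6 = np.asarray(cr6_ppm, dtype=float)
    if np.any(cr6 < 0):
        raise ValueError("Cr(VI) concentration must be nonnegative")
    out = cr6 / CR_MASS_FRACTION
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Shirley's test
# ---------------------------------------------------------------------------

# Williams' one-sided t-bar critical values at infinite degrees of freedom
# (the limiting values appropriate for rank statistics), indexed by the
# number of dose groups being amalgamated. Interpolated for intermediate k.
_TBAR = {
    0.05: {1: 1.645, 2: 1.716, 3: 1.739, 4: 1.750, 5: 1.756,
           6: 1.760, 7: 1.763, 8: 1.765, 9: 1.766, 10: 1.767},
    0.01: {1: 2.326, 2: 2.366, 3: 2.377, 4: 2.382, 5: 2.385,
           6: 2.386, 7: 2.387, 8: 2.388, 9: 2.389, 10: 2.390},
}


def _tbar_critical(k: int, alpha: float) -> float:
    if alpha not in _TBAR:
        raise ValueError(f"no critical-value table for alpha={alpha}")
    tab = _TBAR[alpha]
    if k in tab:
        return tab[k]
    kmax = max(tab)
    if k > kmax:
        return tab[kmax]
    lo = max(i for i in tab if i < k)
    hi = min(i for i in tab if i > k)
    w = (k - lo) / (hi - lo)
    return tab[lo] * (1 - w) + tab[hi] * w


def _pava_max(means: np.ndarray, weights: np.ndarray) -> float:
    """Isotonic-smoothed value of the last element:
    max over u of min over v>=u of the weighted mean of means[u:v+1]."""
    k = len(means)
    best = -np.inf
    for u in range(k):
        cw = np.cumsum(weights[u:])
        cm = np.cumsum(weights[u:] * means[u:]) / cw
        best = max(best, cm.min())
    return best


@dataclass
class ShirleyResult:
    """Per-dose outcome of the step-down Shirley trend test."""

    doses: np.ndarray           # dose labels, ascending, excluding control
    statistic: np.ndarray       # t-bar statistic per dose (NaN below stop)
    critical: np.ndarray        # critical value used per dose
    significant: np.ndarray     # boolean flags
    direction: str              # "increasing" or "decreasing"
    alpha: float

    def summary(self) -> str:
        lines = [f"Shirley step-down trend test ({self.direction}, alpha={self.alpha})",
                 f"{'dose':>10} {'t-bar':>8} {'crit':>6} {'signif':>7}"]
        for d, t, c, s in zip(self.doses, self.statistic, self.critical,
                              self.significant):
            ts = "" if np.isnan(t) else f"{t:.3f}"
            lines.append(f"{d:>10g} {ts:>8} {c:>6.3f} {str(bool(s)):>7}")
        return "\n".join(lines)


def shirley_test(groups, alpha: float = 0.05,
                 alternative: str = "greater") -> ShirleyResult:
    """Rank-based Williams-type step-down comparison of dose groups to control.

    Parameters
    ----------
    groups
        Mapping dose -> 1-D array of replicate values, or a sequence of
        (dose, values) pairs. Must include the control at the lowest dose
        (typically 0) and have >= 2 replicates per group.
    alpha
        One-sided significance level (0.05 or 0.01; tabulated values).
    alternative
        ``"greater"`` assumes responses increase with dose, ``"less"``
        the reverse.

    Notes
    -----
    At each step the highest remaining dose is tested: all remaining
    observations are (mid-)ranked jointly, treated-group mean ranks are
    smoothed by pool-adjacent-violators amalgamation, and the standardized
    contrast against the control mean rank (with tie-corrected rank
    variance) is compared to Williams' t-bar critical value. A
    non-significant dose stops the procedure; all lower doses are declared
    non-significant, making the flags downward-closed.
    """
    if isinstance(groups, dict):
        items = sorted(groups.items())
    else:
        items = sorted((float(d), np.asarray(v, float)) for d, v in groups)
    if len(items) < 2:
        raise ValueError("need a control and at least one dose group")
    doses = np.array([d for d, _ in items])
    data = [np.asarray(v, dtype=float) for _, v in items]
    for d, v in zip(doses, data):
        if len(v) < 2:
            raise ValueError(f"dose group {d} has < 2 replicates")
    if alternative == "less":
        data = [-v for v in data]
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")

    k_total = len(items) - 1
    stat = np.full(k_total, np.nan)
    crit = np.array([_tbar_critical(i + 1, alpha) for i in range(k_total)])
    sig = np.zeros(k_total, dtype=bool)

    for k in range(k_total, 0, -1):
        sub = data[: k + 1]                       # control + doses 1..k
        pooled = np.concatenate(sub)
        if np.all(pooled == pooled[0]):
            break                                 # all identical: nothing to flag
        ranks = rankdata(pooled)                  # midranks for ties
        n = np.array([len(v) for v in sub])
        idx = np.cumsum(n)
        mean_ranks = np.array([ranks[s:e].mean()
                               for s, e in zip(np.r_[0, idx[:-1]], idx)])
        N = len(pooled)
        # tie-corrected rank variance
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts ** 3 - counts).sum()
        v_rank = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
        smoothed = _pava_max(mean_ranks[1:], n[1:].astype(float))
        se = np.sqrt(v_rank * (1.0 / n[k] + 1.0 / n[0]))
        t = (smoothed - mean_ranks[0]) / se
        stat[k - 1] = t
        if t > _tbar_critical(k, alpha):
            sig[k - 1] = True
        else:
            break                                 # step-down stop

    return ShirleyResult(doses=doses[1:], statistic=stat, critical=crit,
                         significant=sig,
                         direction="increasing" if alternative == "greater"
                         else "decreasing", alpha=alpha)
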
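"""Multistage cancer modeling of tumor incidence and risk arithmetic.

The multistage model with background gamma and nonnegative stage
coefficients beta_i is

    P(d) = gamma + (1 - gamma) * (1 - exp(-sum_{i=1..degree} beta_i d^i))

fitted by binomial maximum likelihood. The BMD at 10% extra risk solves
[P(d) - P(0)] / [1 - P(0)] = 0.10, which for the multistage form reduces to
sum_i beta_i d^i = -ln(0.9) independently of gamma. The BMDL is the
one-sided 95% profile-likelihood lower bound under the beta_i >= 0
constraints (deviance cutoff 2.7055).

Downstream risk metrics follow the regulatory conventions: cancer slope
factor = BMR / BMDL, risk-specific dose = target risk / slope factor,
RfD = BMDL / composite uncertainty factor, and a drinking-water
concentration of dose * body weight / daily intake. Reports round to two
significant figures; the reported risk-specific dose is derived from the
*rounded* slope factor, matching how such chains are presented in
assessments.

Goodness of fit is the Pearson chi-square against observed proportions
with df = #groups - #parameters not estimated at a bound (the BMDS
convention); the AIC parameter count likewise drops boundary parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log10, floor

import numpy as np
from scipy import optimize, stats

from .io import IncidenceTable

logger = logging.getLogger("crvi_bmd")

__all__ = [
    "MultistageFit",
    "MultistageModel",
    "fit_multistage",
    "bmd_extra_risk",
    "bmdl_profile",
    "select_multistage",
    "allometric_hed",
    "RiskMetrics",
    "derive_risk_metrics",
    "round_sig",
]

_BOUND_TOL = 1e-8


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-layer rounding)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def _response(doses, gamma, betas):
    s = sum(b * doses ** (i + 1) for i, b in enumerate(betas))
    return gamma + (1.0 - gamma) * (1.0 - np.exp(-s))


def _binom_nll(theta, doses, n, k, degree):
    gamma, betas = theta[0], theta[1:]
    p = np.clip(_response(doses, gamma, betas), 1e-12, 1.0 - 1e-12)
    return -float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())


@dataclass
class MultistageFit:
    """Fitted multistage cancer model (results object)."""

    degree: int
    gamma: float
    betas: np.ndarray
    loglik: float
    aic: float
    gof_p: float
    n_free: int                     # parameters not at a bound
    converged: bool
    dose_metric: str = "ppm"
    doses: np.ndarray = field(default=None, repr=False)
    n_total: np.ndarray = field(default=None, repr=False)
    n_affected: np.ndarray = field(default=None, repr=False)
    flag: str = ""

    def predict(self, d) -> np.ndarray:
        return _response(np.asarray(d, dtype=float), self.gamma, self.betas)

    def extra_risk(self, d) -> np.ndarray:
        p0 = self.predict(0.0)
        return (self.predict(d) - p0) / (1.0 - p0)

    def bmd(self, bmr: float = 0.10) -> float:
        """Dose at ``bmr`` extra risk; closed form for degree 1."""
        return bmd_extra_risk(self, bmr)

    def bmdl(self, bmr: float = 0.10, confidence: float = 0.95) -> float:
        return bmdl_profile(self, bmr, confidence)

    def summary(self, bmr: float = 0.10) -> str:
        beta_s = ", ".join(f"beta{i+1}={b:.6g}" for i, b in enumerate(self.betas))
        return "\n".join([
            f"Multistage cancer model, degree {self.degree} ({self.dose_metric})",
            f"  gamma = {self.gamma:.6g}; {beta_s}",
            f"  loglik = {self.loglik:.4f}   AIC = {self.aic:.4f}   "
            f"GOF p = {self.gof_p:.4f}",
            f"  BMD{int(bmr*100)} = {self.bmd(bmr):.6g}   "
            f"BMDL{int(bmr*100)} = {self.bmdl(bmr):.6g}",
        ] + ([f"  flag: {self.flag}"] if self.flag else []))

    def plot(self, bmr: float = 0.10, ax=None):
        """Observed incidence proportions and the fitted response curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.n_affected / self.n_total
        ax.plot(self.doses, obs, "o", label="observed incidence")
        grid = np.linspace(0.0, self.doses.max(), 300)
        ax.plot(grid, self.predict(grid), "-",
                label=f"multistage degree {self.degree}")
        bmd = self.bmd(bmr)
        if np.isfinite(bmd):
            ax.axvline(bmd, ls="--", color="gray",
                       label=f"BMD{int(bmr*100)} = {bmd:.3g}")
        ax.set_xlabel(f"dose ({self.dose_metric})")
        ax.set_ylabel("tumor incidence")
        ax.legend()
        return ax


class MultistageModel:
    """Model object for multistage tumor dose-response.

    Parameters
    ----------
    incidence
        An :class:`~crvi_bmd.io.IncidenceTable` (control row first).
    degree
        Polynomial degree of the dose term (1-3 in practice).
    dose_metric
        Label carried through reporting (e.g. ``"ppm"`` or ``"mg/kg HED"``).
    """

    def __init__(self, incidence: IncidenceTable, degree: int = 1,
                 dose_metric: str = "ppm"):
        if degree < 1:
            raise ValueError("degree must be >= 1")
        if len(incidence.table) < degree + 2:
            logger.warning("multistage degree %d with only %d dose groups",
                           degree, len(incidence.table))
        self.incidence = incidence
        self.degree = degree
        self.dose_metric = dose_metric

    def fit(self, max_iter: int = 250) -> MultistageFit:
        doses = self.incidence.doses
        n = self.incidence.n_total
        k = self.incidence.n_affected
        degree = self.degree
        scale = max(doses.max(), 1.0)
        bounds = [(0.0, 1.0 - 1e-9)] + [(0.0, None)] * degree

        p0 = max(k[0] / n[0], 1e-3)
        rate = max((k[-1] / n[-1]) - p0, 1e-3)
        starts = []
        for g0 in (p0, 1e-3, 0.05):
            for b0 in (rate / scale, 1e-2 / scale, 1e-4 / scale):
                starts.append([g0] + [b0 / scale ** i for i in range(degree)])
        best = None
        for x0 in starts:
            res = optimize.minimize(_binom_nll, x0, args=(doses, n, k, degree),
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": max_iter})
            if best is None or res.fun < best.fun:
                best = res
        # polish with Nelder-Mead (projected onto bounds)
        def nll_proj(theta):
            t = np.array(theta, dtype=float)
            t[0] = np.clip(t[0], 0.0, 1.0 - 1e-9)
            t[1:] = np.maximum(t[1:], 0.0)
            return _binom_nll(t, doses, n, k, degree)
        res2 = optimize.minimize(nll_proj, best.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-12,
                                          "fatol": 1e-12})
        theta = np.array(res2.x if res2.fun < best.fun else best.x, dtype=float)
        theta[0] = np.clip(theta[0], 0.0, 1.0 - 1e-9)
        theta[1:] = np.maximum(theta[1:], 0.0)
        ll = -_binom_nll(theta, doses, n, k, degree)

        gamma, betas = float(theta[0]), theta[1:]
        at_bound = [gamma <= _BOUND_TOL] + [b <= _BOUND_TOL for b in betas]
        n_free = int(sum(not a for a in at_bound))
        aic = 2.0 * n_free - 2.0 * ll
        gof_p = _pearson_gof(doses, n, k, _response(doses, gamma, betas), n_free)
        converged = bool(best.success or res2.success)
        if not converged:
            logger.warning("multistage degree %d did not converge", degree)
        return MultistageFit(degree=degree, gamma=gamma, betas=betas,
                             loglik=ll, aic=aic, gof_p=gof_p, n_free=n_free,
                             converged=converged, dose_metric=self.dose_metric,
                             doses=doses, n_total=n, n_affected=k,
                             flag="" if converged else "non-convergence")


def fit_multistage(incidence: IncidenceTable, degree: int,
                   dose_metric: str = "ppm", max_iter: int = 250) -> MultistageFit:
    """Functional wrapper over :class:`MultistageModel`."""
    return MultistageModel(incidence, degree, dose_metric).fit(max_iter)


def _pearson_gof(doses, n, k, p_hat, n_free) -> float:
    obs = k / n
    var = np.clip(p_hat * (1.0 - p_hat), 1e-12, None)
    chi2 = float((n * (obs - p_hat) ** 2 / var).sum())
    df = len(doses) - n_free
    if df <= 0:
        return np.nan
    return float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# BMD / BMDL
# ---------------------------------------------------------------------------

def bmd_extra_risk(fit: MultistageFit, bmr: float = 0.10) -> float:
    """Dose with extra risk ``bmr``; gamma cancels for the multistage form."""
    target = -np.log1p(-bmr)
    betas = fit.betas
    if np.all(betas <= 0):
        return np.nan
    if fit.degree == 1 or np.all(betas[1:] <= 0):
        # effectively degree 1: closed form
        b1 = betas[0]
        if b1 > 0:
            return float(target / b1)
    poly = lambda d: sum(b * d ** (i + 1) for i, b in enumerate(betas)) - target
    hi = 1.0
    while poly(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return np.nan
    return float(optimize.brentq(poly, 0.0, hi, xtol=1e-14, rtol=1e-14))


def _profile_ll_at_bmd(fit: MultistageFit, b: float, bmr: float) -> float:
    """Max binomial loglik subject to BMD = b (beta_i >= 0, gamma in [0,1))."""
    doses, n, k = fit.doses, fit.n_total, fit.n_affected
    degree = fit.degree
    target = -np.log1p(-bmr)

    def nll(free):
        gamma = np.clip(free[0], 0.0, 1.0 - 1e-9)
        rest = np.maximum(free[1:], 0.0)          # beta_2..beta_degree
        beta1 = (target - sum(bb * b ** (i + 2) for i, bb in enumerate(rest))) / b
        if beta1 < 0:
            return 1e12
        betas = np.concatenate([[beta1], rest])
        p = np.clip(_response(doses, gamma, betas), 1e-12, 1 - 1e-12)
        return -float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    starts = [np.concatenate([[fit.gamma], np.maximum(fit.betas[1:], 0.0)])]
    starts.append(np.concatenate([[max(fit.gamma, 0.01)],
                                  np.zeros(degree - 1)]))
    if degree > 1:
        starts.append(np.concatenate([[fit.gamma],
                                      np.full(degree - 1, target / b ** 2 / degree)]))
    best = np.inf
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-12,
                                         "fatol": 1e-12})
        best = min(best, res.fun)
    return -best


def bmdl_profile(fit: MultistageFit, bmr: float = 0.10,
                 confidence: float = 0.95) -> float:
    """One-sided profile-likelihood lower bound on the BMD."""
    bmd = fit.bmd(bmr)
    if not np.isfinite(bmd) or bmd <= 0:
        return np.nan
    cutoff = stats.chi2.ppf(2.0 * confidence - 1.0, 1)

    def excess(b):
        return 2.0 * (fit.loglik - _profile_ll_at_bmd(fit, b, bmr)) - cutoff

    lo = bmd
    for _ in range(80):
        lo /= 1.4
        if excess(lo) > 0:
            break
    else:
        logger.warning("BMDL profile failed to bracket below BMD=%g", bmd)
        return np.nan
    return float(optimize.brentq(excess, lo, bmd, xtol=1e-9 * bmd, rtol=1e-9))


def select_multistage(fits: list[MultistageFit],
                      gof_min: float = 0.1) -> MultistageFit:
    """Lowest-AIC fit among those with acceptable goodness of fit.

    Fits with GOF p > ``gof_min`` compete on AIC (ties to the lowest
    degree). If none is acceptable the best-AIC fit is returned flagged
    ``"no acceptable fit"``.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged multistage fit")
    ok = [f for f in converged if np.isfinite(f.gof_p) and f.gof_p > gof_min]
    pool = ok or converged
    best = min(pool, key=lambda f: (round(f.aic, 9), f.degree))
    if not ok:
        best.flag = "no acceptable fit"
    logger.info("multistage selection: degree %d (AIC %.3f, GOF p %.3f)%s",
                best.degree, best.aic, best.gof_p,
                " [no acceptable fit]" if not ok else "")
    return best


# ---------------------------------------------------------------------------
# risk arithmetic
# ---------------------------------------------------------------------------

def allometric_hed(dose_mg_kg, bw_animal_kg: float, bw_human_kg: float = 80.0):
    """Human equivalent of an animal daily dose by body-weight-3/4 scaling.

    HED = dose * (BW_animal / BW_human)^(1/4); linear in dose.
    """
    if bw_animal_kg <= 0 or bw_human_kg <= 0:
        raise ValueError("body weights must be positive")
    return np.asarray(dose_mg_kg, dtype=float) * (bw_animal_kg / bw_human_kg) ** 0.25


@dataclass
class RiskMetrics:
    """Risk-assessment chain from a BMDL point of departure.

    Internal fields keep full precision; :meth:`report` applies the
    2-significant-figure presentation rounding (with the risk-specific
    dose re-derived from the rounded slope factor, as assessments print it).
    """

    bmdl: float
    bmr: float
    risk_level: float
    uf: float
    body_weight_kg: float
    intake_L: float
    slope_factor: float
    risk_specific_dose: float
    rfd: float
    water_linear: float      # from the risk-specific dose (linear extrapolation)
    water_nonlinear: float   # from the RfD (threshold/nonlinear approach)

    def report(self, sig: int = 2) -> dict:
        sf = round_sig(self.slope_factor, sig)
        rsd = round_sig(self.risk_level / sf, sig)
        rfd = round_sig(self.rfd, sig)
        per_L = self.body_weight_kg / self.intake_L
        return {
            "slope_factor": sf,
            "risk_specific_dose": rsd,
            "rfd": rfd,
            "water_linear": round_sig(rsd * per_L, sig),
            "water_nonlinear": round_sig(rfd * per_L, sig),
        }

    def summary(self) -> str:
        r = self.report()
        return "\n".join([
            f"Point of departure (BMDL{int(self.bmr*100)}): {self.bmdl:.6g}",
            f"  slope factor       : {self.slope_factor:.6g}  (reported {r['slope_factor']:g})",
            f"  {self.risk_level:g} risk-specific dose: {self.risk_specific_dose:.6g}"
            f"  (reported {r['risk_specific_dose']:g})",
            f"  RfD (UF {self.uf:g})     : {self.rfd:.6g}  (reported {r['rfd']:g})",
            f"  water, linear      : {self.water_linear:.6g}  (reported {r['water_linear']:g})",
            f"  water, nonlinear   : {self.water_nonlinear:.6g}  (reported {r['water_nonlinear']:g})",
        ])


def derive_risk_metrics(bmdl: float, bmr: float = 0.10, uf: float = 30.0,
                        risk_level: float = 1e-6, body_weight_kg: float = 80.0,
                        intake_L: float = 2.5) -> RiskMetrics:
    """Slope factor, risk-specific dose, RfD and drinking-water equivalents.

    slope_factor = bmr/bmdl; risk_specific_dose = risk_level/slope_factor;
    rfd = bmdl/uf; water concentration = dose * body_weight / intake (so
    rsd * slope_factor == risk_level and rfd * uf == bmdl exactly at full
    precision).
    """
    if bmdl <= 0 or not np.isfinite(bmdl):
        raise ValueError("bmdl must be positive and finite")
    sf = bmr / bmdl
    rsd = risk_level / sf
    rfd = bmdl / uf
    per_L = body_weight_kg / intake_L
    return RiskMetrics(bmdl=bmdl, bmr=bmr, risk_level=risk_level, uf=uf,
                       body_weight_kg=body_weight_kg, intake_L=intake_L,
                       slope_factor=sf, risk_specific_dose=rsd, rfd=rfd,
                       water_linear=rsd * per_L, water_nonlinear=rfd * per_L)
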
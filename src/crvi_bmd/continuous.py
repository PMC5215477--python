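"""Continuous benchmark-dose modeling of expression dose-response.

Four mean models are fitted to log2 expression by maximum likelihood under
Normal(mu(d), sigma^2) with a shared (constant) variance:

* hill:   mu(d) = intercept + v * d^n / (k^n + d^n)
* power:  mu(d) = gamma + beta * d^delta
* linear: mu(d) = beta0 + beta1 * d
* poly2:  mu(d) = beta0 + beta1 * d + beta2 * d^2

The benchmark dose (BMD) is the smallest positive dose shifting the mean by
``bmr_factor`` (default 1.349) residual standard deviations from the
control mean, direction-agnostic. The BMDL is the one-sided 95%
profile-likelihood lower bound (deviance cutoff chi2_1(0.90) = 2.7055),
computed by reparameterising each model so the BMD is an explicit
parameter. Model selection and the retention filters follow the
BMDExpress conventions: Hill is excluded when its half-maximal dose k is
at or below one third of the lowest tested dose, quadratic must beat
linear in a nested likelihood-ratio test at p < 0.05, the lowest AIC wins
(ties to the simpler model), and winning fits are retained only when
BMD/BMDL <= 20, lowest_dose/3 <= BMD <= highest_dose and the
lack-of-fit p (likelihood ratio against the saturated per-dose-means
model) exceeds 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import DoseDesign, ExpressionMatrix, RunConfig

logger = logging.getLogger("crvi_bmd")

__all__ = [
    "MODELS",
    "ContinuousFit",
    "ContinuousDoseResponse",
    "fit_continuous_model",
    "compute_bmd",
    "compute_bmdl",
    "select_best_model",
    "apply_retention_filters",
    "run_continuous_screen",
]

MODELS = ("linear", "power", "poly2", "hill")
_SHAPE_BOUNDS = (0.1, 18.0)      # hill n and power delta
_COMPLEXITY = {"linear": 0, "power": 1, "poly2": 2, "hill": 3}
_N_MEAN_PARAMS = {"linear": 2, "power": 3, "poly2": 3, "hill": 4}


def _loglik_from_sse(sse: float, n: int) -> float:
    """Profile log-likelihood at the ML variance sigma^2 = SSE/n."""
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


@dataclass
class ContinuousFit:
    """Fitted continuous dose-response model (results object)."""

    model: str
    params: dict
    sigma: float
    loglik: float
    aic: float
    gof_p: float
    converged: bool
    doses: np.ndarray = field(repr=False)
    responses: np.ndarray = field(repr=False)
    bmr_factor: float = 1.349
    retained: bool | None = None
    removal_reasons: list = field(default_factory=list)

    # -- mean function -----------------------------------------------------
    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p = self.params
        if self.model == "linear":
            return p["beta0"] + p["beta1"] * d
        if self.model == "poly2":
            return p["beta0"] + p["beta1"] * d + p["beta2"] * d ** 2
        if self.model == "power":
            return p["gamma"] + p["beta"] * d ** p["delta"]
        if self.model == "hill":
            with np.errstate(invalid="ignore"):
                f = np.where(d > 0, d ** p["n"] / (p["k"] ** p["n"] + d ** p["n"]), 0.0)
            return p["intercept"] + p["v"] * f
        raise ValueError(self.model)

    @property
    def direction(self) -> float:
        """Sign of the fitted trend at the top dose (+1 up, -1 down)."""
        delta = self.predict(self.doses.max()) - self.predict(0.0)
        return 1.0 if delta >= 0 else -1.0

    # -- benchmark dose ----------------------------------------------------
    def bmd(self, bmr_factor: float | None = None) -> float:
        """Smallest positive dose with |mu(d) - mu(0)| = bmr_factor * sigma.

        Closed form where available, otherwise bracketed root-finding on
        [0, 10 * max dose]. NaN when no solution exists in range.
        """
        bf = self.bmr_factor if bmr_factor is None else bmr_factor
        if not self.converged or self.sigma <= 0:
            return np.nan
        shift = bf * self.sigma
        p = self.params
        if self.model == "linear":
            return shift / abs(p["beta1"]) if p["beta1"] != 0 else np.nan
        if self.model == "power":
            if p["beta"] == 0:
                return np.nan
            return (shift / abs(p["beta"])) ** (1.0 / p["delta"])
        if self.model == "hill":
            v = abs(p["v"])
            if v <= shift:
                return np.nan  # shift beyond the asymptotic effect
            return p["k"] * (shift / (v - shift)) ** (1.0 / p["n"])
        if self.model == "poly2":
            roots = []
            for s in (+shift, -shift):
                for r in np.roots([p["beta2"], p["beta1"], -s]):
                    if abs(r.imag) < 1e-12 and r.real > 0:
                        roots.append(r.real)
            if not roots:
                return np.nan
            b = min(roots)
            return b if b <= 10.0 * self.doses.max() else np.nan
        raise ValueError(self.model)

    def bmdl(self, confidence: float = 0.95,
             bmr_factor: float | None = None) -> float:
        """One-sided profile-likelihood lower confidence limit on the BMD."""
        bf = self.bmr_factor if bmr_factor is None else bmr_factor
        return _profile_bmdl(self, confidence, bf)

    def summary(self) -> str:
        par = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        lines = [
            f"Continuous dose-response fit: {self.model}",
            f"  parameters : {par}",
            f"  sigma      : {self.sigma:.6g}",
            f"  loglik     : {self.loglik:.4f}   AIC: {self.aic:.4f}",
            f"  lack-of-fit p: {self.gof_p:.4f}",
            f"  BMD (BMR {self.bmr_factor} sd): {self.bmd():.6g}",
        ]
        if self.retained is not None:
            lines.append(f"  retained   : {self.retained} "
                         f"{self.removal_reasons if not self.retained else ''}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed responses, fitted curve, and the BMD marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.doses, self.responses, "o", alpha=0.6, label="observed")
        grid = np.linspace(0.0, self.doses.max(), 300)
        ax.plot(grid, self.predict(grid), "-", label=f"{self.model} fit")
        bmd = self.bmd()
        if np.isfinite(bmd):
            ax.axvline(bmd, ls="--", color="gray",
                       label=f"BMD = {bmd:.3g}")
        ax.set_xlabel("dose (mg/L SDD)")
        ax.set_ylabel("log2 expression")
        ax.legend()
        return ax


class ContinuousDoseResponse:
    """Model object: continuous dose-response of one endpoint.

    Parameters
    ----------
    doses, responses
        Paired arrays; responses are log2 expression (or any continuous
        endpoint with approximately constant variance).
    model
        One of ``linear``, ``power``, ``poly2``, ``hill``.
    """

    def __init__(self, doses, responses, model: str = "linear"):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must be the same length")
        if len(np.unique(self.doses)) < 3:
            raise ValueError("need >= 3 distinct doses")
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        self.model = model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose",
                       response_col: str = "response",
                       model: str = "linear") -> "ContinuousDoseResponse":
        return cls(df[dose_col], df[response_col], model)

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 250) -> ContinuousFit:
        d, y = self.doses, self.responses
        n = len(y)
        converged = True
        if self.model == "linear":
            coef = np.polyfit(d, y, 1)
            params = {"beta0": coef[1], "beta1": coef[0]}
            sse = float(((np.polyval(coef, d) - y) ** 2).sum())
        elif self.model == "poly2":
            coef = np.polyfit(d, y, 2)
            params = {"beta0": coef[2], "beta1": coef[1], "beta2": coef[0]}
            sse = float(((np.polyval(coef, d) - y) ** 2).sum())
        elif self.model == "power":
            params, sse, converged = _fit_power(d, y, max_iter)
        else:
            params, sse, converged = _fit_hill(d, y, max_iter)
        sigma = float(np.sqrt(sse / n))
        ll = _loglik_from_sse(sse, n)
        k_mean = _N_MEAN_PARAMS[self.model]
        aic = 2.0 * (k_mean + 1) - 2.0 * ll          # +1 for the variance
        gof = _lack_of_fit_p(d, y, ll, k_mean)
        return ContinuousFit(model=self.model, params=params, sigma=sigma,
                             loglik=ll, aic=aic, gof_p=gof,
                             converged=converged, doses=d, responses=y)


def fit_continuous_model(doses, responses, model: str,
                         max_iter: int = 250) -> ContinuousFit:
    """Functional wrapper over :class:`ContinuousDoseResponse`."""
    return ContinuousDoseResponse(doses, responses, model).fit(max_iter)


# ---------------------------------------------------------------------------
# conditionally-linear fitters (power, hill)
# ---------------------------------------------------------------------------

def _ols_sse(x_cols: list[np.ndarray], y: np.ndarray):
    X = np.column_stack(x_cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _fit_power(d, y, max_iter):
    """Profile (gamma, beta) out by OLS; optimize delta on its bounds."""
    lo, hi = _SHAPE_BOUNDS

    def sse_of(delta):
        _, sse = _ols_sse([np.ones_like(d), d ** delta], y)
        return sse

    grid = np.geomspace(lo, hi, 40)
    sses = [sse_of(g) for g in grid]
    i = int(np.argmin(sses))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse_of, bounds=(a, b), method="bounded",
                                   options={"maxiter": max_iter})
    delta = float(np.clip(res.x, lo, hi))
    coef, sse = _ols_sse([np.ones_like(d), d ** delta], y)
    return ({"gamma": float(coef[0]), "beta": float(coef[1]), "delta": delta},
            sse, bool(res.success))


def _hill_frac(d, k, n):
    with np.errstate(invalid="ignore", over="ignore"):
        return np.where(d > 0, d ** n / (k ** n + d ** n), 0.0)


def _fit_hill(d, y, max_iter):
    """Profile (intercept, v) by OLS; 5 deterministic starts over (k, n)."""
    lo_n, hi_n = _SHAPE_BOUNDS
    pos = np.unique(d[d > 0])
    dmin, dmax = pos.min(), pos.max()

    def sse_of(theta):
        log_k, n = theta
        n = np.clip(n, lo_n, hi_n)
        k = np.exp(np.clip(log_k, np.log(dmin) - 7, np.log(dmax) + 5))
        _, sse = _ols_sse([np.ones_like(d), _hill_frac(d, k, n)], y)
        return sse

    starts = [(np.log(dmin), 1.0), (np.log(np.median(pos)), 1.0),
              (np.log(np.median(pos)), 3.0), (np.log(dmax / 2.0), 6.0),
              (np.log(dmax), 0.5)]
    best, best_sse, ok = None, np.inf, False
    for s in starts:
        res = optimize.minimize(sse_of, s, method="Nelder-Mead",
                                options={"maxiter": max_iter, "xatol": 1e-8,
                                         "fatol": 1e-12})
        if res.fun < best_sse:
            best, best_sse, ok = res.x, res.fun, bool(res.success)
    log_k, n = best
    n = float(np.clip(n, lo_n, hi_n))
    k = float(np.exp(np.clip(log_k, np.log(dmin) - 7, np.log(dmax) + 5)))
    coef, sse = _ols_sse([np.ones_like(d), _hill_frac(d, k, n)], y)
    return ({"intercept": float(coef[0]), "v": float(coef[1]), "k": k, "n": n},
            sse, ok)


def _lack_of_fit_p(d, y, ll_model, k_mean) -> float:
    """LRT of the model against the saturated per-dose-means model."""
    groups = {dd: y[d == dd] for dd in np.unique(d)}
    sse_sat = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    ll_sat = _loglik_from_sse(sse_sat, len(y))
    df = len(groups) - k_mean
    if df <= 0:
        return 1.0
    dev = max(2.0 * (ll_sat - ll_model), 0.0)
    return float(stats.chi2.sf(dev, df))


# ---------------------------------------------------------------------------
# BMD / BMDL
# ---------------------------------------------------------------------------

def compute_bmd(fit: ContinuousFit, bmr_factor: float = 1.349) -> float:
    """Benchmark dose of a fitted model (see :meth:`ContinuousFit.bmd`)."""
    return fit.bmd(bmr_factor)


def compute_bmd_rootfind(fit: ContinuousFit, bmr_factor: float = 1.349) -> float:
    """BMD by bracketed root-finding (cross-check for the closed forms)."""
    if not fit.converged or fit.sigma <= 0:
        return np.nan
    shift = bmr_factor * fit.sigma
    mu0 = fit.predict(0.0)

    def g(dd):
        return abs(fit.predict(dd) - mu0) - shift

    hi = 10.0 * fit.doses.max()
    grid = np.linspace(0.0, hi, 4096)
    vals = np.array([g(x) for x in grid])
    idx = np.nonzero(vals >= 0)[0]
    if len(idx) == 0 or idx[0] == 0:
        return np.nan
    return float(optimize.brentq(g, grid[idx[0] - 1], grid[idx[0]],
                                 xtol=1e-12, rtol=1e-14))


def _constrained_nll(fit: ContinuousFit, b: float, bf: float):
    """Return nll(free_params) for the model constrained to BMD = b."""
    d, y = fit.doses, fit.responses
    n = len(y)
    s = fit.direction
    model = fit.model
    lo_n, hi_n = _SHAPE_BOUNDS

    def nll(theta):
        log_sigma = theta[-1]
        sigma = np.exp(np.clip(log_sigma, -30, 30))
        shift = s * bf * sigma
        if model == "linear":
            beta0 = theta[0]
            mu = beta0 + (shift / b) * d
        elif model == "power":
            gamma, delta = theta[0], np.clip(theta[1], lo_n, hi_n)
            mu = gamma + (shift / b ** delta) * d ** delta
        elif model == "poly2":
            beta0, beta2 = theta[0], theta[1]
            beta1 = (shift - beta2 * b * b) / b
            mu = beta0 + beta1 * d + beta2 * d ** 2
        else:  # hill
            c, log_k, nn = theta[0], theta[1], np.clip(theta[2], lo_n, hi_n)
            k = np.exp(np.clip(log_k, -30, 30))
            fb = b ** nn / (k ** nn + b ** nn)
            v = shift / fb
            mu = c + v * _hill_frac(d, k, nn)
        sse = float(((y - mu) ** 2).sum())
        return 0.5 * n * np.log(2.0 * np.pi * sigma ** 2) + sse / (2.0 * sigma ** 2)

    return nll


def _constrained_start(fit: ContinuousFit):
    p, s = fit.params, max(fit.sigma, 1e-6)
    if fit.model == "linear":
        return [p["beta0"], np.log(s)]
    if fit.model == "power":
        return [p["gamma"], p["delta"], np.log(s)]
    if fit.model == "poly2":
        return [p["beta0"], p["beta2"], np.log(s)]
    return [p["intercept"], np.log(p["k"]), p["n"], np.log(s)]


def _profile_loglik_at(fit: ContinuousFit, b: float, bf: float) -> float:
    nll = _constrained_nll(fit, b, bf)
    x0 = np.asarray(_constrained_start(fit), dtype=float)
    best = np.inf
    for scale in (1.0, 1.1):
        res = optimize.minimize(nll, x0 * scale, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-9,
                                         "fatol": 1e-10})
        best = min(best, res.fun)
    return -best


def _profile_bmdl(fit: ContinuousFit, confidence: float, bf: float) -> float:
    bmd = fit.bmd(bf)
    if not np.isfinite(bmd) or bmd <= 0:
        return np.nan
    cutoff = stats.chi2.ppf(2.0 * confidence - 1.0, 1)

    def excess(b):
        return 2.0 * (fit.loglik - _profile_loglik_at(fit, b, bf)) - cutoff

    hi = bmd
    lo = bmd
    for _ in range(60):
        lo /= 1.4
        if excess(lo) > 0:
            break
    else:
        return np.nan  # profile never crossed the cutoff: flat likelihood
    try:
        return float(optimize.brentq(excess, lo, hi, xtol=1e-10 * bmd,
                                     rtol=1e-8))
    except ValueError:
        return np.nan


def compute_bmdl(fit: ContinuousFit, confidence: float = 0.95,
                 bmr_factor: float = 1.349) -> float:
    """One-sided profile-likelihood lower bound on the BMD."""
    return _profile_bmdl(fit, confidence, bmr_factor)


# ---------------------------------------------------------------------------
# model selection and retention
# ---------------------------------------------------------------------------

def select_best_model(fits: list[ContinuousFit], lowest_dose: float,
                      lrt_alpha: float = 0.05) -> ContinuousFit | None:
    """BMDExpress-style winner among per-probe fits.

    Hill is ineligible when its k is at or below lowest_dose/3; poly2 is
    eligible over linear only when the nested LRT rejects at ``lrt_alpha``;
    among eligible models the lowest AIC wins, AIC ties broken by
    simplicity (linear < power < poly2 < hill). Returns None when no model
    is eligible.
    """
    by_name = {f.model: f for f in fits if f.converged}
    eligible = dict(by_name)
    hill = eligible.get("hill")
    if hill is not None and hill.params["k"] <= lowest_dose / 3.0:
        del eligible["hill"]
    if "poly2" in eligible and "linear" in by_name:
        dev = max(2.0 * (by_name["poly2"].loglik - by_name["linear"].loglik), 0.0)
        if stats.chi2.sf(dev, 1) >= lrt_alpha:
            del eligible["poly2"]
    if not eligible:
        return None
    return min(eligible.values(),
               key=lambda f: (round(f.aic, 9), _COMPLEXITY[f.model]))


def apply_retention_filters(fit: ContinuousFit, lowest_dose: float,
                            highest_dose: float, bmd: float | None = None,
                            bmdl: float | None = None,
                            ratio_max: float = 20.0,
                            gof_min: float = 0.1) -> tuple[bool, list[str]]:
    """Retention verdict for a selected fit; all rules are evaluated.

    Removal reasons: ``no_bmd`` (undefined BMD), ``ratio`` (undefined BMDL
    or BMD/BMDL > 20), ``bmd_below_range`` (< lowest_dose/3),
    ``bmd_above_range`` (> highest dose) and ``gof`` (lack-of-fit
    p <= 0.1). The verdict is independent of evaluation order.
    """
    bmd = fit.bmd() if bmd is None else bmd
    bmdl = fit.bmdl() if bmdl is None else bmdl
    reasons = []
    if not np.isfinite(bmd):
        reasons.append("no_bmd")
    else:
        if not np.isfinite(bmdl) or bmd / bmdl > ratio_max:
            reasons.append("ratio")
        if bmd < lowest_dose / 3.0:
            reasons.append("bmd_below_range")
        if bmd > highest_dose:
            reasons.append("bmd_above_range")
    if not (fit.gof_p > gof_min):
        reasons.append("gof")
    retained = not reasons
    fit.retained = retained
    fit.removal_reasons = reasons
    return retained, reasons


def run_continuous_screen(matrix: ExpressionMatrix, design: DoseDesign,
                          pdeg_probes, config: RunConfig | None = None
                          ) -> pd.DataFrame:
    """Model every pDEG probe against dose and apply the retention rules.

    Responses are log2 intensities; the dose metric is mg/L SDD. Per-probe
    failures are logged and recorded, never fatal to the batch. Returns one
    row per probe: winning model, parameters, BMD, BMDL, lack-of-fit p and
    the retention verdict with removal reasons.
    """
    cfg = config or RunConfig()
    design.check_matches(matrix)
    doses_by_sample = design.dose_of()
    samples = list(matrix.sample_ids)
    d = doses_by_sample.reindex(samples).to_numpy()
    pos = np.unique(d[d > 0])
    lowest, highest = float(pos.min()), float(pos.max())
    log2 = matrix.log2()

    rows = []
    for probe in pdeg_probes:
        if probe not in matrix.data.index:
            logger.warning("screen: probe %r not in matrix, skipped", probe)
            continue
        y = log2.loc[probe].to_numpy()
        fits = []
        for model in MODELS:
            try:
                fits.append(fit_continuous_model(d, y, model,
                                                 cfg.max_iterations))
            except Exception as exc:  # noqa: BLE001 - batch robustness
                logger.warning("screen: %s fit failed for %r: %s",
                               model, probe, exc)
        best = select_best_model(fits, lowest)
        if best is None:
            rows.append({"probe_id": probe, "model": None, "retained": False,
                         "reasons": ["no_eligible_model"]})
            continue
        bmd = best.bmd(cfg.bmr_factor)
        bmdl = best.bmdl(cfg.confidence, cfg.bmr_factor)
        retained, reasons = apply_retention_filters(
            best, lowest, highest, bmd=bmd, bmdl=bmdl)
        rows.append({"probe_id": probe, "model": best.model,
                     "params": best.params, "sigma": best.sigma,
                     "loglik": best.loglik, "aic": best.aic,
                     "gof_p": best.gof_p, "bmd": bmd, "bmdl": bmdl,
                     "retained": retained, "reasons": reasons})
    out = pd.DataFrame(rows)
    n_ret = int(out["retained"].sum()) if len(out) else 0
    logger.info("continuous screen: %d probes modeled, %d retained",
                len(out), n_ret)
    return out
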
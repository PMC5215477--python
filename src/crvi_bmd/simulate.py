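"""Study-shaped synthetic data with known ground truth.

The generators emulate the statistical structure of a 90-day Cr(VI)
drinking-water study: 6 dose groups (0, 0.3, 4, 14, 60, 170, 520 mg/L SDD
is the full grid; rats omit 14) with 3 biological replicates, log-normal
microarray noise, a small planted fraction of dose-responsive probes
following Hill/power/linear/quadratic curves, tissue chromium with a
hockey-stick (breakpoint) dose dependence censored at the 0.02 mg/kg
detection limit, and binomial tumor incidence from a multistage model.

Noise is Gaussian on the log2 scale (constant CV on the linear scale),
matching the constant-variance assumption of the downstream benchmark-dose
models. All generators are fully seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DoseDesign, ExpressionMatrix, IncidenceTable

__all__ = [
    "PAPER_SDD_GRID",
    "default_design",
    "SimTruth",
    "simulate_expression",
    "simulate_tissue_burden",
    "simulate_tumor_incidence",
]

PAPER_SDD_GRID = (0.0, 0.3, 4.0, 14.0, 60.0, 170.0, 520.0)
DETECTION_LIMIT = 0.02  # mg Cr/kg tissue

_CURVES = ("hill", "power", "linear", "poly2")


def default_design(n_reps: int = 3, doses=PAPER_SDD_GRID[:3] + PAPER_SDD_GRID[4:],
                   species: str = "rat", timepoint: str = "day91") -> DoseDesign:
    """The study layout: 6 dose groups x 3 replicates (rats skip 14 mg/L)."""
    from .dosimetry import sdd_to_cr6
    rows = []
    for d in doses:
        for r in range(n_reps):
            rows.append({"sample_id": f"{species}_{timepoint}_d{d:g}_r{r+1}",
                         "sdd_mgL": d, "cr6_ppm": sdd_to_cr6(d),
                         "timepoint": timepoint, "species": species})
    return DoseDesign(pd.DataFrame(rows))


@dataclass
class SimTruth:
    """Ground truth for one simulated expression matrix."""

    planted: pd.DataFrame   # probe_id, model, params (dict), true_bmd
    sigma: float            # log2-scale noise SD
    seed: int
    bmr_factor: float = 1.349

    def responsive_probes(self) -> list[str]:
        return list(self.planted.loc[self.planted["model"] != "null", "probe_id"])


def _curve(model: str, params: dict, d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if model == "hill":
        return params["v"] * d ** params["n"] / (params["k"] ** params["n"]
                                                 + d ** params["n"])
    if model == "power":
        return params["beta"] * d ** params["delta"]
    if model == "linear":
        return params["beta1"] * d
    if model == "poly2":
        return params["beta1"] * d + params["beta2"] * d ** 2
    if model == "null":
        return np.zeros_like(d)
    raise ValueError(f"unknown curve family {model!r}")


def _true_bmd(model: str, params: dict, sigma: float, bmr_factor: float,
              dmax: float) -> float:
    """Smallest positive dose where |curve(d)| reaches bmr_factor * sigma."""
    if model == "null" or sigma <= 0:
        return np.nan
    shift = bmr_factor * sigma
    grid = np.linspace(0.0, 10.0 * dmax, 20001)
    excess = np.abs(_curve(model, params, grid)) - shift
    hit = np.nonzero(excess >= 0)[0]
    if len(hit) == 0 or hit[0] == 0:
        return np.nan
    # linear refinement between bracketing grid points
    i = hit[0]
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = excess[i - 1], excess[i]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def _draw_params(model: str, rng: np.random.Generator, dmax: float,
                 amplitude: float) -> dict:
    """Curve parameters scaled so the top-dose effect is ~amplitude log2 units."""
    sign = rng.choice([-1.0, 1.0])
    a = sign * amplitude
    if model == "hill":
        k = rng.uniform(0.05, 0.5) * dmax
        n = rng.uniform(1.0, 3.0)
        sat = dmax ** n / (k ** n + dmax ** n)
        return {"v": a / sat, "k": k, "n": n}
    if model == "power":
        delta = rng.uniform(0.5, 1.5)
        return {"beta": a / dmax ** delta, "delta": delta}
    if model == "linear":
        return {"beta1": a / dmax}
    if model == "poly2":
        w = rng.uniform(0.3, 0.7)
        return {"beta1": a * w / dmax, "beta2": a * (1 - w) / dmax ** 2}
    raise ValueError(model)


def simulate_expression(design: DoseDesign, n_probes: int = 2000,
                        frac_responsive: float = 0.0,
                        curve_family_weights: dict | None = None,
                        sigma: float = 0.25, seed: int = 0,
                        amplitude: tuple[float, float] = (1.0, 2.0),
                        baseline_range: tuple[float, float] = (6.0, 12.0),
                        bmr_factor: float = 1.349,
                        ) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a probe x sample intensity matrix with planted responders.

    log2 intensity = per-probe baseline + curve(dose) + N(0, sigma); the
    matrix is returned on the linear scale. ``amplitude`` bounds the
    uniform draw of the top-dose effect size in log2 units (the study
    itself showed essentially no oral-mucosa responders, so defaults are
    chosen for test power, not biological fidelity).
    """
    if design.table.empty:
        raise ValueError("empty design")
    if not (0.0 <= frac_responsive <= 1.0):
        raise ValueError("frac_responsive must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    weights = curve_family_weights or {m: 1.0 for m in _CURVES}
    fams = [m for m in _CURVES if weights.get(m, 0.0) > 0]
    w = np.array([weights[m] for m in fams], dtype=float)
    w /= w.sum()

    rng = np.random.default_rng(seed)
    doses = design.dose_of().to_numpy()
    samples = list(design.table["sample_id"])
    dmax = doses.max()
    n_resp = int(round(frac_responsive * n_probes))
    probe_ids = [f"probe_{i:05d}" for i in range(n_probes)]

    baselines = rng.uniform(*baseline_range, size=n_probes)
    log2 = baselines[:, None] + rng.normal(0.0, sigma, size=(n_probes, len(samples)))

    truth_rows = []
    responsive = rng.choice(n_probes, size=n_resp, replace=False)
    models = rng.choice(fams, size=n_resp, p=w)
    for idx, model in zip(responsive, models):
        params = _draw_params(model, rng, dmax, rng.uniform(*amplitude))
        log2[idx] += _curve(model, params, doses)
        truth_rows.append({"probe_id": probe_ids[idx], "model": model,
                           "params": params,
                           "true_bmd": _true_bmd(model, params, sigma,
                                                 bmr_factor, dmax)})
    planted = set(responsive)
    for i in range(n_probes):
        if i not in planted:
            truth_rows.append({"probe_id": probe_ids[i], "model": "null",
                               "params": None, "true_bmd": np.nan})
    truth = pd.DataFrame(truth_rows).set_index("probe_id").loc[probe_ids].reset_index()

    matrix = ExpressionMatrix(pd.DataFrame(2.0 ** log2, index=probe_ids,
                                           columns=samples))
    return matrix, SimTruth(planted=truth, sigma=sigma, seed=seed,
                            bmr_factor=bmr_factor)


def simulate_tissue_burden(cr6_ppm, breakpoint: float, slopes=(0.0, 0.15),
                           noise_sd: float = 0.5, n_reps: int = 5,
                           seed: int = 0, intercept: float = 0.1,
                           detection_limit: float = DETECTION_LIMIT
                           ) -> pd.DataFrame:
    """Tissue chromium replicates with a hockey-stick dose dependence.

    mean(dose) = intercept + b1*dose + b2*max(0, dose - breakpoint), with
    Gaussian noise. Values below the ICP-MS detection limit are reported AT
    the limit with ``censored=True`` (report-at-limit convention).
    """
    doses = np.asarray(cr6_ppm, dtype=float)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (doses.min() <= breakpoint <= doses.max()):
        raise ValueError("breakpoint must lie within the dose range")
    b1, b2 = slopes
    if not (np.isfinite(b1) and np.isfinite(b2)):
        raise ValueError("slopes must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mean = intercept + b1 * d + b2 * max(0.0, d - breakpoint)
        vals = mean + rng.normal(0.0, noise_sd, size=n_reps)
        for v in vals:
            censored = v < detection_limit
            rows.append({"cr6_ppm": d,
                         "tissue_cr_mg_kg": detection_limit if censored else v,
                         "censored": censored})
    return pd.DataFrame(rows)


def simulate_tumor_incidence(doses, gamma: float, betas, n_per_group: int = 50,
                             seed: int = 0) -> IncidenceTable:
    """Binomial tumor incidence from the multistage dose-response.

    P(d) = gamma + (1 - gamma) * (1 - exp(-sum_i beta_i d^i)).
    """
    doses = np.asarray(doses, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    if (betas < 0).any():
        raise ValueError("stage coefficients must be nonnegative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    s = sum(b * doses ** (i + 1) for i, b in enumerate(betas))
    p = gamma + (1.0 - gamma) * (1.0 - np.exp(-s))
    affected = rng.binomial(n_per_group, p)
    return IncidenceTable(pd.DataFrame({"dose": doses,
                                        "n_total": n_per_group,
                                        "n_affected": affected}))
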
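"""Segmented (bilinear) regression of DEG counts against tissue chromium.

The mean is the hockey-stick

    E[y] = beta0 + beta1 * x + beta2 * max(0, x - psi)

with Gaussian error; psi is the breakpoint dose (BPD). Estimation follows
the iterative-linearization scheme of segmented regression: at each step a
working linear model with the gap covariate U = (x - psi)_+ and the
indicator derivative V = -1{x > psi} is refitted and psi updated by
psi <- psi + gamma_hat / beta2_hat until the update is negligible. The
standard error of psi comes from the delta method (se(gamma)/|beta2| at
convergence) and the one-sided 95% lower confidence limit (BPDL) is
psi - 1.645 * se — an approximation, flagged as such. A deterministic
grid search over candidate breakpoints backs the iteration up when it
diverges or oscillates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("crvi_bmd")

__all__ = ["BreakpointFit", "BilinearModel", "fit_bilinear",
           "assemble_concordance_table"]

_Z_95 = 1.6448536269514722  # one-sided 95% normal quantile


def _working_fit(x, y, psi, with_gap_derivative=True):
    u = np.maximum(x - psi, 0.0)
    cols = [np.ones_like(x), x, u]
    if with_gap_derivative:
        cols.append(-(x > psi).astype(float))
    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    n, p = X.shape
    cov = None
    if n > p and rank == p:
        sigma2 = sse / (n - p)
        cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, sse, cov


@dataclass
class BreakpointFit:
    """Fitted bilinear model (results object)."""

    beta0: float
    beta1: float
    beta2: float
    psi: float
    psi_se: float
    bpdl: float
    sse: float
    converged: bool
    n_iter: int
    diagnostic: str = ""

    @property
    def bpd(self) -> float:
        return self.psi

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta0 + self.beta1 * x + self.beta2 * np.maximum(x - self.psi, 0.0)

    def summary(self) -> str:
        return "\n".join([
            "Bilinear breakpoint fit",
            f"  beta0 = {self.beta0:.6g}  beta1 = {self.beta1:.6g}  "
            f"beta2 (slope change) = {self.beta2:.6g}",
            f"  BPD (psi) = {self.psi:.6g}  se = {self.psi_se:.6g}",
            f"  BPDL (one-sided 95%, delta method) = {self.bpdl:.6g}",
            f"  converged = {self.converged} after {self.n_iter} iterations"
            + (f"  [{self.diagnostic}]" if self.diagnostic else ""),
        ])

    def plot(self, x=None, y=None, ax=None):
        """Hockey-stick fit with the breakpoint and its lower limit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if x is not None and y is not None:
            ax.plot(x, y, "o", alpha=0.6, label="observed")
            grid = np.linspace(min(x), max(x), 300)
        else:
            grid = np.linspace(0.0, 2.0 * self.psi, 300)
        ax.plot(grid, self.predict(grid), "-", label="bilinear fit")
        ax.axvline(self.psi, ls="--", color="gray",
                   label=f"BPD = {self.psi:.3g}")
        if np.isfinite(self.bpdl):
            ax.axvline(self.bpdl, ls=":", color="gray",
                       label=f"BPDL = {self.bpdl:.3g}")
        ax.set_xlabel("tissue Cr (mg/kg)")
        ax.set_ylabel("DEGs per animal")
        ax.legend()
        return ax


class BilinearModel:
    """Model object: hockey-stick regression of y on x.

    Needs >= 6 points with at least two distinct x values on each side of
    any admissible breakpoint.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must be the same length")
        if len(x) < 6:
            raise ValueError("need >= 6 points for a bilinear fit")
        if len(np.unique(x)) < 4:
            raise ValueError("need >= 4 distinct x values")
        order = np.argsort(x, kind="stable")
        self.x, self.y = x[order], y[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_col: str = "tissue_cr_mg_kg",
                       y_col: str = "n_degs") -> "BilinearModel":
        return cls(df[x_col], df[y_col])

    # ------------------------------------------------------------------
    def _candidates(self, n_grid: int = 200) -> np.ndarray:
        ux = np.unique(self.x)
        lo, hi = ux[1], ux[-2]          # >= 2 distinct x on each side
        if lo >= hi:
            return np.array([(ux[0] + ux[-1]) / 2.0])
        return np.linspace(lo, hi, n_grid)

    def _grid_psi(self) -> float:
        best_psi, best_sse = None, np.inf
        for psi in self._candidates():
            _, sse, _ = _working_fit(self.x, self.y, psi,
                                     with_gap_derivative=False)
            if sse < best_sse - 1e-15:
                best_psi, best_sse = psi, sse
        return float(best_psi)

    def fit(self, psi0: float | None = None, max_iter: int = 100,
            tol: float = 1e-8) -> BreakpointFit:
        x, y = self.x, self.y
        rng_x = float(x.max() - x.min())
        ux = np.unique(x)
        psi = float(psi0) if psi0 is not None else self._grid_psi()
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            psi_clipped = float(np.clip(psi, ux[1] - 1e-12, ux[-2] + 1e-12))
            coef, _, _ = _working_fit(x, y, psi_clipped)
            beta2, gamma = coef[2], coef[3]
            if abs(beta2) < 1e-300:
                break
            step = gamma / beta2
            psi = psi_clipped + step
            if abs(step) < tol * max(rng_x, 1e-300):
                converged = True
                break
        if not converged or not (ux[0] < psi < ux[-1]):
            # fall back on the deterministic grid optimum
            psi = self._grid_psi()
            diagnostic = "iteration diverged; grid-search fallback"
        else:
            diagnostic = ""

        psi = float(np.clip(psi, ux[1] - 1e-12, ux[-2] + 1e-12))
        coef, sse, cov = _working_fit(x, y, psi)
        beta0, beta1, beta2, gamma = coef
        if cov is not None and abs(beta2) > 1e-12:
            psi_se = float(np.sqrt(max(cov[3, 3], 0.0)) / abs(beta2))
        else:
            psi_se = np.nan
        fit_converged = converged or diagnostic != ""
        if abs(beta2) > 1e-12 and np.isfinite(psi_se):
            ci_half = _Z_95 * psi_se
            # slope change detectable only if its two-sided 95% CI excludes 0
            if not (abs(beta2) > 1.959963984540054 * np.sqrt(max(cov[2, 2], 0.0))):
                diagnostic = (diagnostic + "; " if diagnostic else "") + \
                    "slope change not distinguishable from zero; psi unreliable"
                fit_converged = False
        else:
            ci_half = np.nan
            diagnostic = (diagnostic + "; " if diagnostic else "") + \
                "no detectable slope change"
            fit_converged = False
        bpdl = psi - ci_half if np.isfinite(ci_half) else np.nan
        if diagnostic:
            logger.info("bilinear fit: %s", diagnostic)
        return BreakpointFit(beta0=float(beta0), beta1=float(beta1),
                             beta2=float(beta2), psi=psi, psi_se=psi_se,
                             bpdl=bpdl, sse=sse, converged=fit_converged,
                             n_iter=n_iter, diagnostic=diagnostic)


def fit_bilinear(x, y, **kwargs) -> BreakpointFit:
    """Functional wrapper over :class:`BilinearModel`."""
    return BilinearModel(x, y).fit(**kwargs)


def assemble_concordance_table(per_animal_counts: dict, tissue_burden: dict
                               ) -> pd.DataFrame:
    """Pool (tissue Cr, per-animal DEG count) pairs across tissues/species.

    Parameters
    ----------
    per_animal_counts
        Mapping of a (tissue, species) label to a DataFrame with columns
        ``sdd_mgL`` (or ``cr6_ppm``) and ``n_degs``, one row per animal.
    tissue_burden
        Mapping of the same labels to DataFrames with the dose column and
        ``tissue_cr_mg_kg`` replicate measurements.

    Each animal is paired with its dose group's MEAN tissue chromium
    (transcriptomes and tissue chemistry came from different animals).
    Groups lacking a tissue measurement are dropped with a warning.
    Provenance columns (tissue/species label, dose) are retained.
    """
    frames = []
    for label, counts in per_animal_counts.items():
        if label not in tissue_burden:
            logger.warning("concordance: no tissue burden for %r, dropped", label)
            continue
        burden = tissue_burden[label]
        dose_col = "sdd_mgL" if "sdd_mgL" in counts.columns else "cr6_ppm"
        if dose_col not in burden.columns:
            raise ValueError(f"burden table for {label!r} lacks {dose_col!r}")
        mean_cr = burden.groupby(dose_col)["tissue_cr_mg_kg"].mean()
        sub = counts.copy()
        sub["tissue_cr_mg_kg"] = sub[dose_col].map(mean_cr)
        missing = sub["tissue_cr_mg_kg"].isna()
        if missing.any():
            dropped = sorted(sub.loc[missing, dose_col].unique())
            logger.warning("concordance: %r groups without tissue Cr dropped: %s",
                           label, dropped)
            sub = sub[~missing]
        sub["source"] = str(label)
        frames.append(sub[["source", dose_col, "tissue_cr_mg_kg", "n_degs"]
                          ].rename(columns={dose_col: "dose"}))
    if not frames:
        raise ValueError("no usable (counts, burden) pairs")
    return pd.concat(frames, ignore_index=True)
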
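"""Microarray preprocessing and differential-expression screening.

The screening chain mirrors a standard single-channel Agilent workflow:
quantile normalization, removal of probes at or below array background,
per-dose-group ANOVA of exposed vs. control on log2 intensities with
fold-change gates on the linear scale, and Benjamini-Hochberg FDR within
each comparison.

Two gate sets are used throughout the package:

* DEG: |FC| >= 2, ANOVA p < 0.05 and BH q < 0.05;
* pDEG ("potential" DEG): |FC| >= 1.5 and p < 0.05 with no q gate —
  the relaxed screen feeding the continuous benchmark-dose stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DoseDesign, ExpressionMatrix

logger = logging.getLogger("crvi_bmd")

__all__ = [
    "quantile_normalize",
    "filter_low_signal",
    "DEGRecord",
    "identify_degs",
    "deg_summary",
    "per_animal_deg_counts",
    "pca_qc",
]

_VAR_FLOOR = 1e-12  # pooled-variance floor for zero-variance probes


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common distribution of row-rank means.

    Each column is replaced by the mean sorted column evaluated at its
    (mid-)ranks, so all samples share identical sorted values while each
    column's internal ordering is preserved. Idempotent on tie-free data.
    """
    df = matrix.data
    if df.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input")
        return matrix
    values = df.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j])  # midranks average tied quantiles
        out[:, j] = np.interp(ranks, grid, ref)
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns),
                            matrix.gene_symbols)


def filter_low_signal(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes below their array's median signal in most samples.

    A probe is retained iff its intensity is >= the per-array median in a
    strict majority (> 50%) of samples; a probe below the median in exactly
    half the samples is therefore kept.
    """
    values = matrix.data.to_numpy()
    col_median = np.median(values, axis=0)
    n_below = (values < col_median).sum(axis=1)
    keep = n_below <= values.shape[1] / 2.0  # removed only on a strict majority
    removed = matrix.data.index[~keep]
    logger.info("background filter: removed %d of %d probes",
                len(removed), len(keep))
    if not keep.any():
        logger.warning("background filter removed every probe")
    gs = matrix.gene_symbols
    return ExpressionMatrix(matrix.data.loc[keep],
                            gs.loc[matrix.data.index[keep]] if gs is not None else None)


@dataclass
class DEGRecord:
    """One probe x exposed-group differential-expression verdict."""

    probe_id: str
    sdd_mgL: float
    fc_linear: float   # mean(exposed)/mean(control), linear scale
    fc_signed: float   # fc_linear if >= 1 else -1/fc_linear
    p_value: float
    q_value: float
    is_deg: bool       # |fc_signed| >= 2 and p < .05 and q < .05
    is_pdeg: bool      # |fc_signed| >= 1.5 and p < .05


def _signed(fc: np.ndarray) -> np.ndarray:
    return np.where(fc >= 1.0, fc, -1.0 / fc)


def identify_degs(matrix: ExpressionMatrix, design: DoseDesign,
                  deg_fc: float = 2.0, pdeg_fc: float = 1.5,
                  p_threshold: float = 0.05, q_threshold: float = 0.05,
                  omnibus: bool = False) -> pd.DataFrame:
    """Screen every probe in every exposed group against the control.

    Statistics are computed on log2 intensities (one-way ANOVA of exposed
    vs. control, which for two groups equals the pooled-variance t-test via
    F = t^2); fold changes are ratios of linear-scale group means. BH FDR
    is applied within each exposed-vs-control comparison across all probes.
    With ``omnibus=True`` an all-groups one-way ANOVA p replaces the
    pairwise p (shared across groups for each probe).

    Returns a DataFrame with one row per (probe, exposed group).
    """
    design.check_matches(matrix)
    control = design.control_samples
    if len(control) < 2:
        raise ValueError("control group needs >= 2 replicates")
    linear = matrix.data
    log2 = matrix.log2()
    ctrl_lin_mean = linear[control].mean(axis=1)
    ctrl_log = log2[control].to_numpy()

    if omnibus:
        groups_log = [log2[design.samples_at(d)].to_numpy()
                      for d in design.doses]
        p_omni = _rowwise_anova(groups_log)

    frames = []
    for dose in design.doses:
        if dose == 0.0:
            continue
        samples = design.samples_at(dose)
        if len(samples) < 2:
            raise ValueError(f"dose group {dose} has < 2 replicates")
        fc = (linear[samples].mean(axis=1) / ctrl_lin_mean).to_numpy()
        p = p_omni if omnibus else _rowwise_anova([log2[samples].to_numpy(),
                                                   ctrl_log])
        q = multipletests(p, method="fdr_bh")[1]
        fcs = _signed(fc)
        frames.append(pd.DataFrame({
            "probe_id": matrix.probe_ids,
            "sdd_mgL": dose,
            "fc_linear": fc,
            "fc_signed": fcs,
            "p_value": p,
            "q_value": q,
            "is_deg": (np.abs(fcs) >= deg_fc) & (p < p_threshold)
                      & (q < q_threshold),
            "is_pdeg": (np.abs(fcs) >= pdeg_fc) & (p < p_threshold),
        }))
    out = pd.concat(frames, ignore_index=True)
    logger.info("DEG screen: %d DEG and %d pDEG (probe x group) records",
                int(out["is_deg"].sum()), int(out["is_pdeg"].sum()))
    return out


def _rowwise_anova(groups: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way ANOVA p per probe (rows) across sample groups."""
    ns = np.array([g.shape[1] for g in groups])
    N = ns.sum()
    k = len(groups)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = (means * ns).sum(axis=1) / N
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1)
                    for g, m in zip(groups, means.T))
    df_b, df_w = k - 1, N - k
    ms_within = np.maximum(ss_within / df_w, _VAR_FLOOR)
    n_floored = int((ss_within / df_w < _VAR_FLOOR).sum())
    if n_floored:
        logger.info("ANOVA: variance floor applied to %d probes", n_floored)
    f = (ss_between / df_b) / ms_within
    return stats.f.sf(f, df_b, df_w)


def deg_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-dose-group DEG/pDEG counts (probes significant in that group)."""
    return (records.groupby("sdd_mgL")[["is_deg", "is_pdeg"]].sum()
            .astype(int).rename(columns={"is_deg": "n_deg", "is_pdeg": "n_pdeg"}))


def per_animal_deg_counts(records: pd.DataFrame, matrix: ExpressionMatrix,
                          design: DoseDesign, fc_threshold: float = 2.0
                          ) -> pd.DataFrame:
    """Count, per exposed animal, the group DEGs it individually recapitulates.

    For each exposed sample, among the probes flagged ``is_deg`` in that
    sample's dose group, count those whose per-animal fold change (animal's
    linear intensity over the control-group mean) passes |FC| >= 2. The
    per-animal count can differ from the group-level DEG total.
    """
    design.check_matches(matrix)
    ctrl_mean = matrix.data[design.control_samples].mean(axis=1)
    rows = []
    for dose in design.doses:
        if dose == 0.0:
            continue
        deg_probes = records.loc[(records["sdd_mgL"] == dose)
                                 & records["is_deg"], "probe_id"]
        for sample in design.samples_at(dose):
            if len(deg_probes):
                fc = matrix.data.loc[deg_probes, sample] / ctrl_mean.loc[deg_probes]
                n = int((np.abs(_signed(fc.to_numpy())) >= fc_threshold).sum())
            else:
                n = 0
            rows.append({"sample_id": sample, "sdd_mgL": dose, "n_degs": n})
    return pd.DataFrame(rows)


def pca_qc(matrix: ExpressionMatrix, design: DoseDesign | None = None,
           k: float = 3.0) -> tuple[pd.DataFrame, pd.Series]:
    """Sample-space PCA on centered log2 data with distance-based flags.

    Returns the first three component scores per sample and a boolean
    outlier flag: a sample is flagged when its Euclidean distance from its
    dose-group centroid (or the global centroid without a design) in PC1-3
    exceeds ``k`` times the median such distance. Flags are advisory only;
    nothing is dropped downstream.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA QC needs >= 3 samples")
    log2 = matrix.log2().to_numpy()
    centered = log2 - log2.mean(axis=1, keepdims=True)
    # samples as observations
    x = centered.T - centered.T.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    n_pc = min(3, vt.shape[0])
    scores = pd.DataFrame(x @ vt[:n_pc].T, index=matrix.sample_ids,
                          columns=[f"PC{i+1}" for i in range(n_pc)])
    if design is not None:
        design.check_matches(matrix)
        group = design.dose_of().reindex(scores.index)
        centroids = scores.groupby(group).transform("mean")
    else:
        centroids = pd.DataFrame(np.tile(scores.mean(axis=0), (len(scores), 1)),
                                 index=scores.index, columns=scores.columns)
    dist = np.sqrt(((scores - centroids) ** 2).sum(axis=1))
    med = float(np.median(dist))
    flags = dist > k * med if med > 0 else pd.Series(False, index=dist.index)
    if flags.any():
        logger.info("PCA QC flagged samples (reported, never dropped): %s",
                    list(flags.index[flags]))
    return scores, flags
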
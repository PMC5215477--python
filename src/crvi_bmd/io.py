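"""Tabular I/O and validated domain containers.

All readers accept tab- or comma-delimited UTF-8 text (``.csv`` implies comma,
anything else tab; gzip is handled transparently by pandas). Validation is
total: malformed inputs raise :class:`ValidationError` or
:class:`ParseError` with a diagnostic naming the offending row/column —
never a silent pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crvi_bmd")

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "DoseDesign",
    "IncidenceTable",
    "GeneSetCollection",
    "RunConfig",
    "read_expression_matrix",
    "read_design",
    "read_incidence",
    "read_gmt",
    "ntp_female_rat_oral_tumors",
]

_NTP_TABLE = Path(__file__).parent / "data" / "ntp_female_rat_oral_tumors.tsv"


class ValidationError(ValueError):
    """A structurally well-formed table violated a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed into the expected tabular structure."""


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample intensity grid on the linear fluorescence scale.

    Parameters
    ----------
    data
        DataFrame indexed by probe ID with one column per sample ID.
        All values must be finite and strictly positive.
    gene_symbols
        Optional probe -> gene symbol mapping (user-supplied annotation).
    """

    data: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe IDs: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("intensity matrix contains non-numeric values")
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"intensity must be finite and > 0; offending value "
                f"{values[i, j]!r} at probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log2(self) -> pd.DataFrame:
        """Log2-scale view of the intensities (statistics happen here)."""
        return np.log2(self.data)

    def subset_probes(self, probes) -> "ExpressionMatrix":
        gs = self.gene_symbols.reindex(probes) if self.gene_symbols is not None else None
        return ExpressionMatrix(self.data.loc[list(probes)], gs)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep=_sep_for(path), index_label="probe_id")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probe x sample intensity table (first column = probe IDs)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
    m = ExpressionMatrix(df.astype(float))
    logger.info("read expression matrix %s: %d probes x %d samples",
                path, *m.shape)
    return m


# ---------------------------------------------------------------------------
# DoseDesign
# ---------------------------------------------------------------------------

_DESIGN_COLS = ("sample_id", "sdd_mgL", "cr6_ppm", "timepoint", "species")


@dataclass
class DoseDesign:
    """Sample-to-dose-group mapping for a drinking-water study arm.

    One row per sample with the administered dose in mg/L sodium dichromate
    dihydrate (SDD), the equivalent ppm Cr(VI), the necropsy timepoint
    (``day8``/``day91``) and species. Exactly one group must be the
    zero-dose control and every non-control group needs >= 2 replicates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in design")
        t["sdd_mgL"] = t["sdd_mgL"].astype(float)
        t = t.sort_values(["sdd_mgL", "sample_id"], kind="stable").reset_index(drop=True)
        n_by_dose = t.groupby("sdd_mgL").size()
        if 0.0 not in n_by_dose.index:
            raise ValidationError("design has no zero-dose control group")
        singles = n_by_dose[n_by_dose < 2]
        if len(singles):
            raise ValidationError(
                f"dose groups with < 2 replicates: {list(singles.index)}"
            )
        self.table = t

    @property
    def doses(self) -> np.ndarray:
        """Sorted unique SDD doses (mg/L), control first."""
        return np.unique(self.table["sdd_mgL"].to_numpy())

    @property
    def control_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["sdd_mgL"] == 0.0, "sample_id"])

    def samples_at(self, sdd_mgL: float) -> list[str]:
        t = self.table
        return list(t.loc[t["sdd_mgL"] == float(sdd_mgL), "sample_id"])

    def dose_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["sdd_mgL"]

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        design_ids = set(self.table["sample_id"])
        matrix_ids = set(matrix.sample_ids)
        if design_ids != matrix_ids:
            raise ValidationError(
                f"design/matrix sample mismatch: only in design "
                f"{sorted(design_ids - matrix_ids)[:5]}, only in matrix "
                f"{sorted(matrix_ids - design_ids)[:5]}"
            )

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep=_sep_for(path), index=False)


def read_design(path: str | Path) -> DoseDesign:
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    d = DoseDesign(df)
    logger.info("read design %s: %d samples, %d dose groups",
                path, len(d.table), len(d.doses))
    return d


# ---------------------------------------------------------------------------
# IncidenceTable
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTable:
    """Dose / n_total / n_affected rows for dichotomous tumor modeling."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for c in ("dose", "n_total", "n_affected"):
            if c not in t.columns:
                raise ValidationError(f"incidence table missing column {c!r}")
        t["dose"] = t["dose"].astype(float)
        t["n_total"] = t["n_total"].astype(int)
        t["n_affected"] = t["n_affected"].astype(int)
        if (t["dose"] < 0).any():
            raise ValidationError("negative dose in incidence table")
        if (t["n_total"] <= 0).any():
            raise ValidationError("n_total must be positive")
        if ((t["n_affected"] < 0) | (t["n_affected"] > t["n_total"])).any():
            bad = t[(t["n_affected"] < 0) | (t["n_affected"] > t["n_total"])]
            raise ValidationError(
                f"n_affected out of [0, n_total] at dose {bad['dose'].iloc[0]}"
            )
        if not t["dose"].is_monotonic_increasing:
            logger.warning("incidence doses not sorted; re-sorting canonically")
            t = t.sort_values("dose", kind="stable").reset_index(drop=True)
        if t["dose"].duplicated().any():
            raise ValidationError("duplicate dose rows in incidence table")
        if t["dose"].iloc[0] != 0.0:
            raise ValidationError("first incidence row must be the control (dose 0)")
        self.table = t.reset_index(drop=True)

    @property
    def doses(self) -> np.ndarray:
        return self.table["dose"].to_numpy()

    @property
    def n_total(self) -> np.ndarray:
        return self.table["n_total"].to_numpy()

    @property
    def n_affected(self) -> np.ndarray:
        return self.table["n_affected"].to_numpy()

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep=_sep_for(path), index=False)


def read_incidence(path: str | Path) -> IncidenceTable:
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    return IncidenceTable(df)


def ntp_female_rat_oral_tumors() -> IncidenceTable:
    """Oral-cavity tumor incidence of female F344 rats (NTP 2008 bioassay).

    Squamous-cell papilloma or carcinoma of the oral mucosa, 50 animals per
    group, doses as ppm Cr(VI) in drinking water (NTP TR-546).
    """
    return read_incidence(_NTP_TABLE)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT contents)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member..."""
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields (need >= 3)"
                )
            name = parts[0]
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            desc[name] = parts[1]
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    logger.info("read GMT %s: %d sets", path, len(sets))
    return GeneSetCollection(sets, desc)


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds and risk-assessment constants.

    Defaults are the study's reported settings: DEG gates |FC| >= 2,
    p < 0.05, q < 0.05 (pDEG relaxes to |FC| >= 1.5 with no q gate); a
    continuous benchmark response of 1.349 residual SDs; 10% extra risk for
    tumors; 95% one-sided confidence limits; a composite uncertainty factor
    of 30; and an 80 kg adult drinking 2.5 L/day.
    """

    deg_fc: float = 2.0
    pdeg_fc: float = 1.5
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    bmr_factor: float = 1.349
    extra_risk_bmr: float = 0.10
    confidence: float = 0.95
    max_iterations: int = 250
    uncertainty_factor: float = 30.0
    body_weight_kg: float = 80.0
    water_intake_L: float = 2.5
    animal_body_weight_kg: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("seed", "animal_body_weight_kg"):
                continue
            if v is None or v <= 0:
                raise ValidationError(f"config {f.name} must be positive, got {v!r}")
        if not (0.0 < self.confidence < 1.0):
            raise ValidationError("confidence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw: Mapping = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
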
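"""Gene-set over-representation by exact hypergeometric tests.

Given a query gene list, a background universe and a GMT-style collection,
each set is scored with the one-sided hypergeometric upper tail
P[X >= k] (Fisher exact enrichment). The conservative EASE variant scores
P[X >= k-1] instead, discounting one overlapping gene. Sets are gated at
raw p < 0.05; a Benjamini-Hochberg-adjusted column is emitted for
information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger("crvi_bmd")

__all__ = ["EnrichmentRecord", "enrich", "enrichment_table"]


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int          # overlap of list with set (within universe)
    n: int          # query list size (within universe)
    K: int          # set size within universe
    N: int          # universe size
    p_value: float  # P[X >= k]
    ease_p: float   # P[X >= k-1]
    enriched: bool  # p_value < alpha


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    # hypergeom.sf(k-1) = P[X >= k]; k <= 0 gives exactly 1
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(gene_list, universe, gene_sets: GeneSetCollection,
           mode: str = "fisher", alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Score every gene set for over-representation of ``gene_list``.

    ``gene_list`` must be a subset of ``universe``; sets are intersected
    with the universe before testing. ``mode`` selects which p gates the
    ``enriched`` flag: ``"fisher"`` (P[X >= k]) or ``"ease"`` (P[X >= k-1]).
    Records are returned sorted by the gating p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(gene_list)
    stray = query - universe
    if stray:
        raise ValueError(
            f"gene list contains genes outside the universe: {sorted(stray)[:5]}"
        )
    if mode not in ("fisher", "ease"):
        raise ValueError("mode must be 'fisher' or 'ease'")
    N, n = len(universe), len(query)
    records = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        p = _upper_tail(k, N, K, n)
        ease = _upper_tail(k - 1, N, K, n)
        gate = p if mode == "fisher" else ease
        records.append(EnrichmentRecord(name, k, n, K, N, p, ease,
                                        enriched=gate < alpha))
    records.sort(key=lambda r: (r.p_value if mode == "fisher" else r.ease_p,
                                r.set_name))
    logger.info("enrichment: %d sets tested, %d at p < %g",
                len(records), sum(r.enriched for r in records), alpha)
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Records as a DataFrame with an informational BH-adjusted column."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if len(df):
        df["bh_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
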
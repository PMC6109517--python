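"""Hypergeometric over-representation analysis (ORA) against GMT sets.

For a query of n genes drawn from a universe of N genes, a set with K
universe members and k overlapping query genes is scored by the
hypergeometric upper tail p = P(X >= k), X ~ Hypergeometric(N, K, n),
BH-adjusted across the tested sets. The universe is, by default, the
genes represented on the cytokine chip rather than the whole genome, so
enrichment is relative to the chip's own composition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues

logger = logging.getLogger(__name__)


def ora(
    query: list[str] | set[str],
    sets: dict[str, dict],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped (count logged); set
    members are intersected with the universe; sets with zero universe
    overlap are skipped. Raises if the query is empty after intersection.
    Returns a frame sorted by p with columns set_name (index), N, K, n,
    k, p, adj_p, overlap_genes.
    """
    universe = set(universe)
    query = set(query)
    dropped = query - universe
    if dropped:
        logger.info("dropping %d query genes outside the universe", len(dropped))
    query &= universe
    if not query:
        raise ValueError("query empty after intersecting with the universe")

    big_n, small_n = len(universe), len(query)
    rows = []
    for name, entry in sets.items():
        members = set(entry["genes"]) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(members), small_n))
        rows.append((name, big_n, len(members), small_n, k, p, ";".join(overlap)))
    out = pd.DataFrame(
        rows, columns=["set_name", "N", "K", "n", "k", "p", "overlap_genes"]
    ).set_index("set_name")
    out["adj_p"] = adjust_pvalues(out["p"].to_numpy(), "BH")
    return out.sort_values(["p", "set_name"], kind="stable")
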
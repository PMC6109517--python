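"""Summary accounting: DMP/DMR totals, hyper/hypo percentages, Venn counts.

Percentages are computed as 100 * count / total and rounded half-up to a
configurable number of decimals (2 for probe-level shares, 1 for
region-level shares, matching common reporting practice). A zero total
yields ``None`` ("not applicable"), never 0.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct(count: int, total: int, decimals: int = 2) -> float | None:
    """100 * count / total, rounded half-up to ``decimals`` places."""
    if total == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, ROUND_HALF_UP))


def _direction_block(n_hyper: int, n_hypo: int, n_none: int = 0, decimals: int = 2) -> dict:
    total = n_hyper + n_hypo + n_none
    return {
        "n": total,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "n_none": n_none,
        "pct_hyper": pct(n_hyper, total, decimals),
        "pct_hypo": pct(n_hypo, total, decimals),
    }


def summarize_disease(dmps, dmrs=None) -> dict:
    """Per-disease accounting from significant DMP and DMR tables.

    ``dmps`` needs columns ``flag`` and ``cgi_relation`` (if present, a
    CGI-context breakdown is added); ``dmrs`` needs ``direction``.
    Flag counts are re-derived and cross-checked against the table length
    — an inconsistency raises instead of being silently repaired.
    """
    n_hyper = int((dmps["flag"] == "HyperM").sum())
    n_hypo = int((dmps["flag"] == "HypoM").sum())
    n_none = int((dmps["flag"] == "none").sum())
    if n_hyper + n_hypo + n_none != len(dmps):
        raise ValueError("flag counts do not sum to the number of DMP records")
    out = {"dmps": _direction_block(n_hyper, n_hypo, n_none, decimals=2)}
    if "cgi_relation" in dmps.columns:
        out["dmps"]["by_cgi"] = {
            c: {"n": int(k), "pct": pct(int(k), len(dmps))}
            for c, k in dmps["cgi_relation"].value_counts().items()
        }
    if dmrs is not None:
        out["dmrs"] = _direction_block(
            int((dmrs["direction"] == "HyperM").sum()),
            int((dmrs["direction"] == "HypoM").sum()),
            int((dmrs["direction"] == "mixed").sum()),
            decimals=1,
        )
    return out


def summarize_cross(shared_sites, classified, shared_dmrs=None, classified_dmrs=None) -> dict:
    """Cross-disease accounting: Venn strata, similarity/difference totals.

    ``shared_sites``: frame with ``cgi_context`` per shared probe.
    ``classified``: frame with ``category`` per shared probe.
    DMR-level inputs are optional frames with a ``category`` column.
    """
    n_island = int((shared_sites["cgi_context"] == "island").sum())
    n_neighbor = int((shared_sites["cgi_context"] == "neighbor").sum())
    n_shared_dmrs = 0 if shared_dmrs is None else len(shared_dmrs)
    n_sim_dmps = int((classified["category"] == "similarity").sum())
    n_diff_dmps = int((classified["category"] == "difference").sum())
    n_sim_dmrs = 0 if classified_dmrs is None else int(
        (classified_dmrs["category"] == "similarity").sum()
    )
    return {
        "n_shared_island_dmps": n_island,
        "n_shared_neighbor_dmps": n_neighbor,
        "n_shared_dmrs": n_shared_dmrs,
        "n_shared_dmvs_total": n_island + n_neighbor + n_shared_dmrs,
        "n_similarity_dmps": n_sim_dmps,
        "n_difference_dmps": n_diff_dmps,
        "n_similarity_dmrs": n_sim_dmrs,
        "n_similarity_dmvs_total": n_sim_dmps + n_sim_dmrs,
    }


def summary_from_counts(counts: dict) -> dict:
    """Recompute all derived percentages from bare printed counts.

    ``counts`` maps an arbitrary label to a dict with keys ``count``,
    ``total`` and optional ``decimals`` (default 2); the result maps the
    same labels to the half-up-rounded percentages. This lets the report
    arithmetic be exercised directly on published summary tables whose
    underlying matrices are unavailable.
    """
    return {
        label: pct(spec["count"], spec["total"], spec.get("decimals", 2))
        for label, spec in counts.items()
    }
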
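"""Cross-disease comparison of differential methylation.

Shared sites are the intersection of the three diseases' significant DMP
sets, stratified by CGI context (island vs neighbor = shore/shelf vs
opensea). Each shared site carries a triple of HypoM/HyperM/none flags
and is classified:

* ``similarity`` — all three flags equal and not none;
* ``difference`` — exactly one disease's flag opposite to the other two
  (one HyperM against two HypoM, or the reverse);
* ``other`` — everything else (including any triple containing none).

Cross-disease differences in methylation level are tested by one-way
fixed-effects ANOVA on per-sample beta values of the three case groups,
BH-corrected across sites. An optional residual mode subtracts each
disease's control mean first, comparing case-vs-control shifts instead
of absolute levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix
from .differential import adjust_pvalues

CATEGORY_SIMILARITY = "similarity"
CATEGORY_DIFFERENCE = "difference"
CATEGORY_OTHER = "other"


def cgi_context(cgi_relation: str) -> str:
    if cgi_relation == "island":
        return "island"
    if cgi_relation in ("shore", "shelf"):
        return "neighbor"
    return "opensea"


def find_shared(dmp_sets: dict[str, pd.Index | set], ann: pd.DataFrame) -> pd.DataFrame:
    """Probes significant in every disease, with their CGI context.

    Returns a frame indexed by probe id with column ``cgi_context``;
    empty intersection yields an empty frame (not an error).
    """
    ids = None
    for probes in dmp_sets.values():
        s = set(probes)
        ids = s if ids is None else ids & s
    shared = sorted(ids or set())
    ctx = [cgi_context(ann.at[p, "cgi_relation"]) for p in shared]
    return pd.DataFrame({"cgi_context": ctx}, index=pd.Index(shared, name="probe_id"))


def classify(flags: tuple[str, str, str]) -> str:
    """Similarity / difference / other for one flag triple."""
    for f in flags:
        if f not in ("HyperM", "HypoM", "none"):
            raise ValueError(f"unknown flag {f!r}")
    if "none" in flags:
        return CATEGORY_OTHER
    n_hyper = sum(f == "HyperM" for f in flags)
    if n_hyper in (0, 3):
        return CATEGORY_SIMILARITY
    return CATEGORY_DIFFERENCE  # 1 vs 2 split, either way


def classify_sites(
    shared: pd.DataFrame, dmp_records: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Attach per-disease flags and the category to each shared site."""
    diseases = list(dmp_records)
    out = shared.copy()
    for d in diseases:
        out[f"flag_{d}"] = dmp_records[d].loc[out.index, "flag"]
    out["category"] = [
        classify(tuple(out.loc[p, [f"flag_{d}" for d in diseases]]))
        for p in out.index
    ]
    return out


def anova_across(
    case_betas: dict[str, pd.DataFrame],
    sites: pd.Index | list[str],
    control_betas: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per site across the disease case groups.

    ``case_betas`` maps disease -> (probes x case samples) beta frame.
    When ``control_betas`` is given, each disease's per-probe control
    mean is subtracted first (residual mode). Returns F, p, adj_p per
    site; a site with zero between- and within-group variance gets
    F = 0, p = 1.
    """
    sites = list(sites)
    groups = []
    for d, frame in case_betas.items():
        vals = frame.loc[sites].to_numpy(dtype=float)
        if vals.shape[1] < 2:
            raise ValueError(f"disease {d} has fewer than 2 case samples")
        if control_betas is not None:
            vals = vals - np.nanmean(
                control_betas[d].loc[sites].to_numpy(dtype=float), axis=1, keepdims=True
            )
        groups.append(vals)

    k = len(groups)
    ns = np.array([g.shape[1] for g in groups], dtype=float)
    n_tot = ns.sum()
    means = np.column_stack([np.nanmean(g, axis=1) for g in groups])
    grand = (means * ns).sum(axis=1) / n_tot
    ss_between = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ss_within = np.column_stack(
        [np.nansum((g - m[:, None]) ** 2, axis=1) for g, m in zip(groups, means.T)]
    ).sum(axis=1)
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ss_within <= 0
    f = np.where(degenerate & (ss_between <= 0), 0.0, f)
    f = np.where(degenerate & (ss_between > 0), np.inf, f)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(degenerate & (ss_between <= 0), 1.0, p)
    out = pd.DataFrame({"anova_F": f, "anova_p": p}, index=pd.Index(sites, name="probe_id"))
    out["anova_adj_p"] = adjust_pvalues(out["anova_p"].to_numpy(), "BH")
    return out


def shared_dmrs(
    dmr_sets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Match DMRs across diseases by >= 1 bp interval overlap on one chromosome.

    Returns one row per overlap triple with the per-disease region ids,
    directions and the classify() category (mixed directions -> other,
    like a none flag).
    """
    diseases = list(dmr_sets)
    if len(diseases) != 3:
        raise ValueError("expected exactly three diseases")
    a, b, c = (dmr_sets[d] for d in diseases)
    rows = []
    for ra, reg_a in a.iterrows():
        for rb, reg_b in b.iterrows():
            if reg_b["chrom"] != reg_a["chrom"]:
                continue
            if reg_b["start"] > reg_a["end"] or reg_b["end"] < reg_a["start"]:
                continue
            for rc, reg_c in c.iterrows():
                if reg_c["chrom"] != reg_a["chrom"]:
                    continue
                lo = max(reg_a["start"], reg_b["start"], reg_c["start"])
                hi = min(reg_a["end"], reg_b["end"], reg_c["end"])
                if lo > hi:
                    continue
                dirs = (reg_a["direction"], reg_b["direction"], reg_c["direction"])
                flags = tuple("none" if d == "mixed" else d for d in dirs)
                rows.append(
                    {
                        "chrom": reg_a["chrom"], "start": int(lo), "end": int(hi),
                        **{f"region_{d}": r for d, r in zip(diseases, (ra, rb, rc))},
                        **{f"direction_{d}": v for d, v in zip(diseases, dirs)},
                        "category": classify(flags),
                    }
                )
    return pd.DataFrame(rows)
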
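"""Inverse-variance meta-analysis of per-probe effects across datasets.

Combines the delta-beta estimates of several chips of one disease.
Fixed-effect: pooled = sum(w_d * e_d) / sum(w_d), w_d = 1 / SE_d^2.
Heterogeneity: Cochran's Q; between-study variance tau^2 by
DerSimonian-Laird, tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)).
Random-effects weights 1 / (SE_d^2 + tau^2). Two-sided normal p per
probe, Benjamini-Hochberg across probes.

Probes absent from some datasets (e.g. removed by QC) are combined over
the datasets that retain them; a single-study probe passes through with
its own effect and SE and an undefined Q.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues, flag_of


def meta_analyze(per_dataset: list[pd.DataFrame], model: str = "auto") -> pd.DataFrame:
    """Combine per-dataset DMP tables (columns delta_beta, se) by probe.

    ``model``: 'fixed', 'random', or 'auto' (random-effects estimate is
    used for the reported effect whenever tau^2 > 0, else fixed; both are
    always reported). Returns one row per probe with pooled effect, SE,
    z, p, adj_p, Q, tau2, k (number of contributing studies), the chosen
    model, plus ``delta_beta``/``flag`` aliases so downstream selection
    and DMR calling work unchanged.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError("model must be 'fixed', 'random' or 'auto'")
    if not per_dataset:
        raise ValueError("no datasets to combine")
    frames = []
    for i, df in enumerate(per_dataset):
        if (df["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        frames.append(df[["delta_beta", "se"]].assign(study=i))
    stacked = pd.concat(frames)

    rows = []
    for probe, grp in stacked.groupby(level=0, sort=True):
        e = grp["delta_beta"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        k = e.size
        w = 1.0 / se**2
        fixed = float((w * e).sum() / w.sum())
        fixed_se = float(np.sqrt(1.0 / w.sum()))
        if k > 1:
            q = float((w * (e - fixed) ** 2).sum())
            denom = w.sum() - (w**2).sum() / w.sum()
            tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        else:
            q, tau2 = np.nan, 0.0
        wr = 1.0 / (se**2 + tau2)
        random = float((wr * e).sum() / wr.sum())
        random_se = float(np.sqrt(1.0 / wr.sum()))
        use_random = model == "random" or (model == "auto" and tau2 > 0)
        eff, eff_se = (random, random_se) if use_random else (fixed, fixed_se)
        z = eff / eff_se
        rows.append((probe, k, fixed, fixed_se, random, random_se, tau2, q,
                     eff, eff_se, z, "random" if use_random else "fixed"))

    out = pd.DataFrame(
        rows,
        columns=["probe_id", "k", "fixed_effect", "fixed_se", "random_effect",
                 "random_se", "tau2", "Q", "pooled_effect", "pooled_se", "z", "model"],
    ).set_index("probe_id")
    out["p"] = 2 * stats.norm.sf(np.abs(out["z"]))
    out["adj_p"] = adjust_pvalues(out["p"].to_numpy(), "BH")
    out["delta_beta"] = out["pooled_effect"]
    out["se"] = out["pooled_se"]
    out["t_stat"] = out["z"]
    out["flag"] = [flag_of(v) for v in out["pooled_effect"]]
    return out
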
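"""Differentially methylated region (DMR) calling.

A DMR is a maximal run of significant probes on one chromosome in which
every successive inter-probe gap is at most ``max_gap`` base pairs
(default 1 kb); runs with at least ``min_probes`` members (default 5)
are reported. Coordinates are 1-based inclusive positions of the first
and last member probe.

The region p-value combines member probe evidence by Stouffer's method
on signed z-scores (sign from delta-beta), so opposing directions cancel;
Fisher's unsigned combination is available as an option. Region p-values
are BH-adjusted across reported regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues


@dataclass
class DMRConfig:
    max_gap: int = 1000
    min_probes: int = 5
    region_p_method: str = "stouffer"  # or "fisher"

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.region_p_method not in ("stouffer", "fisher"):
            raise ValueError("region_p_method must be 'stouffer' or 'fisher'")


def _signed_z(p: np.ndarray, delta: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-300, 1.0)
    z = stats.norm.isf(p / 2)  # two-sided magnitude
    return np.sign(delta) * z


def _region_p(p: np.ndarray, delta: np.ndarray, method: str) -> float:
    if method == "fisher":
        chi2 = -2 * np.log(np.clip(p, 1e-300, 1.0)).sum()
        return float(stats.chi2.sf(chi2, 2 * p.size))
    z = _signed_z(p, delta).sum() / np.sqrt(p.size)
    return float(2 * stats.norm.sf(abs(z)))


def call_dmrs(dmps: pd.DataFrame, ann: pd.DataFrame, cfg: DMRConfig | None = None) -> pd.DataFrame:
    """Cluster significant probes into regions per the gap rule.

    ``dmps`` is a table of significant DMP records (index probe_id,
    columns delta_beta, p, flag) already sorted by (chrom, pos) per the
    annotation — unsorted input raises, no silent re-sorting, so that
    coordinate handling stays auditable.

    Returns one row per region: chrom, start, end, probe_ids
    (semicolon-joined, in positional order), n_probes, mean_delta_beta,
    direction (HyperM/HypoM when all member flags agree, else mixed),
    region_p, region_adj_p.
    """
    cfg = cfg or DMRConfig()
    if dmps.empty:
        return pd.DataFrame(
            columns=["region_id", "chrom", "start", "end", "probe_ids", "n_probes",
                     "mean_delta_beta", "direction", "region_p", "region_adj_p"]
        ).set_index("region_id")
    missing = dmps.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing {len(missing)} probes")
    chrom = ann.loc[dmps.index, "chrom"].to_numpy()
    pos = ann.loc[dmps.index, "pos"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(dmps))):
        raise ValueError("DMP input must be sorted by (chrom, pos)")

    new_run = np.ones(len(dmps), dtype=bool)
    if len(dmps) > 1:
        same = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= cfg.max_gap
        new_run[1:] = ~(same & close)
    run_id = np.cumsum(new_run)

    rows = []
    for rid in np.unique(run_id):
        mask = run_id == rid
        if mask.sum() < cfg.min_probes:
            continue
        members = dmps.index[mask]
        deltas = dmps.loc[members, "delta_beta"].to_numpy(dtype=float)
        flags = set(dmps.loc[members, "flag"])
        direction = flags.pop() if len(flags) == 1 and flags != {"none"} else "mixed"
        if direction == "none":
            direction = "mixed"
        rows.append(
            {
                "chrom": chrom[mask][0],
                "start": int(pos[mask][0]),
                "end": int(pos[mask][-1]),
                "probe_ids": ";".join(members),
                "n_probes": int(mask.sum()),
                "mean_delta_beta": float(deltas.mean()),
                "direction": direction,
                "region_p": _region_p(dmps.loc[members, "p"].to_numpy(dtype=float),
                                      deltas, cfg.region_p_method),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=["chrom", "start", "end", "probe_ids", "n_probes",
                     "mean_delta_beta", "direction", "region_p"]
        )
    out.index = pd.Index([f"dmr{i + 1:04d}" for i in range(len(out))], name="region_id")
    out["region_adj_p"] = adjust_pvalues(out["region_p"].to_numpy(dtype=float), "BH")
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive spans to BED (0-based half-open) records."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": dmrs.index,
            "score": dmrs["n_probes"],
            "strand": ".",
        }
    )
    return bed.reset_index(drop=True)
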
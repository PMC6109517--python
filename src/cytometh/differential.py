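"""Per-probe case/control differential methylation testing.

The workhorse is a two-group linear-model t-test per probe (equivalent to
the pooled two-sample t-test when variance shrinkage is off), run on the
beta scale by default or optionally on the M scale. Effect size is always
reported as delta-beta = mean(beta_case) - mean(beta_control), with the
methylation-status flag HyperM / HypoM / none by its sign.

Variance shrinkage, when enabled, moderates the per-probe pooled variance
toward the cross-probe mean with a prior degrees-of-freedom d0
(empirical-Bayes style): s2* = (d0*s0^2 + df*s2) / (d0 + df), and the
t statistic is referred to a t distribution with df + d0 degrees of
freedom. This approximates the moderated tests of the standard array
toolchains without being a byte-level clone of any of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, beta_to_m


@dataclass
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    scale: str = "beta"  # or "M"
    shrink_var: bool = False
    prior_df: float = 3.0
    variance_floor: float = 1e-10
    correction: str = "BH"  # or "bonferroni"
    alpha: float = 0.05
    min_abs_delta_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if self.correction not in ("BH", "bonferroni"):
            raise ValueError("correction must be 'BH' or 'bonferroni'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_delta_beta < 0:
            raise ValueError("min_abs_delta_beta must be >= 0")


#: The stringent selection mode: Bonferroni-corrected p < 0.05 and
#: |delta-beta| >= 0.01 (used when controls come from stochastic sampling).
STRINGENT = TestConfig(correction="bonferroni", min_abs_delta_beta=0.01)


def flag_of(delta: float) -> str:
    if delta > 0:
        return "HyperM"
    if delta < 0:
        return "HypoM"
    return "none"


def delta_beta(beta: BetaMatrix, probe: str) -> tuple[float, float, float, str]:
    """(beta_case, beta_control, delta_beta, flag) for one probe.

    Missing values are excluded from the group means. Raises if a group
    has no non-missing value for the probe.
    """
    row = beta.values.loc[probe]
    case = row[beta.samples_in_group("case")].dropna()
    ctrl = row[beta.samples_in_group("control")].dropna()
    if case.empty or ctrl.empty:
        raise ValueError(f"probe {probe} has an all-missing group")
    bc, bn = float(case.mean()), float(ctrl.mean())
    d = bc - bn
    return bc, bn, d, flag_of(d)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, input order preserved.

    BH: step-up adjusted values (monotone, capped at 1), ties resolved by
    stable sort. bonferroni: min(1, m * p).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "BH":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dmp_test(beta: BetaMatrix, cfg: TestConfig | None = None, dataset_id: str = "") -> pd.DataFrame:
    """Two-group t-test per probe; returns one DMP record per probe.

    Columns: probe_id (index), beta_case_mean, beta_control_mean,
    delta_beta, se (standard error of delta_beta on the beta scale),
    t_stat, p, adj_p, flag, dataset_id, n_case, n_control.

    Probes with an all-missing group are dropped (counted in the
    ``attrs['n_invalid']`` attribute of the returned frame). Probes with
    zero residual variance get t = 0, p = 1 when the group means agree;
    otherwise the variance is replaced by ``variance_floor`` and a
    warning is emitted.
    """
    cfg = cfg or TestConfig()
    case_ids = beta.samples_in_group("case")
    ctrl_ids = beta.samples_in_group("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need >= 2 samples per group")

    bvals = beta.values.to_numpy(dtype=float)
    case_cols = beta.values.columns.get_indexer(case_ids)
    ctrl_cols = beta.values.columns.get_indexer(ctrl_ids)
    bc_all, bn_all = bvals[:, case_cols], bvals[:, ctrl_cols]

    x = beta_to_m(bvals) if cfg.scale == "M" else bvals
    xc, xn = x[:, case_cols], x[:, ctrl_cols]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1 = np.sum(~np.isnan(xc), axis=1).astype(float)
        n2 = np.sum(~np.isnan(xn), axis=1).astype(float)
        m1, m2 = np.nanmean(xc, axis=1), np.nanmean(xn, axis=1)
        v1, v2 = np.nanvar(xc, axis=1, ddof=1), np.nanvar(xn, axis=1, ddof=1)
        beta_case = np.nanmean(bc_all, axis=1)
        beta_ctrl = np.nanmean(bn_all, axis=1)
        vb1 = np.nanvar(bc_all, axis=1, ddof=1)
        vb2 = np.nanvar(bn_all, axis=1, ddof=1)

    valid = (n1 >= 2) & (n2 >= 2)
    n_invalid = int((~valid).sum())

    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if cfg.shrink_var:
        s0 = np.nanmean(pooled[valid]) if valid.any() else 0.0
        d0 = cfg.prior_df
        pooled = (d0 * s0 + df * pooled) / (d0 + df)
        df = df + d0

    diff = m1 - m2
    zero_var = valid & (pooled <= 0)
    conflict = zero_var & (diff != 0)
    if conflict.any():
        warnings.warn(
            f"{int(conflict.sum())} probes with zero variance but unequal means; "
            "variance floored", RuntimeWarning, stacklevel=2,
        )
        pooled = np.where(conflict, cfg.variance_floor, pooled)
        zero_var = valid & (pooled <= 0)

    denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    p = 2 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(zero_var, 1.0, p)

    d = beta_case - beta_ctrl
    se = np.sqrt(vb1 / n1 + vb2 / n2)
    out = pd.DataFrame(
        {
            "beta_case_mean": beta_case,
            "beta_control_mean": beta_ctrl,
            "delta_beta": d,
            "se": se,
            "t_stat": t,
            "p": p,
            "n_case": n1.astype(int),
            "n_control": n2.astype(int),
        },
        index=beta.probe_ids.rename("probe_id"),
    )[valid]
    out["adj_p"] = adjust_pvalues(out["p"].to_numpy(), cfg.correction)
    out["flag"] = [flag_of(v) for v in out["delta_beta"]]
    out["dataset_id"] = dataset_id
    out.attrs["n_invalid"] = n_invalid
    return out


def select_significant(records: pd.DataFrame, cfg: TestConfig | None = None) -> pd.DataFrame:
    """adj_p < alpha and |delta_beta| >= min_abs_delta_beta."""
    cfg = cfg or TestConfig()
    keep = (records["adj_p"] < cfg.alpha) & (
        records["delta_beta"].abs() >= cfg.min_abs_delta_beta
    )
    return records[keep]
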
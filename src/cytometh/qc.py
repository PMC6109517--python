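"""Sample and probe quality-control filters for 450K-style beta matrices.

Filtering order is fixed: samples first, then probes. Sample filtering
changes the denominator of the per-probe low-bead-count fraction, so the
order matters; running samples first matches the convention of the
standard array-QC toolchains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import BetaMatrix


@dataclass
class QCConfig:
    """Thresholds of the quality filters.

    A probe measurement is "failed" when its detection p-value exceeds
    ``detection_p_threshold``; a sample is discarded when its failed
    fraction is strictly greater than ``max_failed_probe_frac_per_sample``.
    A probe is discarded when its bead count falls below ``min_beadcount``
    in at least ``max_lowbead_sample_frac`` of samples, or when it is
    flagged as SNP-overlapping or multi-mapping, or lies on chromosome Y.
    """

    max_failed_probe_frac_per_sample: float = 0.10
    detection_p_threshold: float = 0.01
    min_beadcount: int = 3
    max_lowbead_sample_frac: float = 0.05
    drop_snp_overlap: bool = True
    drop_multihit: bool = True
    drop_chry: bool = True

    def __post_init__(self) -> None:
        for name in ("max_failed_probe_frac_per_sample", "detection_p_threshold",
                     "max_lowbead_sample_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_beadcount < 1:
            raise ValueError("min_beadcount must be >= 1")


class QCError(ValueError):
    pass


def filter_samples(beta: BetaMatrix, cfg: QCConfig, report: dict | None = None) -> BetaMatrix:
    """Drop samples whose failed-probe fraction exceeds the threshold.

    Strict inequality: a sample at exactly the threshold is retained.
    Raises :class:`QCError` if a (dataset, group) cell is emptied.
    """
    if beta.detection_p is None:
        raise QCError("detection p-value matrix required for sample QC")
    failed_frac = (beta.detection_p > cfg.detection_p_threshold).mean(axis=0)
    keep = failed_frac <= cfg.max_failed_probe_frac_per_sample
    dropped = list(failed_frac.index[~keep])
    kept = beta.select_samples(list(failed_frac.index[keep]))
    groups = kept.sample_sheet.groupby(["dataset_id", "group"]).size()
    before = beta.sample_sheet.groupby(["dataset_id", "group"]).size()
    for key in before.index:
        if key not in groups.index:
            raise QCError(f"group emptied by QC: dataset={key[0]} group={key[1]}")
    if report is not None:
        report["samples_dropped"] = dropped
        report["sample_failed_fraction"] = failed_frac.round(4).to_dict()
    return kept


def filter_probes(
    beta: BetaMatrix, ann: pd.DataFrame, cfg: QCConfig, report: dict | None = None
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop probes failing bead-count, SNP-overlap, multi-hit or chrY rules.

    Note the bead-count criterion as printed in array-QC write-ups is
    often garbled; here it is the standard reading: a probe is removed
    when its bead count is below ``min_beadcount`` in at least
    ``max_lowbead_sample_frac`` of the (already sample-filtered) samples.
    """
    missing = beta.probe_ids.difference(ann.index)
    if len(missing):
        raise QCError(f"annotation missing {len(missing)} probes")
    sub = ann.loc[beta.probe_ids]

    drop = pd.Series(False, index=beta.probe_ids)
    reasons: dict[str, int] = {}
    if beta.beadcount is not None:
        lowbead = (beta.beadcount < cfg.min_beadcount).mean(axis=1) >= cfg.max_lowbead_sample_frac
        drop |= lowbead
        reasons["low_beadcount"] = int(lowbead.sum())
    if cfg.drop_snp_overlap:
        drop |= sub["snp_overlap"]
        reasons["snp_overlap"] = int(sub["snp_overlap"].sum())
    if cfg.drop_multihit:
        drop |= sub["multihit"]
        reasons["multihit"] = int(sub["multihit"].sum())
    if cfg.drop_chry:
        chry = sub["chrom"] == "chrY"
        drop |= chry
        reasons["chrY"] = int(chry.sum())

    keep_ids = list(beta.probe_ids[~drop])
    if not keep_ids:
        raise QCError("all probes removed by QC")
    if report is not None:
        report["probes_dropped"] = int(drop.sum())
        report["probes_dropped_by_criterion"] = reasons
        report["beadcount_rule"] = (
            f"drop probes with beadcount < {cfg.min_beadcount} in >= "
            f"{cfg.max_lowbead_sample_frac:.0%} of samples (standard reading of the "
            "conventional, ambiguously printed criterion)"
        )
    return beta.select_probes(keep_ids), sub.loc[keep_ids]


def run_qc(
    beta: BetaMatrix, ann: pd.DataFrame, cfg: QCConfig | None = None
) -> tuple[BetaMatrix, pd.DataFrame, dict]:
    """Samples first, then probes; returns (beta, annotation, report)."""
    cfg = cfg or QCConfig()
    report: dict = {}
    beta = filter_samples(beta, cfg, report)
    beta, ann = filter_probes(beta, ann, cfg, report)
    return beta, ann, report
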
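"""In-memory containers shared across the pipeline.

The universal carrier is :class:`BetaMatrix`: a probes x samples matrix of
methylation beta values (fraction methylated, in [0, 1]) together with the
per-sample metadata sheet and, optionally, the companion detection p-value
and bead-count matrices produced by the array scanner.

Probe annotation travels as a plain :class:`pandas.DataFrame` indexed by
probe id with the columns listed in :data:`ANNOTATION_COLUMNS`; helper
validators enforce the schema at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a probe annotation frame (index: probe_id).
ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "genes",
    "feature",
    "cgi_relation",
    "design_type",
    "snp_overlap",
    "multihit",
)

FEATURES = ("TSS200", "TSS1500", "1stExon", "Body", "5'UTR", "3'UTR", "IGR")
CGI_RELATIONS = ("island", "shore", "shelf", "opensea")

#: Promoter-region features, in the priority order used for gene-level stats.
PROMOTER_FEATURES = ("TSS200", "1stExon", "TSS1500")


class SchemaError(ValueError):
    """Raised when a container violates its documented schema."""


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation frame against the schema and return it.

    Requires unique probe ids, 1-based positions and no duplicated
    (chrom, pos) pairs so that probes are unambiguously sortable along
    the genome.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise SchemaError(f"annotation missing columns: {missing}")
    if not ann.index.is_unique:
        raise SchemaError("probe ids are not unique")
    if (ann["pos"] < 1).any():
        raise SchemaError("positions must be 1-based (>= 1)")
    if ann.duplicated(subset=["chrom", "pos"]).any():
        raise SchemaError("duplicate (chrom, pos) coordinates")
    bad_feat = set(ann["feature"]) - set(FEATURES)
    if bad_feat:
        raise SchemaError(f"unknown feature values: {sorted(bad_feat)}")
    bad_cgi = set(ann["cgi_relation"]) - set(CGI_RELATIONS)
    if bad_cgi:
        raise SchemaError(f"unknown cgi_relation values: {sorted(bad_cgi)}")
    if not set(ann["design_type"]) <= {"I", "II"}:
        raise SchemaError("design_type must be 'I' or 'II'")
    return ann


def split_genes(genes: str) -> list[str]:
    """Split a semicolon-joined gene field into clean symbols ('' -> [])."""
    if not isinstance(genes, str) or not genes.strip():
        return []
    return [g.strip() for g in genes.split(";") if g.strip()]


@dataclass
class BetaMatrix:
    """Probes x samples methylation matrix with sample metadata.

    Attributes
    ----------
    values
        DataFrame of beta values in [0, 1] (NaN allowed), indexed by
        probe id, columns are sample ids.
    sample_sheet
        DataFrame indexed by sample id with columns ``group`` (one of
        ``case``/``control``), ``dataset_id``, ``age``, ``sex``.
    detection_p, beadcount
        Optional companion matrices aligned with ``values``.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    beadcount: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_sheet.index):
            raise SchemaError("sample sheet not aligned with value columns")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise SchemaError("beta values outside [0, 1]")
        for name in ("detection_p", "beadcount"):
            comp = getattr(self, name)
            if comp is not None and (
                list(comp.index) != list(self.values.index)
                or list(comp.columns) != list(self.values.columns)
            ):
                raise SchemaError(f"{name} matrix not aligned with values")

    # -- convenience -------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        sheet = self.sample_sheet
        return list(sheet.index[sheet["group"] == group])

    def select_samples(self, sample_ids: list[str]) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values[sample_ids],
            sample_sheet=self.sample_sheet.loc[sample_ids],
            detection_p=None if self.detection_p is None else self.detection_p[sample_ids],
            beadcount=None if self.beadcount is None else self.beadcount[sample_ids],
        )

    def select_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.loc[probe_ids],
            sample_sheet=self.sample_sheet,
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            beadcount=None if self.beadcount is None else self.beadcount.loc[probe_ids],
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.copy(),
            sample_sheet=self.sample_sheet.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            beadcount=None if self.beadcount is None else self.beadcount.copy(),
        )


def beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """log2(beta / (1 - beta)) after clipping into [eps, 1 - eps]."""
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse logit2: beta = 2^M / (2^M + 1), always in (0, 1)."""
    # computed via expit-style stable form
    out = np.empty_like(np.asarray(m, dtype=float))
    m = np.asarray(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + 2.0 ** (-m[pos]))
    out[~pos] = 2.0 ** m[~pos] / (2.0 ** m[~pos] + 1.0)
    return out
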
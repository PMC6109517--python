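"""Cytokine-chip construction: probe subsetting by gene list + composition.

A "cytokine chip" is the restriction of the full probe universe to probes
annotated to a curated list of cytokine-relevant genes; downstream
differential analyses run on this subset only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import CGI_RELATIONS, split_genes
from .report import pct


@dataclass
class GeneList:
    """Case-normalized, de-duplicated gene symbols with optional notes."""

    symbols: frozenset[str]
    descriptions: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneList":
        symbols = frame.iloc[:, 0].astype(str).str.strip().str.upper()
        symbols = symbols[symbols != ""]
        if symbols.empty:
            raise ValueError("gene list is empty")
        desc = {}
        if frame.shape[1] > 1:
            desc = dict(zip(symbols, frame.iloc[:, 1].astype(str)))
        return cls(symbols=frozenset(symbols), descriptions=desc)

    @classmethod
    def from_symbols(cls, symbols) -> "GeneList":
        return cls.from_frame(pd.DataFrame({"gene": list(symbols)}))


def subset_chip(ann: pd.DataFrame, genes: GeneList) -> pd.DataFrame:
    """Retain probes whose gene set intersects the list (any-match rule).

    A probe annotated to several genes ("A;C") is retained if any one of
    them is listed. Symbols are compared case-insensitively after
    whitespace stripping. Probe order is preserved. Raises if no probe
    matches.
    """
    listed = genes.symbols
    keep = ann["genes"].apply(
        lambda gs: any(g.upper() in listed for g in split_genes(gs))
    )
    if not keep.any():
        raise ValueError("gene list matches no probes")
    return ann[keep]


def chip_composition(ann: pd.DataFrame) -> dict:
    """Probe counts and percentages per CGI relation and chromosome."""
    if ann.empty:
        raise ValueError("empty annotation")
    n = len(ann)
    cgi_counts = {c: int((ann["cgi_relation"] == c).sum()) for c in CGI_RELATIONS}
    chrom_counts = ann["chrom"].value_counts().to_dict()
    return {
        "n_probes": n,
        "cgi_counts": cgi_counts,
        "cgi_percent": {c: pct(k, n) for c, k in cgi_counts.items()},
        "chrom_counts": {c: int(v) for c, v in chrom_counts.items()},
        "chrom_percent": {c: pct(int(v), n) for c, v in chrom_counts.items()},
    }
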
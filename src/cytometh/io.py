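"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular files are TSV (beta matrix, annotation, detection p, bead
counts, gene list, PPI edge list, truth tables) except the sample sheet,
which is CSV, and gene-set collections, which use the standard GMT layout
(set name, description, then tab-separated gene symbols).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ANNOTATION_COLUMNS, BetaMatrix, validate_annotation


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a probes x samples TSV whose first column is the probe id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col=0)
    required = {"group", "dataset_id"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(required - set(sheet.columns))}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype={"chrom": str, "genes": str},
        keep_default_na=False,
        na_values=[],
    )
    ann["pos"] = ann["pos"].astype(int)
    for col in ("snp_overlap", "multihit"):
        if ann[col].dtype == object:
            ann[col] = ann[col].astype(str).str.lower().isin(("true", "1", "yes"))
        else:
            ann[col] = ann[col].astype(bool)
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index_label="probe_id", columns=list(ANNOTATION_COLUMNS))


def read_beta_matrix(beta_path, sheet_path, detp_path=None, beads_path=None) -> BetaMatrix:
    """Assemble a BetaMatrix from its on-disk parts."""
    return BetaMatrix(
        values=read_matrix_tsv(beta_path),
        sample_sheet=read_sample_sheet(sheet_path),
        detection_p=None if detp_path is None else read_matrix_tsv(detp_path),
        beadcount=None if beads_path is None else read_matrix_tsv(beads_path),
    )


def write_beta_matrix(beta: BetaMatrix, outdir, prefix: str) -> dict[str, Path]:
    """Write all parts of a BetaMatrix under ``outdir`` with a name prefix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"beta": outdir / f"{prefix}_beta.tsv", "sheet": outdir / f"{prefix}_samples.csv"}
    write_matrix_tsv(beta.values, paths["beta"])
    write_sample_sheet(beta.sample_sheet, paths["sheet"])
    if beta.detection_p is not None:
        paths["detp"] = outdir / f"{prefix}_detp.tsv"
        write_matrix_tsv(beta.detection_p, paths["detp"])
    if beta.beadcount is not None:
        paths["beads"] = outdir / f"{prefix}_beads.tsv"
        write_matrix_tsv(beta.beadcount, paths["beads"])
    return paths


def read_gene_list(path) -> pd.DataFrame:
    """Read a gene list TSV: first column symbol, optional description."""
    genes = pd.read_csv(path, sep="\t")
    first = genes.columns[0]
    if first.lower() not in ("gene", "symbol", "gene_symbol"):
        # headerless single-column file
        genes = pd.read_csv(path, sep="\t", header=None, names=["gene"])
    genes = genes.rename(columns={first: "gene"}) if "gene" not in genes.columns else genes
    genes["gene"] = genes["gene"].astype(str).str.strip().str.upper()
    return genes


def read_ppi(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    if edges.shape[1] < 2:
        raise ValueError("PPI edge list needs two gene columns")
    edges.columns = ["gene_a", "gene_b", *edges.columns[2:]]
    return edges


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file into {set_name: {'description': str, 'genes': [..]}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = {"description": desc, "genes": genes}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for name, entry in sets.items():
            fh.write("\t".join([name, entry.get("description", ""), *entry["genes"]]) + "\n")
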
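"""Synthetic 450K-style methylation studies with known planted effects.

The generator emulates the inputs of the cross-disease pipeline: one probe
annotation shared by all datasets (as with a real array manifest),
case/control beta matrices per dataset with companion detection-p and
bead-count matrices, a cytokine gene list, a PPI network with a planted
dense differentially methylated module, and GMT gene-set collections.

Beta values are produced on the M scale (log2-odds of methylation), where
effects are additive, and back-transformed with beta = 2^M / (2^M + 1):

* each probe draws an unmethylated / hemimethylated / methylated state and
  a design-type-specific baseline M around that state's mode — type-II
  modes are compressed toward 0.5 relative to type I, mimicking the
  Infinium type-I/type-II discrepancy that BMIQ-style normalization
  corrects;
* case samples receive a signed shift of ``effect_delta`` M-units at
  planted probes;
* independent Gaussian M-noise is added per sample, then values are mapped
  back to the beta scale.

Planted regions (DMRs) occupy consecutive probes of one gene cluster with
inter-probe gaps below 1 kb; gene clusters are separated by more than 1 kb
so a region's probe membership is unambiguous. A truth table records every
planted probe and region with its direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix, m_to_beta, validate_annotation

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

# M-scale modes of the unmethylated / hemi / methylated states per design
# type; type II is compressed toward 0 (beta 0.5).
_MODES_TYPE1 = np.log2(np.array([0.05, 0.5, 0.95]) / (1 - np.array([0.05, 0.5, 0.95])))
_MODES_TYPE2 = np.log2(np.array([0.10, 0.5, 0.85]) / (1 - np.array([0.10, 0.5, 0.85])))
_STATE_PROBS = (0.4, 0.2, 0.4)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic single-disease methylation study.

    ``effect_delta`` is the planted case-vs-control shift in M-units
    (log2-odds); at a hemimethylated baseline (M = 0) a shift of 1.0
    corresponds to a delta-beta of 2/3 - 1/2 = 1/6.
    """

    n_probes: int = 2000
    n_genes: int = 400
    n_datasets: int = 1
    n_cases: int = 50
    n_controls: int = 50
    frac_dmp: float = 0.05
    effect_delta: float = 1.0
    dmr_spec: Sequence[tuple[str, int, int]] = ()  # (gene, n_probes >= 5, direction +1/-1)
    frac_type2: float = 0.5
    noise_sd: float = 0.5
    detection_fail_rate: float = 0.002
    beadcount_low_rate: float = 0.002
    frac_chry: float = 0.01
    frac_snp: float = 0.01
    frac_multihit: float = 0.005
    ppi_spec: tuple[int, float, int] = (150, 0.05, 12)  # (n_nodes, edge_prob, module size)
    rng_seed: int = 0
    allow_null: bool = False

    def __post_init__(self) -> None:
        for name in ("frac_dmp", "frac_type2", "detection_fail_rate",
                     "beadcount_low_rate", "frac_chry", "frac_snp", "frac_multihit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_probes", "n_genes", "n_datasets", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for gene, k, direction in self.dmr_spec:
            if k < 5:
                raise ValueError(f"planted region {gene!r} needs >= 5 probes")
            if direction not in (-1, 1):
                raise ValueError("region direction must be +1 or -1")


@dataclass
class Truth:
    """Planted-effect bookkeeping.

    ``probes``: one row per planted probe (probe_id, gene, direction,
    kind in {dmp, dmr}, region_id). ``regions``: one row per planted
    region (region_id, gene, chrom, start, end, probe ids, direction).
    """

    probes: pd.DataFrame
    regions: pd.DataFrame


@dataclass
class SimulatedStudy:
    datasets: dict[str, BetaMatrix]
    annotation: pd.DataFrame
    truth: Truth
    baseline_m: pd.Series = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# annotation


def _gene_symbols(n: int) -> list[str]:
    return [f"CYT{i + 1:04d}" for i in range(n)]

def make_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out gene probe clusters along chromosomes.

    Every gene cluster starts with a TSS200 probe (then TSS1500, 1stExon,
    then gene-body-like features), so each gene has promoter probes for
    gene-level statistics. Clusters are separated by > 1 kb; within a
    cluster successive probes are 50-900 bp apart.
    """
    genes = _gene_symbols(cfg.n_genes)
    dmr_genes = [g for g, _, _ in cfg.dmr_spec]
    unknown = set(dmr_genes) - set(genes)
    if unknown:
        raise ValueError(f"dmr_spec genes not in gene universe: {sorted(unknown)}")
    dmr_sizes = {g: k for g, k, _ in cfg.dmr_spec}

    # number of probes per gene cluster; planted-region genes get their
    # required count (+1 extra promoter probe kept un-planted upstream of
    # the region is not needed: the whole cluster is the region)
    n_assigned = 0
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g] = dmr_sizes.get(g, 0)
        n_assigned += sizes[g]
    remaining = cfg.n_probes - n_assigned
    free_genes = [g for g in genes if g not in dmr_sizes]
    if remaining < len(free_genes):
        raise ValueError("n_probes too small for n_genes and dmr_spec")
    extra = rng.multinomial(remaining - len(free_genes), np.full(len(free_genes), 1 / len(free_genes)))
    for g, e in zip(free_genes, extra):
        sizes[g] = 1 + int(e)

    n_chry_genes = int(round(cfg.frac_chry * len(free_genes)))
    chry_genes = set(rng.choice(free_genes, size=n_chry_genes, replace=False)) if n_chry_genes else set()

    feature_pool = np.array(["Body", "Body", "Body", "5'UTR", "3'UTR"])
    cgi_probs = np.array([0.34, 0.23, 0.07, 0.36])

    rows = []
    cursors: dict[str, int] = {}
    order = list(genes)
    rng.shuffle(order)
    for gi, g in enumerate(order):
        k = sizes[g]
        chrom = "chrY" if g in chry_genes else _AUTOSOMES[gi % len(_AUTOSOMES)]
        cur = cursors.get(chrom, 10_000)
        cur += int(rng.integers(1500, 5000))
        cgi = ["island", "shore", "shelf", "opensea"][int(rng.choice(4, p=cgi_probs))]
        for j in range(k):
            if j > 0:
                cur += int(rng.integers(50, 900))
            if j == 0:
                feature = "TSS200"
            elif j == 1:
                feature = "TSS1500"
            elif j == 2:
                feature = "1stExon"
            else:
                feature = str(rng.choice(feature_pool))
            rows.append((chrom, cur, g, feature, cgi))
        cursors[chrom] = cur

    ann = pd.DataFrame(rows, columns=["chrom", "pos", "genes", "feature", "cgi_relation"])
    ann = ann.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ann.index = pd.Index([f"cg{i + 1:06d}" for i in range(len(ann))], name="probe_id")

    n = len(ann)
    ann["design_type"] = np.where(rng.random(n) < cfg.frac_type2, "II", "I")
    ann["snp_overlap"] = rng.random(n) < cfg.frac_snp
    ann["multihit"] = rng.random(n) < cfg.frac_multihit
    # planted-region probes must survive probe QC, or the region could
    # never reach its probe count again
    if dmr_genes:
        in_region = ann["genes"].str.split(";").apply(
            lambda gs: any(g in dmr_sizes for g in gs)
        )
        ann.loc[in_region, ["snp_overlap", "multihit"]] = False
    # a small share of probes annotate to two genes
    multi = rng.random(n) < 0.02
    second = rng.choice(genes, size=n)
    ann.loc[multi, "genes"] = ann.loc[multi, "genes"] + ";" + second[multi]
    ann = ann[["chrom", "pos", "genes", "feature", "cgi_relation",
               "design_type", "snp_overlap", "multihit"]]
    return validate_annotation(ann)


def draw_baselines(ann: pd.DataFrame, rng: np.random.Generator) -> pd.Series:
    """Per-probe baseline M from the design-type-specific trimodal mixture."""
    n = len(ann)
    states = rng.choice(3, size=n, p=_STATE_PROBS)
    modes = np.where(ann["design_type"].to_numpy() == "I",
                     _MODES_TYPE1[states], _MODES_TYPE2[states])
    return pd.Series(modes + rng.normal(0, 0.3, n), index=ann.index, name="baseline_m")


# ---------------------------------------------------------------------------
# planting


def _eligible_probes(ann: pd.DataFrame) -> pd.Index:
    ok = (ann["chrom"] != "chrY") & ~ann["snp_overlap"] & ~ann["multihit"]
    return ann.index[ok]


def plant_effects(cfg: SimulationConfig, ann: pd.DataFrame, rng: np.random.Generator) -> Truth:
    """Choose planted DMP probes and planted regions, with directions."""
    probe_rows = []
    region_rows = []
    taken: set[str] = set()
    for ri, (gene, k, direction) in enumerate(cfg.dmr_spec):
        member = ann.index[ann["genes"].str.split(";").apply(lambda gs: gene in gs)]
        member = member[:k]
        if len(member) < k:
            raise ValueError(f"gene {gene} has fewer than {k} probes")
        sub = ann.loc[member].sort_values(["chrom", "pos"])
        region_id = f"dmr{ri + 1:03d}"
        region_rows.append((region_id, gene, sub["chrom"].iloc[0],
                            int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]),
                            len(sub), direction, ";".join(sub.index)))
        for pid in sub.index:
            probe_rows.append((pid, gene, direction, "dmr", region_id))
            taken.add(pid)

    n_dmp = int(round(cfg.frac_dmp * cfg.n_probes))
    if n_dmp < 1 and not cfg.dmr_spec and not cfg.allow_null:
        raise ValueError("no effects to plant (set allow_null=True for a null simulation)")
    pool = [p for p in _eligible_probes(ann) if p not in taken]
    chosen = rng.choice(pool, size=min(n_dmp, len(pool)), replace=False) if n_dmp else []
    for pid in chosen:
        direction = 1 if rng.random() < 0.5 else -1
        gene = ann.at[pid, "genes"].split(";")[0]
        probe_rows.append((pid, gene, direction, "dmp", ""))

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene", "direction", "kind", "region_id"])
    regions = pd.DataFrame(region_rows, columns=["region_id", "gene", "chrom", "start",
                                                 "end", "n_probes", "direction", "probe_ids"])
    return Truth(probes=probes, regions=regions)


def signed_delta(ann: pd.DataFrame, truth: Truth, effect_delta: float) -> pd.Series:
    """Per-probe signed M-scale shift applied to case samples."""
    delta = pd.Series(0.0, index=ann.index)
    if len(truth.probes):
        delta.loc[truth.probes["probe_id"].to_numpy()] = (
            truth.probes["direction"].to_numpy(dtype=float) * effect_delta
        )
    return delta


# ---------------------------------------------------------------------------
# matrices


def generate_dataset(
    ann: pd.DataFrame,
    baseline_m: pd.Series,
    delta: pd.Series,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    dataset_id: str,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> BetaMatrix:
    """One case/control dataset from shared baselines and a signed shift."""
    n_cases = cfg.n_cases if n_cases is None else n_cases
    n_controls = cfg.n_controls if n_controls is None else n_controls
    n_probes, n = len(ann), n_cases + n_controls
    m = baseline_m.to_numpy()[:, None] + rng.normal(0, cfg.noise_sd, (n_probes, n))
    m[:, :n_cases] += delta.to_numpy()[:, None]
    beta = m_to_beta(m)

    sample_ids = [f"{dataset_id}_case{i + 1:03d}" for i in range(n_cases)] + [
        f"{dataset_id}_ctrl{i + 1:03d}" for i in range(n_controls)
    ]
    sheet = pd.DataFrame(
        {
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "dataset_id": dataset_id,
            "age": np.round(np.clip(rng.normal(52, 12, n), 18, 90), 1),
            "sex": rng.choice(["F", "M"], size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    detp = rng.uniform(0, 0.005, (n_probes, n))
    fail = rng.random((n_probes, n)) < cfg.detection_fail_rate
    detp[fail] = rng.uniform(0.02, 0.6, fail.sum())
    beads = rng.poisson(11, (n_probes, n)) + 3
    low = rng.random((n_probes, n)) < cfg.beadcount_low_rate
    beads[low] = rng.integers(1, 3, low.sum())

    idx, cols = ann.index, pd.Index(sample_ids)
    return BetaMatrix(
        values=pd.DataFrame(beta, index=idx, columns=cols),
        sample_sheet=sheet,
        detection_p=pd.DataFrame(detp, index=idx, columns=cols),
        beadcount=pd.DataFrame(beads, index=idx, columns=cols),
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full single-disease study: datasets, annotation, truth."""
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(3 + cfg.n_datasets)
    ann = make_annotation(cfg, np.random.default_rng(seeds[0]))
    baseline = draw_baselines(ann, np.random.default_rng(seeds[1]))
    truth = plant_effects(cfg, ann, np.random.default_rng(seeds[2]))
    delta = signed_delta(ann, truth, cfg.effect_delta)
    datasets = {}
    for d in range(cfg.n_datasets):
        ds_id = f"ds{d + 1}"
        datasets[ds_id] = generate_dataset(
            ann, baseline, delta, cfg, np.random.default_rng(seeds[3 + d]), ds_id
        )
    return SimulatedStudy(datasets=datasets, annotation=ann, truth=truth, baseline_m=baseline)


# ---------------------------------------------------------------------------
# cross-disease wrapper


@dataclass
class CrossDiseaseStudy:
    """Three diseases sharing one annotation, with per-disease truth.

    ``site_truth`` has one row per planted cross-compare probe with the
    signed direction in each disease and the planted category
    (similarity: all three agree; difference: exactly one opposite).
    """

    datasets: dict[str, dict[str, BetaMatrix]]  # disease -> dataset -> matrix
    annotation: pd.DataFrame
    site_truth: pd.DataFrame
    region_truth: pd.DataFrame
    truths: dict[str, Truth]


def simulate_cross_disease(
    cfg: SimulationConfig,
    diseases: Sequence[str] = ("SLE", "RA", "pSS"),
    n_datasets: dict[str, int] | None = None,
    n_cases: dict[str, int] | None = None,
    n_controls: dict[str, int] | None = None,
    n_similarity: int = 40,
    n_difference: int = 30,
    n_specific: int = 15,
    shared_dmrs: Sequence[tuple[str, int, str]] = (),  # (gene, n_probes, 'similarity'|'difference')
) -> CrossDiseaseStudy:
    """Three-disease study with planted concordant and discordant sites.

    Mirrors the study design the pipeline targets: one disease (the first)
    spans several constituent datasets to be meta-analyzed, the others one
    dataset each. Similarity sites share one direction across all three
    diseases; difference sites flip the direction in exactly one disease,
    rotated round-robin.
    """
    if n_datasets is None:
        n_datasets = {d: (3 if i == 0 else 1) for i, d in enumerate(diseases)}
    if n_cases is None:
        n_cases = {d: cfg.n_cases for d in diseases}
    if n_controls is None:
        n_controls = {d: cfg.n_controls for d in diseases}

    dmr_spec = [(g, k, 1) for g, k, _ in shared_dmrs]
    cfg = SimulationConfig(**{**cfg.__dict__, "dmr_spec": tuple(dmr_spec)})
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(4)
    ann = make_annotation(cfg, np.random.default_rng(seeds[0]))
    baseline = draw_baselines(ann, np.random.default_rng(seeds[1]))
    rng = np.random.default_rng(seeds[2])

    region_template = plant_effects(
        SimulationConfig(**{**cfg.__dict__, "frac_dmp": 0.0, "allow_null": True}), ann, rng
    )
    dmr_probe_ids = set(region_template.probes["probe_id"])

    pool = [p for p in _eligible_probes(ann) if p not in dmr_probe_ids]
    n_sites = n_similarity + n_difference + n_specific * len(diseases)
    if n_sites > len(pool):
        raise ValueError("not enough eligible probes for the requested planting")
    chosen = rng.choice(pool, size=n_sites, replace=False)
    sim_sites = chosen[:n_similarity]
    diff_sites = chosen[n_similarity:n_similarity + n_difference]
    spec_sites = chosen[n_similarity + n_difference:]

    site_rows = []
    for pid in sim_sites:
        d0 = 1 if rng.random() < 0.5 else -1
        site_rows.append((pid, "similarity", *[d0] * len(diseases)))
    for i, pid in enumerate(diff_sites):
        d0 = 1 if rng.random() < 0.5 else -1
        dirs = [d0] * len(diseases)
        dirs[i % len(diseases)] = -d0  # the odd one out, rotated
        site_rows.append((pid, "difference", *dirs))
    for i, pid in enumerate(spec_sites):
        dirs = [0] * len(diseases)
        dirs[i % len(diseases)] = 1 if rng.random() < 0.5 else -1
        site_rows.append((pid, "specific", *dirs))
    site_truth = pd.DataFrame(
        site_rows, columns=["probe_id", "category", *[f"dir_{d}" for d in diseases]]
    )

    region_rows = []
    for (gene, k, category), (_, row) in zip(shared_dmrs, region_template.regions.iterrows()):
        d0 = -1  # shared regions planted hypomethylated by default
        dirs = [d0] * len(diseases)
        if category == "difference":
            dirs[len(region_rows) % len(diseases)] = -d0
        region_rows.append((row["region_id"], gene, row["chrom"], row["start"], row["end"],
                            row["n_probes"], row["probe_ids"], category, *dirs))
    region_truth = pd.DataFrame(
        region_rows,
        columns=["region_id", "gene", "chrom", "start", "end", "n_probes", "probe_ids",
                 "category", *[f"dir_{d}" for d in diseases]],
    )

    ds_seeds = np.random.SeedSequence(cfg.rng_seed + 1).spawn(sum(n_datasets.values()))
    seed_iter = iter(ds_seeds)
    datasets: dict[str, dict[str, BetaMatrix]] = {}
    truths: dict[str, Truth] = {}
    for di, disease in enumerate(diseases):
        delta = pd.Series(0.0, index=ann.index)
        delta.loc[site_truth["probe_id"].to_numpy()] = (
            site_truth[f"dir_{disease}"].to_numpy(dtype=float) * cfg.effect_delta
        )
        probe_rows = []
        for _, row in region_truth.iterrows():
            for pid in row["probe_ids"].split(";"):
                delta.at[pid] = row[f"dir_{disease}"] * cfg.effect_delta
                probe_rows.append((pid, row["gene"], row[f"dir_{disease}"], "dmr", row["region_id"]))
        active = site_truth[site_truth[f"dir_{disease}"] != 0]
        for _, row in active.iterrows():
            gene = ann.at[row["probe_id"], "genes"].split(";")[0]
            probe_rows.append((row["probe_id"], gene, row[f"dir_{disease}"], "dmp", ""))
        truths[disease] = Truth(
            probes=pd.DataFrame(probe_rows, columns=["probe_id", "gene", "direction",
                                                     "kind", "region_id"]),
            regions=region_truth.rename(columns={f"dir_{disease}": "direction"})[
                ["region_id", "gene", "chrom", "start", "end", "n_probes", "direction", "probe_ids"]
            ],
        )
        datasets[disease] = {}
        for d in range(n_datasets[disease]):
            ds_id = f"{disease}_ds{d + 1}"
            datasets[disease][ds_id] = generate_dataset(
                ann, baseline, delta, cfg, np.random.default_rng(next(seed_iter)), ds_id,
                n_cases=n_cases[disease], n_controls=n_controls[disease],
            )
    return CrossDiseaseStudy(datasets=datasets, annotation=ann, site_truth=site_truth,
                             region_truth=region_truth, truths=truths)


# ---------------------------------------------------------------------------
# auxiliary inputs


def cytokine_gene_list(ann: pd.DataFrame) -> pd.DataFrame:
    """The full synthetic gene universe as a cytokine gene list TSV frame."""
    genes = sorted({g for gs in ann["genes"] for g in gs.split(";") if g})
    return pd.DataFrame({"gene": genes, "description": [f"synthetic cytokine gene {g}" for g in genes]})


def simulate_ppi(cfg: SimulationConfig, truth: Truth, ann: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Erdos-Renyi PPI over gene symbols with a planted dense module.

    The planted module members are genes carrying planted effects (so that
    their gene-level statistics are large); they are wired as a random
    spanning tree plus dense extra edges, guaranteeing connectivity.
    Returns the edge list and the planted module gene list.
    """
    n_nodes, edge_prob, module_size = cfg.ppi_spec
    if not 0.0 < edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in (0, 1], got {edge_prob}")
    if module_size < 10:
        raise ValueError("planted_module_size must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(5)[4])

    effect_genes = sorted(set(truth.probes["gene"]))
    if len(effect_genes) < module_size:
        raise ValueError("not enough planted-effect genes for the module")
    module = list(rng.choice(effect_genes, size=module_size, replace=False))
    universe = sorted({g for gs in ann["genes"] for g in gs.split(";") if g})
    background_pool = [g for g in universe if g not in module]
    n_bg = min(n_nodes - module_size, len(background_pool))
    nodes = module + list(rng.choice(background_pool, size=n_bg, replace=False))

    edges: set[tuple[str, str]] = set()
    k = len(nodes)
    mask = rng.random((k, k)) < edge_prob
    for i in range(k):
        for j in range(i + 1, k):
            if mask[i, j]:
                edges.add(tuple(sorted((nodes[i], nodes[j]))))
    # planted module: spanning path over a random permutation + dense extras
    perm = list(rng.permutation(module))
    for a, b in zip(perm, perm[1:]):
        edges.add(tuple(sorted((a, b))))
    for i in range(module_size):
        for j in range(i + 1, module_size):
            if rng.random() < 0.8:
                edges.add(tuple(sorted((module[i], module[j]))))
    edge_df = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])
    return edge_df, sorted(module)


def simulate_gene_sets(
    ann: pd.DataFrame, truth: Truth, rng_seed: int = 0, n_random: int = 3
) -> dict[str, dict]:
    """GMT collection: one set enriched for planted-effect genes + random sets."""
    universe = sorted({g for gs in ann["genes"] for g in gs.split(";") if g})
    if not universe:
        raise ValueError("annotation has no genes")
    rng = np.random.default_rng(rng_seed)
    effect_genes = sorted(set(truth.probes["gene"]) & set(universe))
    n_eff = min(16, len(effect_genes))
    n_decoy = max(1, n_eff // 8)  # keeps the set >= 80% effect genes
    members = list(rng.choice(effect_genes, size=n_eff, replace=False))
    decoys = [g for g in universe if g not in members]
    members += list(rng.choice(decoys, size=min(n_decoy, len(decoys)), replace=False))
    sets = {"planted_set": {"description": "enriched for planted-effect genes",
                            "genes": sorted(members)}}
    size = max(5, n_eff)
    for i in range(n_random):
        sets[f"random_set_{i + 1}"] = {
            "description": "random background set",
            "genes": sorted(rng.choice(universe, size=min(size, len(universe)), replace=False)),
        }
    return sets
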
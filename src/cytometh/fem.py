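"""Functional-epigenetic-module (FEM) style hotspot detection.

Gene-level differential methylation statistics (signed t averaged over
promoter probes, TSS200 > 1stExon > TSS1500 priority) weight the edges of
a protein-protein interaction network; modules are grown greedily from
high-statistic seed genes and their significance is assessed by Monte
Carlo permutation of the gene statistics over the network nodes.

Edge weight: w_ij = (|t_i| + |t_j|) / 2, normalized by the maximum so
w in (0, 1]. Module score: total induced edge weight divided by the
number of member genes — an average edge weight per member, which
rewards modules that are both heavy and dense. Growth adds, at each
step, the neighboring gene giving the largest strict increase of the
score (deterministic tie-break by gene symbol) and stops when no
neighbor improves it or the size cap is reached.

The Monte Carlo null permutes the statistics over nodes, keeping the
graph fixed, recomputes edge weights (including the normalization),
regrows the module from the same seed and reports
p = (1 + #{permuted score >= observed}) / (n_mc + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import PROMOTER_FEATURES, split_genes


@dataclass
class FEMConfig:
    n_seeds: int = 100
    n_mc: int = 1000
    min_module_size: int = 10
    p_threshold: float = 0.05
    max_module_size: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_seeds", "n_mc", "min_module_size", "max_module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class NetworkModule:
    seed_gene: str
    members: list[str]  # includes the seed
    score: float
    mc_p: float | None = None
    member_stats: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_signs(self) -> dict[str, str]:
        """hyper/hypo per member by the sign of its gene statistic."""
        return {g: ("hyper" if s > 0 else "hypo" if s < 0 else "flat")
                for g, s in self.member_stats.items()}


def gene_level_stat(dmps: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Signed gene-level statistic from promoter probes.

    Per gene, the mean t statistic of its TSS200 probes; if the gene has
    none, its 1stExon probes; failing that, TSS1500 (priority cascade).
    Genes with only gene-body/UTR probes are absent from the output.
    Returns a frame indexed by gene with columns stat, n_probes_used,
    feature_source.
    """
    sub = ann.loc[ann.index.intersection(dmps.index)]
    records: dict[str, dict[str, list[float]]] = {}
    for pid, row in sub.iterrows():
        if row["feature"] not in PROMOTER_FEATURES:
            continue
        t = float(dmps.at[pid, "t_stat"])
        for gene in split_genes(row["genes"]):
            records.setdefault(gene, {}).setdefault(row["feature"], []).append(t)
    rows = []
    for gene in sorted(records):
        by_feature = records[gene]
        for feature in PROMOTER_FEATURES:
            if feature in by_feature:
                vals = by_feature[feature]
                rows.append((gene, float(np.mean(vals)), len(vals), feature))
                break
    return pd.DataFrame(
        rows, columns=["gene", "stat", "n_probes_used", "feature_source"]
    ).set_index("gene")


def weight_network(edges: pd.DataFrame, stats: pd.Series, min_nodes: int = 1) -> nx.Graph:
    """PPI graph restricted to genes with statistics, edges weighted.

    Edge weight (|t_i| + |t_j|) / 2 normalized by the maximum over the
    restricted graph. Node attribute ``stat`` carries the signed gene
    statistic. Raises if the restricted graph is empty.
    """
    have = set(stats.index)
    g = nx.Graph()
    for _, row in edges.iterrows():
        u, v = row.iloc[0], row.iloc[1]
        if u == v or u not in have or v not in have:
            continue
        g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError("no PPI edge connects two genes with statistics")
    if g.number_of_nodes() < min_nodes:
        raise ValueError("restricted graph smaller than the minimum module size")
    absstat = stats.abs()
    raw = {(u, v): (absstat[u] + absstat[v]) / 2 for u, v in g.edges}
    max_w = max(raw.values())
    for (u, v), w in raw.items():
        g.edges[u, v]["weight"] = w / max_w if max_w > 0 else 1.0
    nx.set_node_attributes(g, stats.to_dict(), "stat")
    return g


# -- internal fast representation -------------------------------------------


class _FastGraph:
    """Index-based adjacency used by growth and permutation loops."""

    def __init__(self, g: nx.Graph):
        self.nodes = sorted(g.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.adj: list[list[int]] = [[] for _ in self.nodes]
        self.edges: list[tuple[int, int]] = []
        for u, v in g.edges:
            iu, iv = self.index[u], self.index[v]
            self.adj[iu].append(iv)
            self.adj[iv].append(iu)
            self.edges.append((iu, iv))
        self.abs_stat = np.array(
            [abs(g.nodes[n]["stat"]) for n in self.nodes], dtype=float
        )

    def max_raw_weight(self, abs_stat: np.ndarray) -> float:
        return max((abs_stat[u] + abs_stat[v]) / 2 for u, v in self.edges)


def _grow(fg: _FastGraph, seed_idx: int, abs_stat: np.ndarray, max_size: int) -> tuple[list[int], float]:
    """Greedy growth on the index graph; returns (member indices, score)."""
    max_w = fg.max_raw_weight(abs_stat)
    if max_w <= 0:
        max_w = 1.0

    members = [seed_idx]
    in_module = {seed_idx}
    # gain[v] = total weight of edges from v into the current module
    gain: dict[int, float] = {}
    for v in fg.adj[seed_idx]:
        gain[v] = (abs_stat[seed_idx] + abs_stat[v]) / (2 * max_w)
    total = 0.0
    score = 0.0
    while len(members) < max_size and gain:
        # best candidate: highest resulting score (must strictly beat the
        # current score), ties broken by gene symbol order (= index order)
        best_v, best_score = -1, score
        for v in sorted(gain):
            cand = (total + gain[v]) / (len(members) + 1)
            if cand > best_score + 1e-12:
                best_v, best_score = v, cand
        if best_v < 0:
            break
        total += gain.pop(best_v)
        members.append(best_v)
        in_module.add(best_v)
        score = total / len(members)
        for v in fg.adj[best_v]:
            if v not in in_module:
                gain[v] = gain.get(v, 0.0) + (abs_stat[best_v] + abs_stat[v]) / (2 * max_w)
    return members, score


def grow_module(graph: nx.Graph, seed: str, cfg: FEMConfig | None = None) -> NetworkModule:
    """Grow one module from a seed gene (deterministic)."""
    cfg = cfg or FEMConfig()
    if seed not in graph:
        raise ValueError(f"seed {seed!r} not in graph")
    fg = _FastGraph(graph)
    members_idx, score = _grow(fg, fg.index[seed], fg.abs_stat, cfg.max_module_size)
    members = sorted(fg.nodes[i] for i in members_idx)
    return NetworkModule(
        seed_gene=seed, members=members, score=score,
        member_stats={m: graph.nodes[m]["stat"] for m in members},
    )


def mc_significance(
    graph: nx.Graph, module: NetworkModule, cfg: FEMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value of a module's score (add-one estimator)."""
    cfg = cfg or FEMConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    fg = _FastGraph(graph)
    seed_idx = fg.index[module.seed_gene]
    count = 0
    for _ in range(cfg.n_mc):
        perm = rng.permutation(fg.abs_stat)
        _, score = _grow(fg, seed_idx, perm, cfg.max_module_size)
        if score >= module.score - 1e-12:
            count += 1
    return (1 + count) / (cfg.n_mc + 1)


def find_hotspots(
    graph: nx.Graph, stats: pd.Series, cfg: FEMConfig | None = None
) -> list[NetworkModule]:
    """Seed at the top-|stat| genes, grow, permutation-test, deduplicate.

    Seeds already absorbed into an accepted module are skipped. Modules
    smaller than ``min_module_size`` or with mc_p >= p_threshold are
    discarded; two accepted modules sharing >= 50% of the smaller one's
    members are merged by keeping the better-scoring one.
    """
    cfg = cfg or FEMConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    in_graph = [g for g in stats.index if g in graph]
    ranked = sorted(in_graph, key=lambda g: (-abs(stats[g]), g))
    seeds = ranked[: min(cfg.n_seeds, len(ranked))]

    accepted: list[NetworkModule] = []
    absorbed: set[str] = set()
    for seed in seeds:
        if seed in absorbed:
            continue
        module = grow_module(graph, seed, cfg)
        if module.size < cfg.min_module_size:
            continue
        module.mc_p = mc_significance(graph, module, cfg, rng)
        if module.mc_p >= cfg.p_threshold:
            continue
        overlap = None
        for prev in accepted:
            shared = len(set(prev.members) & set(module.members))
            if shared / min(prev.size, module.size) >= 0.5:
                overlap = prev
                break
        if overlap is None:
            accepted.append(module)
            absorbed |= set(module.members)
        elif module.score > overlap.score:
            accepted[accepted.index(overlap)] = module
            absorbed |= set(module.members)
    return sorted(accepted, key=lambda m: (m.mc_p, -m.score))
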
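"""FEM hotspot detection: gene stats, edge weights, growth, Monte Carlo."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cytometh.fem import (
    FEMConfig,
    find_hotspots,
    gene_level_stat,
    grow_module,
    mc_significance,
    weight_network,
)


def _ann(rows):
    """rows: (probe, gene, feature)"""
    return pd.DataFrame(
        {
            "chrom": "chr1", "pos": range(1, len(rows) + 1),
            "genes": [g for _, g, _ in rows],
            "feature": [f for _, _, f in rows],
            "cgi_relation": "island", "design_type": "II",
            "snp_overlap": False, "multihit": False,
        },
        index=pd.Index([p for p, _, _ in rows], name="probe_id"),
    )


def _dmps(stats):
    return pd.DataFrame({"t_stat": list(stats.values())},
                        index=pd.Index(stats.keys(), name="probe_id"))


def test_gene_stat_priority_cascade():
    ann = _ann([
        ("p1", "A", "TSS200"), ("p2", "A", "TSS200"), ("p3", "A", "1stExon"),
        ("p4", "B", "1stExon"), ("p5", "B", "TSS1500"),
        ("p6", "C", "TSS1500"),
        ("p7", "D", "Body"),
    ])
    stats = gene_level_stat(_dmps({"p1": 2.0, "p2": 4.0, "p3": 99.0, "p4": -2.5,
                                   "p5": 99.0, "p6": 1.5, "p7": 9.0}), ann)
    assert stats.loc["A", "stat"] == 3.0 and stats.loc["A", "feature_source"] == "TSS200"
    assert stats.loc["B", "stat"] == -2.5 and stats.loc["B", "feature_source"] == "1stExon"
    assert stats.loc["C", "feature_source"] == "TSS1500"
    assert "D" not in stats.index  # body-only genes absent, not zero-filled


def _edges(pairs):
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def test_weight_network_formula_and_restriction():
    stats = pd.Series({"A": 1.0, "B": -3.0, "C": 2.0})
    g = weight_network(_edges([("A", "B"), ("B", "C"), ("C", "Z")]), stats)
    assert "Z" not in g  # no statistic -> removed with incident edges
    # raw weights: AB = 2.0, BC = 2.5 -> normalized 0.8, 1.0
    assert g.edges["A", "B"]["weight"] == pytest.approx(0.8)
    assert g.edges["B", "C"]["weight"] == pytest.approx(1.0)


def test_weight_network_all_equal_stats():
    stats = pd.Series({"A": 2.0, "B": -2.0, "C": 2.0})
    g = weight_network(_edges([("A", "B"), ("B", "C")]), stats)
    assert all(d["weight"] == 1.0 for _, _, d in g.edges(data=True))


def test_weight_network_empty_raises():
    with pytest.raises(ValueError):
        weight_network(_edges([("X", "Y")]), pd.Series({"A": 1.0}))


def _star_graph():
    stats = {"CTR": 10.0, **{f"L{i}": 10.0 for i in range(5)}, "B1": 0.1, "B2": 0.1}
    pairs = [("CTR", f"L{i}") for i in range(5)] + [("CTR", "B1"), ("CTR", "B2")]
    g = weight_network(_edges(pairs), pd.Series(stats))
    return g, stats


def module_score(g, members):
    sub = g.subgraph(members)
    return sum(d["weight"] for _, _, d in sub.edges(data=True)) / len(members)


def test_grow_module_star_matches_bruteforce():
    g, _ = _star_graph()
    got = grow_module(g, "CTR", FEMConfig())
    # oracle: best-scoring connected subgraph containing the seed, by
    # exhaustive enumeration over all node subsets of this toy graph
    best, best_score = None, -1.0
    nodes = [n for n in g.nodes if n != "CTR"]
    for r in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            members = {"CTR", *combo}
            if not nx.is_connected(g.subgraph(members)):
                continue
            s = module_score(g, members)
            if s > best_score:
                best, best_score = members, s
    assert set(got.members) == best == {"CTR", "L0", "L1", "L2", "L3", "L4"}
    assert got.score == pytest.approx(best_score) == pytest.approx(5 / 6)


def test_grow_module_deterministic():
    g, _ = _star_graph()
    a = grow_module(g, "CTR")
    b = grow_module(g, "CTR")
    assert a.members == b.members and a.score == b.score


def test_grow_module_isolated_seed_and_relabeling():
    stats = pd.Series({"A": 5.0, "B": 3.0, "C": 1.0, "D": 4.0})
    g = weight_network(_edges([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]), stats)
    m = grow_module(g, "A")
    # relabeled graph (distinct stats -> no tie-break ambiguity)
    mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
    g2 = weight_network(
        _edges([(mapping[u], mapping[v]) for u, v in [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]]),
        pd.Series({mapping[k]: v for k, v in stats.items()}),
    )
    m2 = grow_module(g2, "W")
    assert sorted(mapping[x] for x in m.members) == sorted(m2.members)
    assert m.score == pytest.approx(m2.score)


def test_mc_identical_stats_give_p_one():
    stats = pd.Series({"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0})
    g = weight_network(_edges([("A", "B"), ("B", "C"), ("C", "D")]), stats)
    m = grow_module(g, "B")
    p = mc_significance(g, m, FEMConfig(n_mc=100, rng_seed=0))
    assert p == 1.0


def test_mc_p_lower_bound():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(12)]
    pairs = [(genes[i], genes[j]) for i in range(12) for j in range(i + 1, 12)
             if rng.random() < 0.5]
    stats = pd.Series(rng.normal(0, 1, 12), index=genes)
    stats[genes[0]] = 8.0
    g = weight_network(_edges(pairs), stats)
    m = grow_module(g, genes[0])
    p = mc_significance(g, m, FEMConfig(n_mc=1000, rng_seed=1))
    assert 1 / 1001 <= p <= 1.0


def test_find_hotspots_seed_truncation_and_min_size():
    stats = pd.Series({"A": 5.0, "B": 4.0, "C": 3.0})
    g = weight_network(_edges([("A", "B"), ("B", "C")]), stats)
    # n_seeds exceeds node count -> truncated, no error; tiny modules dropped
    out = find_hotspots(g, stats, FEMConfig(n_seeds=50, n_mc=20, min_module_size=10))
    assert out == []
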
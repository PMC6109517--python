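"""Generator sanity: determinism, planted effects, PPI and gene sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytometh.containers import m_to_beta, validate_annotation
from cytometh.simulate import (
    SimulationConfig,
    cytokine_gene_list,
    simulate_cross_disease,
    simulate_gene_sets,
    simulate_ppi,
    simulate_study,
)


def test_seeded_determinism():
    cfg = SimulationConfig(n_probes=200, n_genes=40, rng_seed=5)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a.datasets["ds1"].values, b.datasets["ds1"].values)
    pd.testing.assert_frame_equal(a.annotation, b.annotation)
    pd.testing.assert_frame_equal(a.truth.probes, b.truth.probes)


def test_annotation_schema_and_layout(small_study):
    _, study = small_study
    ann = validate_annotation(study.annotation)
    # every gene cluster starts with a TSS200 probe -> promoter stats exist
    first = ann.sort_values(["chrom", "pos"]).groupby(
        ann["genes"].str.split(";").str[0]
    )["feature"].first()
    assert (first == "TSS200").all()


def test_planted_regions_are_tight_runs(small_study):
    _, study = small_study
    ann = study.annotation
    for _, reg in study.truth.regions.iterrows():
        pids = reg["probe_ids"].split(";")
        pos = ann.loc[pids].sort_values("pos")["pos"].to_numpy()
        assert (np.diff(pos) < 1000).all()
        assert ann.loc[pids, "chrom"].nunique() == 1


def test_null_simulation_has_no_realized_effect():
    cfg = SimulationConfig(n_probes=300, n_genes=60, frac_dmp=0.05,
                           effect_delta=0.0, n_cases=50, n_controls=50, rng_seed=3)
    study = simulate_study(cfg)
    bm = study.datasets["ds1"]
    case = bm.values[bm.samples_in_group("case")].to_numpy()
    ctrl = bm.values[bm.samples_in_group("control")].to_numpy()
    planted = study.truth.probes["probe_id"].to_numpy()
    rows = bm.values.index.get_indexer(planted)
    d = case[rows].mean(axis=1) - ctrl[rows].mean(axis=1)
    se = np.sqrt(case[rows].var(axis=1, ddof=1) / case.shape[1]
                 + ctrl[rows].var(axis=1, ddof=1) / ctrl.shape[1])
    assert (np.abs(d) < 3 * se).mean() > 0.95


def test_effect_delta_matches_logistic_closed_form():
    """A 1 M-unit shift at baseline M=0 yields delta-beta ~ 2/(2+1) - 1/2."""
    from cytometh.simulate import generate_dataset

    cfg = SimulationConfig(n_probes=50, n_genes=10, n_cases=400, n_controls=400,
                           noise_sd=0.2, rng_seed=9)
    study = simulate_study(SimulationConfig(n_probes=50, n_genes=10, rng_seed=9))
    ann = study.annotation
    baseline = pd.Series(0.0, index=ann.index)
    delta = pd.Series(1.0, index=ann.index)
    bm = generate_dataset(ann, baseline, delta, cfg, np.random.default_rng(1), "ds1")
    case = bm.values[bm.samples_in_group("case")].to_numpy().mean()
    ctrl = bm.values[bm.samples_in_group("control")].to_numpy().mean()
    assert abs((case - ctrl) - (2 / 3 - 1 / 2)) < 0.01


def test_no_effects_to_plant_raises():
    with pytest.raises(ValueError, match="no effects"):
        simulate_study(SimulationConfig(n_probes=100, n_genes=20, frac_dmp=0.0))
    # explicit null simulation is allowed
    study = simulate_study(SimulationConfig(n_probes=100, n_genes=20, frac_dmp=0.0,
                                            allow_null=True))
    assert study.truth.probes.empty


@given(st.floats(min_value=-30, max_value=30))
@settings(deadline=None, max_examples=50)
def test_m_to_beta_in_unit_interval_and_monotone(m):
    b = m_to_beta(np.array([m, m + 0.1]))
    assert 0 < b[0] < 1
    assert b[1] > b[0]


# -- PPI -------------------------------------------------------------------


def test_ppi_complete_graph_and_determinism(small_study):
    cfg, study = small_study
    cfg5 = SimulationConfig(**{**cfg.__dict__, "ppi_spec": (15, 1.0, 12)})
    edges, module = simulate_ppi(cfg5, study.truth, study.annotation)
    n = len(set(edges["gene_a"]) | set(edges["gene_b"]))
    assert len(edges) == n * (n - 1) // 2  # complete graph
    edges2, module2 = simulate_ppi(cfg5, study.truth, study.annotation)
    pd.testing.assert_frame_equal(edges, edges2)
    assert module == module2


def test_ppi_planted_module_connected(small_study):
    import networkx as nx

    cfg, study = small_study
    edges, module = simulate_ppi(cfg, study.truth, study.annotation)
    g = nx.from_pandas_edgelist(edges, "gene_a", "gene_b")
    assert nx.is_connected(g.subgraph(module))
    assert set(module) <= set(study.truth.probes["gene"])


def test_ppi_bad_edge_prob(small_study):
    cfg, study = small_study
    bad = SimulationConfig(**{**cfg.__dict__, "ppi_spec": (50, 0.0, 12)})
    with pytest.raises(ValueError, match="edge_prob"):
        simulate_ppi(bad, study.truth, study.annotation)


# -- gene sets -------------------------------------------------------------


def test_gene_sets_planted_enrichment_and_determinism(small_study):
    _, study = small_study
    sets = simulate_gene_sets(study.annotation, study.truth, rng_seed=2)
    effect = set(study.truth.probes["gene"])
    planted = sets["planted_set"]["genes"]
    assert sum(g in effect for g in planted) / len(planted) >= 0.8
    for entry in sets.values():
        assert len(entry["genes"]) == len(set(entry["genes"]))  # no duplicates
    universe = set(cytokine_gene_list(study.annotation)["gene"])
    assert all(set(e["genes"]) <= universe for e in sets.values())
    assert sets == simulate_gene_sets(study.annotation, study.truth, rng_seed=2)
    assert len(sets) >= 3


# -- cross-disease ---------------------------------------------------------


def test_cross_disease_truth_structure():
    cfg = SimulationConfig(n_probes=400, n_genes=80, frac_dmp=0.0, allow_null=True,
                           n_cases=5, n_controls=5, rng_seed=4)
    study = simulate_cross_disease(cfg, n_similarity=10, n_difference=6, n_specific=3)
    truth = study.site_truth
    sim = truth[truth["category"] == "similarity"]
    assert (sim["dir_SLE"] == sim["dir_RA"]).all() and (sim["dir_RA"] == sim["dir_pSS"]).all()
    diff = truth[truth["category"] == "difference"]
    dirs = diff[["dir_SLE", "dir_RA", "dir_pSS"]].to_numpy()
    assert (np.abs(dirs.sum(axis=1)) == 1).all()  # exactly one disease flips
    assert set(study.datasets) == {"SLE", "RA", "pSS"}
    assert len(study.datasets["SLE"]) == 3 and len(study.datasets["RA"]) == 1
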
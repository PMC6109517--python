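"""DMR clustering: gap rule, minimum size, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from cytometh.dmr import DMRConfig, call_dmrs, dmrs_to_bed


def _inputs(positions, chroms=None, deltas=None, pvals=None):
    n = len(positions)
    probes = pd.Index([f"cg{i:03d}" for i in range(n)], name="probe_id")
    ann = pd.DataFrame(
        {
            "chrom": chroms or ["chr1"] * n,
            "pos": positions,
            "genes": "G",
            "feature": "Body",
            "cgi_relation": "island",
            "design_type": "II",
            "snp_overlap": False,
            "multihit": False,
        },
        index=probes,
    )
    dmps = pd.DataFrame(
        {
            "delta_beta": deltas if deltas is not None else [0.1] * n,
            "p": pvals if pvals is not None else [1e-4] * n,
        },
        index=probes,
    )
    dmps["flag"] = np.where(dmps["delta_beta"] > 0, "HyperM",
                            np.where(dmps["delta_beta"] < 0, "HypoM", "none"))
    return dmps, ann


def cluster_bruteforce(chroms, positions, max_gap, min_probes):
    """O(n^2) oracle: probes i, j belong to one region iff a chain of
    probes on the same chromosome links them with every step <= max_gap."""
    n = len(positions)
    linked = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            linked[i, j] = (
                chroms[i] == chroms[j] and abs(positions[i] - positions[j]) <= max_gap
            )
    # transitive closure
    for k in range(n):
        for i in range(n):
            if linked[i, k]:
                linked[i] |= linked[k]
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = sorted(j for j in range(n) if linked[i, j])
        seen |= set(comp)
        if len(comp) >= min_probes:
            clusters.append(comp)
    return clusters


def test_single_run_within_gap():
    dmps, ann = _inputs([100, 600, 1100, 1600, 2100])
    out = call_dmrs(dmps, ann)
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["start"], row["end"], row["n_probes"]) == (100, 2100, 5)
    assert row["direction"] == "HyperM"


def test_large_gap_splits_runs():
    dmps, ann = _inputs([100, 600, 2101, 2600, 3100])
    assert len(call_dmrs(dmps, ann)) == 0  # clusters of 2 and 3 < 5 probes
    out = call_dmrs(dmps, ann, DMRConfig(min_probes=3))
    assert len(out) == 1 and out.iloc[0]["n_probes"] == 3


def test_four_probes_no_region():
    dmps, ann = _inputs([100, 600, 1100, 1600])
    assert len(call_dmrs(dmps, ann)) == 0


def test_unsorted_input_raises():
    dmps, ann = _inputs([2100, 100, 600, 1100, 1600])
    with pytest.raises(ValueError, match="sorted"):
        call_dmrs(dmps, ann)


def test_mixed_direction_region():
    dmps, ann = _inputs([100, 600, 1100, 1600, 2100],
                        deltas=[0.1, 0.1, -0.1, 0.1, 0.1])
    out = call_dmrs(dmps, ann)
    assert out.iloc[0]["direction"] == "mixed"


def test_regions_disjoint_ordered_members_subset():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 60000, 7), size=40, replace=False))
    dmps, ann = _inputs(list(pos))
    out = call_dmrs(dmps, ann, DMRConfig(min_probes=2))
    prev_end = -1
    members = []
    for _, row in out.iterrows():
        assert row["start"] > prev_end
        prev_end = row["end"]
        members += row["probe_ids"].split(";")
    assert set(members) <= set(dmps.index)
    assert len(members) == len(set(members))


@pytest.mark.parametrize("seed", range(25))
def test_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 50))
    chroms = sorted(rng.choice(["chr1", "chr2"], size=n))
    positions = []
    used = {c: set() for c in ("chr1", "chr2")}
    for c in chroms:
        while True:
            p = int(rng.integers(1, 20000))
            if p not in used[c]:
                used[c].add(p)
                positions.append(p)
                break
    order = np.lexsort((positions, chroms))
    chroms = [chroms[i] for i in order]
    positions = [positions[i] for i in order]
    dmps, ann = _inputs(positions, chroms=chroms)
    out = call_dmrs(dmps, ann, DMRConfig(min_probes=2))
    expected = cluster_bruteforce(chroms, positions, 1000, 2)
    got = [sorted(dmps.index.get_indexer(r["probe_ids"].split(";")))
           for _, r in out.iterrows()]
    assert sorted(map(tuple, got)) == sorted(map(tuple, expected))


def test_region_p_and_bed_conversion():
    dmps, ann = _inputs([100, 600, 1100, 1600, 2100],
                        pvals=[1e-6, 1e-5, 1e-4, 1e-6, 1e-5])
    out = call_dmrs(dmps, ann)
    assert 0 < out.iloc[0]["region_p"] < 1e-6  # concordant evidence strengthens
    assert out.iloc[0]["region_adj_p"] >= out.iloc[0]["region_p"]
    bed = dmrs_to_bed(out)
    assert bed.iloc[0]["start"] == 99 and bed.iloc[0]["end"] == 2100
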
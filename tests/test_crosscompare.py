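"""Shared-site identification, flag classification, cross-disease ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cytometh.crosscompare import (
    anova_across,
    cgi_context,
    classify,
    classify_sites,
    find_shared,
    shared_dmrs,
)

from conftest import make_beta_matrix


def _ann(probe_ids, cgi):
    return pd.DataFrame(
        {"cgi_relation": cgi, "chrom": "chr1",
         "pos": range(1, len(probe_ids) + 1)},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def test_find_shared_examples():
    ann = _ann(list("abcd"), ["island", "shore", "opensea", "shelf"])
    out = find_shared({"d1": {"a", "b", "c"}, "d2": {"b", "c", "d"}, "d3": {"c", "b"}}, ann)
    assert list(out.index) == ["b", "c"]
    assert list(out["cgi_context"]) == ["neighbor", "opensea"]
    empty = find_shared({"d1": {"a"}, "d2": {"b"}, "d3": {"c"}}, ann)
    assert empty.empty  # disjoint sets are not an error


def classify_oracle(flags):
    """Exhaustive rule restatement used as the independent oracle."""
    if any(f == "none" for f in flags):
        return "other"
    hyper = [f == "HyperM" for f in flags]
    if all(hyper) or not any(hyper):
        return "similarity"
    if sum(hyper) in (1, 2):
        return "difference"
    return "other"


def test_classify_matches_27_triple_oracle():
    cats = {"similarity": 0, "difference": 0, "other": 0}
    for triple in itertools.product(["HyperM", "HypoM", "none"], repeat=3):
        got = classify(triple)
        assert got == classify_oracle(triple), triple
        cats[got] += 1
    # partition is total and disjoint over the 27-triple space
    assert sum(cats.values()) == 27
    assert cats["similarity"] == 2   # all-HyperM, all-HypoM
    assert cats["difference"] == 6   # 2 sign patterns x 3 positions
    assert cats["other"] == 19


def test_classify_paper_style_examples():
    assert classify(("HypoM", "HypoM", "HypoM")) == "similarity"
    assert classify(("HyperM", "HypoM", "HyperM")) == "difference"
    assert classify(("HyperM", "none", "HyperM")) == "other"
    with pytest.raises(ValueError):
        classify(("HyperM", "HypoM", "weird"))


def test_classify_sites_joins_flags():
    ann = _ann(["a", "b"], ["island", "shore"])
    shared = find_shared({"d1": {"a", "b"}, "d2": {"a", "b"}, "d3": {"a", "b"}}, ann)
    recs = {
        "d1": pd.DataFrame({"flag": ["HypoM", "HyperM"]}, index=["a", "b"]),
        "d2": pd.DataFrame({"flag": ["HypoM", "HypoM"]}, index=["a", "b"]),
        "d3": pd.DataFrame({"flag": ["HypoM", "HypoM"]}, index=["a", "b"]),
    }
    out = classify_sites(shared, recs)
    assert out.loc["a", "category"] == "similarity"
    assert out.loc["b", "category"] == "difference"


def test_anova_textbook_oracle():
    groups = {
        "d1": pd.DataFrame([[1.0, 2.0, 3.0]], index=["site"]) / 10,
        "d2": pd.DataFrame([[2.0, 3.0, 4.0]], index=["site"]) / 10,
        "d3": pd.DataFrame([[6.0, 7.0, 8.0]], index=["site"]) / 10,
    }
    out = anova_across(groups, ["site"])
    # hand-computed sums of squares on (1,2,3),(2,3,4),(6,7,8):
    # grand mean 4, SSB = 3*(2-4)^2+3*(3-4)^2+3*(7-4)^2 = 42, SSW = 2+2+2 = 6
    # F = (42/2)/(6/6) = 21 (scale-invariant, so /10 does not change it)
    assert out.loc["site", "anova_F"] == pytest.approx(21.0)
    from scipy.stats import f as fdist

    assert out.loc["site", "anova_p"] == pytest.approx(fdist.sf(21.0, 2, 6))


def test_anova_scipy_cross_check():
    from scipy.stats import f_oneway

    rng = np.random.default_rng(0)
    data = {d: pd.DataFrame(rng.uniform(0, 1, (5, 6)),
                            index=[f"s{i}" for i in range(5)]) for d in "abc"}
    out = anova_across(data, [f"s{i}" for i in range(5)])
    for i in range(5):
        ref = f_oneway(*[data[d].iloc[i] for d in "abc"])
        assert out.iloc[i]["anova_F"] == pytest.approx(ref.statistic)
        assert out.iloc[i]["anova_p"] == pytest.approx(ref.pvalue)


def test_anova_degenerate_identical_values():
    groups = {d: pd.DataFrame([[0.5, 0.5, 0.5]], index=["s"]) for d in "abc"}
    out = anova_across(groups, ["s"])
    assert out.loc["s", "anova_F"] == 0.0
    assert out.loc["s", "anova_p"] == 1.0


def test_anova_null_calibration():
    rng = np.random.default_rng(7)
    sites = [f"s{i}" for i in range(1000)]
    data = {d: pd.DataFrame(rng.normal(0.5, 0.05, (1000, 10)).clip(0, 1), index=sites)
            for d in "abc"}
    out = anova_across(data, sites)
    frac = (out["anova_p"] < 0.05).mean()
    # 99% binomial bounds around 0.05 at n=1000
    assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 1000)


def test_shared_dmrs_interval_overlap():
    mk = lambda rows: pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction"],
        index=pd.Index([f"r{i}" for i in range(len(rows))], name="region_id"),
    )
    a = mk([("chr1", 100, 500, "HypoM"), ("chr2", 100, 200, "HyperM")])
    b = mk([("chr1", 400, 900, "HypoM")])
    c = mk([("chr1", 450, 460, "HypoM"), ("chr1", 5000, 6000, "HyperM")])
    out = shared_dmrs({"d1": a, "d2": b, "d3": c})
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["start"], row["end"]) == (450, 460)
    assert row["category"] == "similarity"


def test_cgi_context_mapping():
    assert cgi_context("island") == "island"
    assert cgi_context("shore") == cgi_context("shelf") == "neighbor"
    assert cgi_context("opensea") == "opensea"
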
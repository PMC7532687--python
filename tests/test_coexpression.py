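"""Co-expression network, distances, enrichment and gene ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import intervals
from ernascope.coexpression import (annotate_distance, build_network,
                                    cis_enrichment, geneset_overrepresentation,
                                    rank_genes)
from ernascope.stats import bh_fdr


def _mats(n_e=5, n_g=5, n=30, seed=1):
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(n)]
    E = pd.DataFrame(rng.normal(size=(n_e, n)),
                     index=[f"e{i}" for i in range(n_e)], columns=cols)
    G = pd.DataFrame(rng.normal(size=(n_g, n)),
                     index=[f"g{i}" for i in range(n_g)], columns=cols)
    return E, G, cols


def test_monotone_pair_has_rho_one():
    E, G, cols = _mats()
    G.loc["g0"] = np.exp(E.loc["e0"])      # strictly monotone transform
    edges = build_network(E, G, cols)
    edge = edges.set_index(["erna_id", "gene_id"]).loc[("e0", "g0")]
    assert edge["rho"] == pytest.approx(1.0)
    assert bool(edge["coexpressed"])


def test_network_matches_per_pair_oracle():
    E, G, cols = _mats()
    edges = build_network(E, G, cols)
    ps = {}
    for e in E.index:
        for g in G.index:
            r = sps.spearmanr(E.loc[e], G.loc[g])
            row = edges.set_index(["erna_id", "gene_id"]).loc[(e, g)]
            assert row["rho"] == pytest.approx(r.statistic, abs=1e-12)
            assert row["p"] == pytest.approx(r.pvalue, rel=1e-6)
            ps[(e, g)] = r.pvalue
    # FDR over all tested pairs
    keys = list(zip(edges["erna_id"], edges["gene_id"]))
    expected_fdr = bh_fdr([ps[k] for k in keys])
    assert np.allclose(edges["fdr"], expected_fdr)


def test_constant_feature_excluded_with_count():
    E, G, cols = _mats()
    E.loc["e1"] = 1.0
    edges = build_network(E, G, cols)
    assert edges.attrs["n_constant_excluded"] == len(G)
    sub = edges[edges["erna_id"] == "e1"]
    assert sub["rho"].isna().all()
    assert not sub["coexpressed"].any()


def test_pair_restriction_changes_fdr_family():
    E, G, cols = _mats()
    pairs = pd.DataFrame({"erna_id": ["e0", "e1"], "gene_id": ["g0", "g1"]})
    edges = build_network(E, G, cols, pairs=pairs)
    assert len(edges) == 2
    expected = bh_fdr(edges["p"])
    assert np.allclose(edges["fdr"], expected)


def test_distance_annotation_strand_aware():
    catalog = intervals([("chr1", 1000, 2000, "e0"), ("chr2", 0, 100, "e1")])
    genes = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [10_500, 4_000],
         "end": [12_000, 9_000], "strand": ["+", "-"],
         "gene_id": ["g0", "g1"]})
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    edges = pd.DataFrame({"erna_id": ["e0", "e0", "e1"],
                          "gene_id": ["g0", "g1", "g0"],
                          "rho": [0.5, 0.5, 0.5]})
    out = annotate_distance(edges, catalog, genes)
    assert out["distance_bp"].iloc[0] == 9000          # |1500 - 10500|
    assert out["distance_bp"].iloc[1] == 8999 - 1500   # minus-strand TSS = end-1
    assert not out["same_chrom"].iloc[2]
    assert np.isnan(out["distance_bp"].iloc[2])


def test_cis_enrichment_direct_arithmetic():
    edges = pd.DataFrame({
        "same_chrom": [True] * 300,
        "coexpressed": [True] * 100 + [False] * 200,
        "distance_bp": [5e5] * 20 + [5e6] * 80 + [5e5] * 10 + [5e6] * 190,
    })
    res = cis_enrichment(edges, window=1e6)
    assert res["table"] == [[20, 80], [10, 190]]
    assert res["enrichment_ratio"] == pytest.approx(4.0)


def test_overrepresentation_er():
    universe = {f"g{i}" for i in range(300)}
    geneset = {f"g{i}" for i in range(30)}
    correlated = {f"g{i}" for i in range(20)} | {f"g{i}" for i in range(100, 180)}
    res = geneset_overrepresentation(correlated, geneset, universe)
    assert res["enrichment_ratio"] == pytest.approx((20 / 100) / (30 / 300))
    # correlated == universe -> ER exactly 1
    res = geneset_overrepresentation(universe, geneset, universe)
    assert res["enrichment_ratio"] == pytest.approx(1.0)
    # empty overlap -> ER 0
    res = geneset_overrepresentation({"g200"}, {"g1"}, universe)
    assert res["enrichment_ratio"] == 0.0


def test_random_geneset_er_centers_on_one():
    rng = np.random.default_rng(9)
    universe = {f"g{i}" for i in range(400)}
    correlated = set(rng.choice(sorted(universe), 120, replace=False))
    ers = [
        geneset_overrepresentation(
            correlated, set(rng.choice(sorted(universe), 40, replace=False)),
            universe)["enrichment_ratio"]
        for _ in range(100)
    ]
    assert np.mean(ers) == pytest.approx(1.0, abs=0.1)


def test_rank_genes_product_score_and_ties():
    edges = pd.DataFrame({
        "erna_id": ["e1", "e2", "e3", "e4"],
        "gene_id": ["gA", "gA", "gA", "gB"],
        "rho": [0.4, 0.4, 0.4, 0.9],
        "coexpressed": [True, True, True, True],
    })
    ranked = rank_genes(edges, universe=["gA", "gB", "gC"])
    assert list(ranked["gene_id"]) == ["gA", "gB", "gC"]
    assert ranked["score"].iloc[0] == pytest.approx(3 * 0.4)
    assert ranked["score"].iloc[1] == pytest.approx(0.9)
    assert ranked["score"].iloc[2] == 0.0
    # identical scores -> lexicographic order
    edges2 = pd.DataFrame({
        "erna_id": ["e1", "e2"], "gene_id": ["gZ", "gA"],
        "rho": [0.5, 0.5], "coexpressed": [True, True]})
    ranked2 = rank_genes(edges2)
    assert list(ranked2["gene_id"]) == ["gA", "gZ"]


def test_permuted_labels_kill_planted_edges():
    """Sample permutation destroys a planted association (null control)."""
    rng = np.random.default_rng(13)
    hits = 0
    for trial in range(20):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        z = rng.normal(size=n)
        E = pd.DataFrame([z + rng.normal(size=n) * 0.5], index=["e0"],
                         columns=cols)
        G = pd.DataFrame([z + rng.normal(size=n) * 0.5], index=["g0"],
                         columns=cols)
        perm = rng.permutation(cols)
        Gp = G[perm]
        Gp.columns = cols
        edges = build_network(E, Gp, cols)
        hits += int(edges["coexpressed"].any())
    assert hits <= 2
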
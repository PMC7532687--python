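"""The functional-pair cascade and copy-number activation criteria."""

import numpy as np
import pandas as pd
import pytest

from conftest import intervals
from ernascope.functional import (call_cna_activated, call_functional,
                                  cis_candidates, locus_cn)


def _de(index, log2fc, fdr, mean_t=10.0, mean_n=10.0):
    return pd.DataFrame(
        {"log2fc": log2fc, "fdr": fdr, "p": fdr,
         "mean_tumor": mean_t, "mean_normal": mean_n},
        index=pd.Index(index, name="feature"),
    )


def _toy_inputs(gene_tss=510_000, rho_sign=+1):
    """One eRNA at 0-2kb, one gene; expression correlated by construction."""
    n = 30
    tumor = [f"P{i}T" for i in range(n)]
    normal = [f"P{i}N" for i in range(n)]
    rng = np.random.default_rng(0)
    z = rng.normal(size=n)
    e_t = 10 + z
    g_t = 10 + rho_sign * z
    erna = pd.DataFrame([list(e_t) + list(rng.normal(10, 1, n))],
                        index=["e1"], columns=tumor + normal)
    gene = pd.DataFrame([list(g_t) + list(rng.normal(10, 1, n))],
                        index=["g1"], columns=tumor + normal)
    catalog = intervals([("chr1", 0, 2000, "e1")])
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [gene_tss],
                          "end": [gene_tss + 10_000], "strand": ["+"],
                          "gene_id": ["g1"], "tss": [gene_tss]})
    return erna, gene, catalog, genes, tumor, normal


def _run(erna, gene, catalog, genes, tumor, normal,
         e_lfc=3.0, e_fdr=0.01, g_lfc=2.5, g_fdr=0.01, g_mean_t=1.0):
    de_e = _de(["e1"], e_lfc, e_fdr)
    de_g = _de(["g1"], g_lfc, g_fdr)
    return call_functional(
        de_e, de_g, erna, gene, catalog, genes, tumor, normal,
        gene_mean_tumor_tpm=pd.Series({"g1": g_mean_t}),
        gene_mean_normal_tpm=pd.Series({"g1": g_mean_t}),
    )


def test_all_three_criteria_give_one_up_call():
    calls, pairs = _run(*_toy_inputs())
    assert len(calls) == 1
    assert calls.iloc[0]["direction"] == "up"
    assert calls.iloc[0]["target_genes"] == "g1"
    assert pairs["functional"].sum() == 1


def test_negative_correlation_blocks_call():
    calls, _ = _run(*_toy_inputs(rho_sign=-1))
    assert calls.empty


def test_distance_window_blocks_call():
    calls, _ = _run(*_toy_inputs(gene_tss=1_201_000))
    assert calls.empty


def test_gene_direction_must_match():
    calls, _ = _run(*_toy_inputs(), g_lfc=-2.5)   # up eRNA, down gene
    assert calls.empty


def test_tpm_floor_blocks_call():
    calls, _ = _run(*_toy_inputs(), g_mean_t=0.2)
    assert calls.empty


def test_raising_lfc_min_shrinks_call_set():
    erna, gene, catalog, genes, tumor, normal = _toy_inputs()
    de_e = _de(["e1"], 2.5, 0.01)
    de_g = _de(["g1"], 2.5, 0.01)
    kwargs = dict(
        gene_mean_tumor_tpm=pd.Series({"g1": 1.0}),
        gene_mean_normal_tpm=pd.Series({"g1": 1.0}),
    )
    loose, _ = call_functional(de_e, de_g, erna, gene, catalog, genes,
                               tumor, normal, lfc_min=2.0, **kwargs)
    strict, _ = call_functional(de_e, de_g, erna, gene, catalog, genes,
                                tumor, normal, lfc_min=3.0, **kwargs)
    assert set(strict["erna_id"]) <= set(loose["erna_id"])
    assert len(loose) == 1 and len(strict) == 0


def test_down_calls_without_normal_samples_error():
    erna, gene, catalog, genes, tumor, _ = _toy_inputs()
    de_e = _de(["e1"], -3.0, 0.01)
    de_g = _de(["g1"], -2.5, 0.01)
    with pytest.raises(ValueError, match="normal"):
        call_functional(de_e, de_g, erna, gene, catalog, genes, tumor, None,
                        gene_mean_tumor_tpm=pd.Series({"g1": 1.0}),
                        gene_mean_normal_tpm=pd.Series({"g1": 1.0}))


def test_cis_candidates_window():
    catalog = intervals([("chr1", 0, 2000, "e1")])
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [500_000, 1_200_000, 100],
        "end": [510_000, 1_210_000, 1100],
        "strand": ["+", "+", "+"],
        "gene_id": ["near", "far", "trans"],
    })
    genes["tss"] = genes["start"]
    cand = cis_candidates(["e1"], catalog, genes, window=1e6)
    assert list(cand["gene_id"]) == ["near"]


# ----------------------------------------------------------- copy number


def _seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "log2ratio", "integer_cn"])


def test_locus_cn_length_weighted_mean():
    segs = _seg_frame([("s1", "chr1", 0, 100, 1.0, 4),
                       ("s1", "chr1", 100, 400, 0.0, 2)])
    cn = locus_cn(segs, "chr1", 0, 400, ["s1", "s2"])
    assert cn.loc["s1", "log2ratio"] == pytest.approx(0.25)
    assert cn.loc["s1", "amplified"] == 1.0       # integer_cn 4 segment
    assert np.isnan(cn.loc["s2", "log2ratio"])    # no coverage


def test_amp_ratio_boundary_ten_percent_passes():
    """8 amplified of 80 tumors = 0.10 satisfies the >= 10% criterion."""
    n = 80
    samples = [f"P{i}T" for i in range(n)]
    rng = np.random.default_rng(3)
    segs = _seg_frame(
        [(s, "chr1", 0, 10_000, 1.0 if i < 8 else 0.0, 3 if i < 8 else 2)
         for i, s in enumerate(samples)])
    z = rng.normal(size=n)
    cnvec = np.where(np.arange(n) < 8, 2.0, 1.0)
    expr_e = pd.DataFrame([cnvec * 10 + z], index=["e1"], columns=samples)
    expr_g = pd.DataFrame([10 + z + rng.normal(size=n) * 0.5], index=["g1"],
                          columns=samples)
    calls = pd.DataFrame({"erna_id": ["e1"], "direction": ["up"],
                          "target_genes": ["g1"]})
    catalog = intervals([("chr1", 1000, 2000, "e1")])
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [6000],
                          "strand": ["+"], "gene_id": ["g1"], "tss": [5000]})
    out = call_cna_activated(calls, segs, catalog, genes, expr_e,
                             expr_g, samples)
    assert out.iloc[0]["amp_ratio"] == pytest.approx(0.10)
    assert bool(out.iloc[0]["cna_activated"])


def test_confounded_pair_fails_partial_correlation():
    """eRNA and gene both exact functions of the gene-locus copy number:
    conditioning wipes the association (criterion 3 fails)."""
    n = 60
    samples = [f"P{i}T" for i in range(n)]
    rng = np.random.default_rng(4)
    cn = rng.choice([2.0, 3.0, 4.0], size=n)
    segs = _seg_frame([(s, "chr1", 0, 10_000, np.log2(c / 2), int(c))
                       for s, c in zip(samples, cn)])
    expr_e = pd.DataFrame([cn * 5.0], index=["e1"], columns=samples)
    expr_g = pd.DataFrame([cn * 3.0], index=["g1"], columns=samples)
    calls = pd.DataFrame({"erna_id": ["e1"], "direction": ["up"],
                          "target_genes": ["g1"]})
    catalog = intervals([("chr1", 1000, 2000, "e1")])
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [6000],
                          "strand": ["+"], "gene_id": ["g1"], "tss": [5000]})
    out = call_cna_activated(calls, segs, catalog, genes, expr_e,
                             expr_g, samples)
    # criteria 1 and 2 hold, criterion 3 must fail
    assert out.iloc[0]["amp_ratio"] > 0.1
    assert out.iloc[0]["cn_expr_rho"] > 0.9
    assert not bool(out.iloc[0]["cna_activated"])


def test_missing_cn_coverage_leaves_flag_missing():
    segs = _seg_frame([("s1", "chr9", 0, 100, 0.0, 2)])
    expr = pd.DataFrame([[1.0, 2.0]], index=["e1"], columns=["s1", "s2"])
    gexpr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s2"])
    calls = pd.DataFrame({"erna_id": ["e1"], "direction": ["up"],
                          "target_genes": ["g1"]})
    catalog = intervals([("chr1", 0, 100, "e1")])
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600],
                          "strand": ["+"], "gene_id": ["g1"], "tss": [500]})
    with pytest.warns(UserWarning, match="no copy-number coverage"):
        out = call_cna_activated(calls, segs, catalog, genes, expr,
                                 gexpr, ["s1", "s2"])
    assert out.iloc[0]["cna_activated"] is pd.NA
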
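"""Paired/rank tests, fold changes and copy-number burden summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ernascope.differential import (correlate_global_with_burden,
                                    genome_fraction_altered, global_paired_test,
                                    mutation_burden, paired_de, status_vs_global,
                                    subgroup_test)


def _expr_and_pairs(tumor, normal):
    """Build an expression frame and pairs table from per-feature arrays."""
    tumor, normal = np.atleast_2d(tumor), np.atleast_2d(normal)
    n = tumor.shape[1]
    cols = [f"P{i}T" for i in range(n)] + [f"P{i}N" for i in range(n)]
    expr = pd.DataFrame(np.hstack([tumor, normal]), columns=cols)
    pairs = pd.DataFrame({"tumor": cols[:n], "normal": cols[n:]},
                         index=[f"P{i}" for i in range(n)])
    return expr, pairs


def test_signed_rank_exact_p_all_same_sign():
    """8 pairs, tumor > normal in all: two-sided exact p = 2/2^8."""
    normal = np.arange(1.0, 9.0)
    tumor = normal + np.linspace(0.5, 4.0, 8)
    expr, pairs = _expr_and_pairs(tumor, normal)
    res = paired_de(expr, pairs)
    assert res["p"].iloc[0] == pytest.approx(2 / 2**8)


def test_identical_groups_degenerate():
    vals = np.arange(1.0, 9.0)
    expr, pairs = _expr_and_pairs(vals, vals)
    res = paired_de(expr, pairs)
    assert res["p"].iloc[0] == 1.0
    assert res["log2fc"].iloc[0] == 0.0
    assert bool(res["degenerate"].iloc[0])


def test_log2fc_pseudocount_arithmetic():
    expr, pairs = _expr_and_pairs(np.full(8, 4.0), np.full(8, 1.0))
    res = paired_de(expr, pairs, pseudocount=0.0)
    assert res["log2fc"].iloc[0] == pytest.approx(2.0)


def test_paired_de_requires_six_pairs():
    expr, pairs = _expr_and_pairs(np.arange(5.0), np.arange(5.0))
    with pytest.raises(ValueError, match="6"):
        paired_de(expr, pairs)


def test_global_test_label_swap_symmetry():
    rng = np.random.default_rng(4)
    t, n = rng.random(12), rng.random(12)
    expr, pairs = _expr_and_pairs(t, n)
    g = expr.iloc[0]
    _, p1 = global_paired_test(g, pairs)
    swapped = pairs.rename(columns={"tumor": "normal", "normal": "tumor"})
    _, p2 = global_paired_test(g, swapped)
    assert p1 == pytest.approx(p2)


def test_subgroup_exact_enumeration_three_vs_three():
    """p for 3 vs 3 without ties equals enumeration over C(6,3) splits."""
    g = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                  index=[f"s{i}" for i in range(6)])
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=g.index)
    stat, p = subgroup_test(g, labels)

    def u_stat(group_a):
        rest = [v for v in g if v not in group_a]
        return sum(1 for x in group_a for y in rest if x > y)

    observed = u_stat(list(g[:3]))
    us = [u_stat(list(c)) for c in itertools.combinations(g, 3)]
    extreme = sum(1 for u in us
                  if abs(u - 4.5) >= abs(observed - 4.5) - 1e-9)
    assert p == pytest.approx(extreme / len(us))


def test_subgroup_requires_two_groups_of_three():
    g = pd.Series(np.arange(5.0), index=[f"s{i}" for i in range(5)])
    with pytest.raises(ValueError):
        subgroup_test(g, pd.Series(["a"] * 5, index=g.index))
    with pytest.raises(ValueError, match="3"):
        subgroup_test(g, pd.Series(["a", "a", "b", "b", "b"], index=g.index))


def _seg(sample, chrom, start, end, lr):
    return dict(sample=sample, chrom=chrom, start=start, end=end, log2ratio=lr)


def test_genome_fraction_whole_genome_gain():
    segs = pd.DataFrame([_seg("s1", "chr1", 0, 1000, 0.5)])
    out = genome_fraction_altered(segs)
    assert out.loc["s1", "frac_amplified"] == 1.0
    assert out.loc["s1", "frac_deleted"] == 0.0


def test_genome_fraction_matches_per_base_oracle():
    segs = pd.DataFrame([
        _seg("s1", "chr1", 0, 100, 0.5), _seg("s1", "chr1", 100, 250, 0.0),
        _seg("s1", "chr1", 250, 300, -0.7), _seg("s1", "chr2", 0, 200, 0.31),
        _seg("s1", "chr2", 200, 500, -0.29),
    ])
    out = genome_fraction_altered(segs, 0.3, -0.3)
    amp = dele = tot = 0
    for _, s in segs.iterrows():
        for _ in range(s.start, s.end):
            tot += 1
            amp += s.log2ratio >= 0.3
            dele += s.log2ratio <= -0.3
    assert out.loc["s1", "frac_amplified"] == pytest.approx(amp / tot)
    assert out.loc["s1", "frac_deleted"] == pytest.approx(dele / tot)


def test_genome_fraction_rejects_overlapping_segments():
    segs = pd.DataFrame([_seg("s1", "chr1", 0, 100, 0.0),
                         _seg("s1", "chr1", 50, 150, 0.0)])
    with pytest.raises(ValueError, match="overlap"):
        genome_fraction_altered(segs)


def test_burden_correlation_monotone_and_rank_invariant():
    g = pd.Series(np.arange(12.0), index=[f"s{i}" for i in range(12)])
    b = pd.Series(np.arange(12.0) ** 3, index=g.index)
    rho, _ = correlate_global_with_burden(g, b)
    assert rho == pytest.approx(1.0)
    rho2, p2 = correlate_global_with_burden(np.exp(g / 4), b)
    assert rho2 == pytest.approx(rho)


def test_status_vs_global_odds_ratio_enumeration():
    # 16 samples split at the median; mutated samples concentrated high
    g = pd.Series(np.arange(16.0), index=[f"s{i}" for i in range(16)])
    status = pd.Series([False] * 16, index=g.index)
    # 6 mutated of 8 high-expression, 2 of 8 low -> [[6,2],[2,6]]
    status.iloc[[2, 3, 8, 9, 10, 11, 12, 13]] = True
    odds, p, table = status_vs_global(status, g)
    assert table.tolist() == [[6, 2], [2, 6]]
    assert odds == pytest.approx(9.0)
    from scipy.stats import hypergeom
    probs = [hypergeom.pmf(a, 16, 8, 8) for a in range(9)]
    p_obs = hypergeom.pmf(6, 16, 8, 8)
    expected = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-9))
    assert p == pytest.approx(expected, rel=1e-9)


def test_mutation_burden_counts_nonsilent_only():
    muts = pd.DataFrame({"sample": ["s1", "s1", "s2"],
                         "gene": ["g1", "g2", "g1"],
                         "non_silent": [1, 0, 1]})
    b = mutation_burden(muts, ["s1", "s2", "s3"])
    assert b.tolist() == [1, 1, 0]
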
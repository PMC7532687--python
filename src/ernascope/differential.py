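"""Tumor-vs-normal comparisons and genome-instability summaries.

Per-feature differential expression uses the paired Wilcoxon signed-rank
test across tumor/normal pairs with BH correction across features; the
fold change is the log2 ratio of group means with a pseudocount.  Subgroup
contrasts of the global eRNA statistic use the rank-sum test.  Copy-number
instability is summarised as the fraction of the segmented genome in
gained / lost segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, fisher_2x2, spearman


def _signed_rank(diff: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired signed-rank (statistic, p, degenerate flag).

    Exact null for small n without ties, normal approximation with
    continuity correction otherwise; zero differences dropped.
    """
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0, 1.0, True
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue), False


def paired_de(
    expr: pd.DataFrame, pairs: pd.DataFrame, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Per-feature paired DE over complete tumor/normal pairs.

    ``pairs`` has columns 'tumor' and 'normal' holding sample IDs (one row
    per patient).  Returns a feature-indexed frame with log2fc, statistic,
    p, fdr, mean_tumor, mean_normal and a degenerate flag.
    """
    if len(pairs) < 6:
        raise ValueError("need at least 6 complete tumor/normal pairs")
    T = expr[list(pairs["tumor"])].to_numpy(dtype=float)
    N = expr[list(pairs["normal"])].to_numpy(dtype=float)
    mean_t, mean_n = T.mean(axis=1), N.mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_n + pseudocount))
    stats_p = [_signed_rank(t - n) for t, n in zip(T, N)]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "statistic": [s for s, _, _ in stats_p],
            "p": [p for _, p, _ in stats_p],
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "degenerate": [d for _, _, d in stats_p],
        },
        index=expr.index,
    )
    out["fdr"] = bh_fdr(out["p"])
    return out[["log2fc", "statistic", "p", "fdr", "mean_tumor", "mean_normal", "degenerate"]]


def global_paired_test(global_expr: pd.Series, pairs: pd.DataFrame) -> tuple[float, float]:
    """Paired signed-rank on the per-sample global eRNA statistic."""
    diff = (
        global_expr[list(pairs["tumor"])].to_numpy()
        - global_expr[list(pairs["normal"])].to_numpy()
    )
    stat, p, _ = _signed_rank(diff)
    return stat, p


def subgroup_test(
    global_expr: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Two-sided rank-sum test of the global statistic between two subgroups.

    ``groups`` maps sample -> label; exactly two labels with >= 3 samples
    each are required.
    """
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 subgroups, got {list(labels)}")
    a = global_expr[groups.index[groups == labels[0]]].dropna()
    b = global_expr[groups.index[groups == labels[1]]].dropna()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each subgroup needs at least 3 samples")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def genome_fraction_altered(
    segments: pd.DataFrame,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
) -> pd.DataFrame:
    """Per-sample fractions of the segmented genome gained and lost.

    Fraction = total length of segments with log2ratio >= gain_threshold
    (resp. <= loss_threshold) over total segmented length.  Segments must
    be non-overlapping within a sample.
    """
    rows = []
    for sample, sub in segments.groupby("sample"):
        offenders = []
        for _, chrom_sub in sub.groupby("chrom"):
            s = chrom_sub.sort_values("start")
            bad = s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]
            if bad.any():
                offenders.extend(
                    s.iloc[1:][bad][["chrom", "start", "end"]].itertuples(index=False)
                )
        if offenders:
            raise ValueError(f"overlapping segments in sample {sample}: {offenders[:3]}")
        length = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        total = length.sum()
        gained = length[sub["log2ratio"].to_numpy() >= gain_threshold].sum()
        lost = length[sub["log2ratio"].to_numpy() <= loss_threshold].sum()
        rows.append((sample, gained / total, lost / total))
    return pd.DataFrame(
        rows, columns=["sample", "frac_amplified", "frac_deleted"]
    ).set_index("sample")


def mutation_burden(mutations: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Non-silent mutation count per sample (zero for unlisted samples)."""
    nonsilent = mutations[mutations["non_silent"].astype(bool)]
    counts = nonsilent.groupby("sample").size()
    return counts.reindex(samples, fill_value=0).astype(int)


def correlate_global_with_burden(
    global_expr: pd.Series, burden: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of global eRNA expression with a burden measure."""
    common = global_expr.index.intersection(burden.index)
    if len(common) < 10:
        raise ValueError("need at least 10 samples with both measurements")
    return spearman(global_expr[common], burden[common])


def status_vs_global(
    status: pd.Series, global_expr: pd.Series
) -> tuple[float, float, np.ndarray]:
    """Fisher test of a binary per-sample status against high/low global eRNA.

    Samples are dichotomised at the cohort median of the global statistic;
    returns (odds_ratio, p, 2x2 table).
    """
    common = status.index.intersection(global_expr.index)
    g = global_expr[common]
    s = status[common].astype(bool)
    if s.sum() < 2 or (~s).sum() < 2:
        raise ValueError("need at least 2 samples per status group")
    if g.nunique() == 1:
        raise ValueError("global expression is constant; median split undefined")
    high = g > g.median()
    table = np.array(
        [
            [int((s & high).sum()), int((s & ~high).sum())],
            [int((~s & high).sum()), int((~s & ~high).sum())],
        ]
    )
    odds, p = fisher_2x2(table)
    return odds, p, table
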
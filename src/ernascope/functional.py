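"""Functional eRNA-gene pair calling and copy-number activation.

A functional pair must survive a three-criterion cascade: (1) the eRNA is
differentially expressed (|log2FC| >= 2, FDR < 0.05); (2) a protein-coding
gene with TSS within 1 Mbp is positively correlated with it (rho >= 0.2,
FDR < 0.05) in tumor samples for up-eRNAs or normal samples for
down-eRNAs; (3) that gene is differentially expressed in the matching
direction and sufficiently expressed (>= 0.5 TPM in the relevant group).

Correlations for criterion 2 are computed over the cis-candidate family
(criterion-1 eRNAs x in-window genes) with BH across that family: the
cascade only ever evaluates these pairs, so that is the family whose false
discoveries matter.

An up-call is additionally flagged CNA-activated when its locus is
amplified in >= 10% of tumors, its expression tracks its copy number
(Spearman >= 0.2, p < 0.05), and its association with the target gene
survives conditioning on the gene-locus copy number (partial Spearman).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coexpression import build_network
from .stats import partial_spearman, spearman


def cis_candidates(
    erna_ids, catalog: pd.DataFrame, genes: pd.DataFrame, window: float = 1e6
) -> pd.DataFrame:
    """All (erna_id, gene_id) pairs with enhancer midpoint within ``window``
    of the gene's strand-aware TSS, on the same chromosome."""
    enh = catalog.set_index("id").loc[list(erna_ids)]
    rows = []
    for eid, e in enh.iterrows():
        mid = (e["start"] + e["end"]) // 2
        near = genes[
            (genes["chrom"] == e["chrom"]) & ((genes["tss"] - mid).abs() <= window)
        ]
        for _, g in near.iterrows():
            rows.append((eid, g["gene_id"], abs(int(g["tss"]) - mid)))
    return pd.DataFrame(rows, columns=["erna_id", "gene_id", "distance_bp"])


def call_functional(
    de_ernas: pd.DataFrame,
    de_genes: pd.DataFrame,
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    catalog: pd.DataFrame,
    genes: pd.DataFrame,
    tumor_samples: list[str],
    normal_samples: list[str] | None,
    gene_mean_tumor_tpm: pd.Series,
    gene_mean_normal_tpm: pd.Series,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
    tpm_min: float = 0.5,
    window: float = 1e6,
    rho_min: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the three-criterion cascade.

    Returns ``(calls, pairs)``: one row per passing eRNA (listing all
    qualifying target genes) and one row per evaluated cis-candidate pair
    with its per-criterion flags.
    """
    up_ids = list(de_ernas.index[(de_ernas["log2fc"] >= lfc_min) & (de_ernas["fdr"] < alpha)])
    down_ids = list(de_ernas.index[(de_ernas["log2fc"] <= -lfc_min) & (de_ernas["fdr"] < alpha)])
    if down_ids and normal_samples is None:
        raise ValueError("down-regulated eRNAs present but no normal-sample network inputs")

    pair_frames = []
    for direction, ids, samples in (
        ("up", up_ids, tumor_samples),
        ("down", down_ids, normal_samples),
    ):
        if not ids:
            continue
        cand = cis_candidates(ids, catalog, genes, window)
        cand = cand[cand["gene_id"].isin(gene_expr.index)]
        if cand.empty:
            continue
        net = build_network(
            erna_expr, gene_expr, list(samples), rho_min=rho_min, alpha=alpha, pairs=cand
        )
        net = cand.merge(net, on=["erna_id", "gene_id"])
        net["direction"] = direction
        pair_frames.append(net)

    if not pair_frames:
        empty = pd.DataFrame(
            columns=["erna_id", "gene_id", "direction", "distance_bp", "rho", "p",
                     "fdr", "cis_positive_pass", "gene_de_pass", "functional"]
        )
        return empty.copy(), empty

    pairs = pd.concat(pair_frames, ignore_index=True)
    pairs["cis_positive_pass"] = (pairs["rho"] >= rho_min) & (pairs["fdr"] < alpha)

    g = de_genes.reindex(pairs["gene_id"])
    up = pairs["direction"].to_numpy() == "up"
    gene_lfc = g["log2fc"].to_numpy()
    gene_fdr = g["fdr"].to_numpy()
    mt = gene_mean_tumor_tpm.reindex(pairs["gene_id"]).to_numpy()
    mn = gene_mean_normal_tpm.reindex(pairs["gene_id"]).to_numpy()
    pairs["gene_de_pass"] = np.where(
        up,
        (gene_lfc >= lfc_min) & (gene_fdr < alpha) & (mt >= tpm_min),
        (gene_lfc <= -lfc_min) & (gene_fdr < alpha) & (mn >= tpm_min),
    )
    pairs["functional"] = pairs["cis_positive_pass"] & pairs["gene_de_pass"]

    hits = pairs[pairs["functional"]]
    calls = (
        hits.groupby(["erna_id", "direction"])["gene_id"]
        .agg(lambda s: ",".join(sorted(s)))
        .rename("target_genes")
        .reset_index()
    )
    calls["erna_de_pass"] = True
    calls["cis_positive_pass"] = True
    calls["gene_de_pass"] = True
    calls["log2fc"] = de_ernas["log2fc"].reindex(calls["erna_id"]).to_numpy()
    return calls.sort_values("erna_id").reset_index(drop=True), pairs


# ------------------------------------------------------------ copy number


def locus_cn(
    segments: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    samples: list[str],
    gain_threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-sample copy-number summary at one locus.

    ``log2ratio`` is the length-weighted mean over overlapping segments;
    ``amplified`` is true when any overlapping segment has integer_cn > 2
    (if present) or the weighted log2ratio reaches ``gain_threshold``.
    Samples with no overlapping segment get NaN.
    """
    sub = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] < end)
        & (segments["end"] > start)
    ]
    has_int = "integer_cn" in segments.columns
    out = pd.DataFrame(index=pd.Index(samples, name="sample"),
                       columns=["log2ratio", "amplified"], dtype=float)
    for sample, ssub in sub.groupby("sample"):
        if sample not in out.index:
            continue
        w = (np.minimum(ssub["end"], end) - np.maximum(ssub["start"], start)).to_numpy(float)
        lr = float(np.average(ssub["log2ratio"].to_numpy(float), weights=w))
        amp = lr >= gain_threshold
        if has_int:
            amp = amp or bool((ssub["integer_cn"] > 2).any())
        out.loc[sample, "log2ratio"] = lr
        out.loc[sample, "amplified"] = float(amp)
    return out


def call_cna_activated(
    calls: pd.DataFrame,
    segments: pd.DataFrame,
    catalog: pd.DataFrame,
    genes: pd.DataFrame,
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    tumor_samples: list[str],
    amp_ratio_min: float = 0.10,
    rho_min: float = 0.2,
    alpha: float = 0.05,
    gain_threshold: float = 0.3,
) -> pd.DataFrame:
    """Annotate up-calls with the three copy-number-activation criteria.

    Adds amp_ratio, cn_expr_rho/p, partial_rho/p (best qualifying target)
    and the boolean ``cna_activated``.  Loci without copy-number coverage
    keep ``cna_activated`` missing, with a warning.
    """
    enh = catalog.set_index("id")
    gidx = genes.set_index("gene_id")
    out = calls.copy()
    for col in ("amp_ratio", "cn_expr_rho", "cn_expr_p", "partial_rho", "partial_p"):
        out[col] = np.nan
    out["cna_activated"] = pd.array([pd.NA] * len(out), dtype="boolean")

    for i, call in out.iterrows():
        if call["direction"] != "up":
            out.loc[i, "cna_activated"] = False
            continue
        e = enh.loc[call["erna_id"]]
        cn_e = locus_cn(segments, e["chrom"], e["start"], e["end"],
                        tumor_samples, gain_threshold)
        if cn_e["log2ratio"].isna().all():
            warnings.warn(f"no copy-number coverage at eRNA {call['erna_id']}")
            continue
        amp_ratio = float(cn_e["amplified"].fillna(0).mean())
        out.loc[i, "amp_ratio"] = amp_ratio
        expr_e = erna_expr.loc[call["erna_id"], tumor_samples]
        rho2, p2 = spearman(cn_e["log2ratio"].fillna(0.0).to_numpy(), expr_e.to_numpy())
        out.loc[i, ["cn_expr_rho", "cn_expr_p"]] = rho2, p2
        crit1 = amp_ratio >= amp_ratio_min
        crit2 = (rho2 >= rho_min) and (p2 < alpha)

        best = (np.nan, np.nan)
        crit3 = False
        for gene_id in str(call["target_genes"]).split(","):
            g = gidx.loc[gene_id]
            cn_g = locus_cn(segments, g["chrom"], g["start"], g["end"],
                            tumor_samples, gain_threshold)
            if cn_g["log2ratio"].isna().all():
                warnings.warn(f"no copy-number coverage at gene {gene_id}")
                continue
            expr_g = gene_expr.loc[gene_id, tumor_samples]
            prho, pp = partial_spearman(
                expr_e.to_numpy(), expr_g.to_numpy(),
                cn_g["log2ratio"].fillna(0.0).to_numpy(),
            )
            if np.isnan(best[0]) or (not np.isnan(prho) and prho > best[0]):
                best = (prho, pp)
            if not np.isnan(prho) and prho >= rho_min and pp < alpha:
                crit3 = True
        out.loc[i, ["partial_rho", "partial_p"]] = best
        out.loc[i, "cna_activated"] = bool(crit1 and crit2 and crit3)
    return out
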
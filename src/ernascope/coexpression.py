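"""eRNA - protein-coding-gene co-expression networks.

Edges are Spearman rank correlations over a chosen sample subset, corrected
by BH across all tested pairs; a pair is "co-expressed" when |rho| exceeds
``rho_min`` and the adjusted p falls below ``alpha``.  Downstream summaries
cover enhancer-TSS distances, cis enrichment within a 1 Mbp window, driver
gene-set over-representation, and the composite gene ranking used for
preranked enrichment analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, enrichment_2x2, spearman_matrix, spearman_pvalues


def build_network(
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    samples: list[str],
    rho_min: float = 0.2,
    alpha: float = 0.05,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman edges between eRNAs and genes over ``samples``.

    By default all eRNA x gene pairs are tested; alternatively ``pairs``
    (columns erna_id, gene_id) restricts the tested family, e.g. to cis
    candidates.  FDR is BH across all tested pairs.  Pairs involving a
    constant feature get NaN rho and are never co-expressed; their count is
    reported via the ``n_constant_excluded`` attribute on the result.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for the co-expression network")
    E = erna_expr[list(samples)]
    G = gene_expr[list(samples)]
    rho = spearman_matrix(E.to_numpy(), G.to_numpy())
    p = spearman_pvalues(rho, len(samples))
    p[np.isnan(rho)] = np.nan
    rho_df = pd.DataFrame(rho, index=E.index, columns=G.index)
    p_df = pd.DataFrame(p, index=E.index, columns=G.index)
    if pairs is None:
        edges = rho_df.stack(future_stack=True).rename("rho").reset_index()
        edges.columns = ["erna_id", "gene_id", "rho"]
        edges["p"] = p_df.to_numpy().ravel()
    else:
        edges = pairs[["erna_id", "gene_id"]].drop_duplicates().copy()
        ei = rho_df.index.get_indexer(edges["erna_id"])
        gi = rho_df.columns.get_indexer(edges["gene_id"])
        if (ei < 0).any() or (gi < 0).any():
            raise KeyError("requested pair features absent from expression matrices")
        edges["rho"] = rho[ei, gi]
        edges["p"] = p[ei, gi]
    edges["fdr"] = bh_fdr(edges["p"])
    edges["coexpressed"] = (
        (edges["rho"].abs() >= rho_min) & (edges["fdr"] < alpha)
    ).fillna(False)
    edges = edges.reset_index(drop=True)
    edges.attrs["n_constant_excluded"] = int(edges["rho"].isna().sum())
    edges.attrs["n_samples"] = len(samples)
    return edges


def annotate_distance(
    edges: pd.DataFrame, catalog: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Attach same-chromosome flags and enhancer-midpoint-to-TSS distances.

    TSS is strand-aware (gene start on +, end on -); trans pairs get
    ``same_chrom=False`` and missing distance.
    """
    enh = catalog.set_index("id")
    mid = ((enh["start"] + enh["end"]) // 2).to_dict()
    echrom = enh["chrom"].to_dict()
    g = genes.set_index("gene_id")
    tss = g["tss"].to_dict()
    gchrom = g["chrom"].to_dict()
    out = edges.copy()
    out["same_chrom"] = [
        echrom.get(e) == gchrom.get(gn) and echrom.get(e) is not None
        for e, gn in zip(out["erna_id"], out["gene_id"])
    ]
    out["distance_bp"] = [
        abs(mid[e] - tss[gn]) if sc else np.nan
        for e, gn, sc in zip(out["erna_id"], out["gene_id"], out["same_chrom"])
    ]
    return out


def cis_enrichment(edges: pd.DataFrame, window: float = 1e6) -> dict:
    """Enrichment of co-expressed pairs within ``window`` bp, among
    same-chromosome pairs.

    2x2 of (co-expressed vs not) x (within window vs not); returns the
    rate-ratio ER, odds ratio and Fisher p.
    """
    cis = edges[edges["same_chrom"]]
    close = cis["distance_bp"] <= window
    co = cis["coexpressed"].astype(bool)
    table = np.array(
        [
            [int((co & close).sum()), int((co & ~close).sum())],
            [int((~co & close).sum()), int((~co & ~close).sum())],
        ]
    )
    return enrichment_2x2(table)


def geneset_overrepresentation(
    correlated_genes: set[str], geneset: set[str], universe: set[str]
) -> dict:
    """Over-representation of a gene set among eRNA-correlated genes.

    ER = (|correlated & set| / |correlated|) / (|set & universe| / |universe|);
    Fisher p from the 2x2 of (correlated vs not) x (in set vs not), with the
    set restricted to the universe.
    """
    correlated = set(correlated_genes) & set(universe)
    gset = set(geneset) & set(universe)
    rest = set(universe) - correlated
    a = len(correlated & gset)
    table = np.array(
        [[a, len(correlated) - a], [len(rest & gset), len(rest) - len(rest & gset)]]
    )
    res = enrichment_2x2(table)
    if len(correlated) and len(universe) and len(gset):
        res["enrichment_ratio"] = (a / len(correlated)) / (len(gset) / len(universe))
    else:
        res["enrichment_ratio"] = float("nan")
    return res


def rank_genes(edges: pd.DataFrame, universe: list[str] | None = None) -> pd.DataFrame:
    """Composite gene ranking from the co-expression network.

    score(gene) = (number of co-expressed eRNAs) x (mean rho over those
    edges); genes with no co-expressed edge score 0.  Descending by score,
    ties broken by mean rho then gene ID, yielding a strict order.
    """
    co = edges[edges["coexpressed"].astype(bool)]
    grouped = co.groupby("gene_id")["rho"].agg(n_edges="size", mean_rho="mean")
    genes = universe if universe is not None else sorted(set(edges["gene_id"]))
    out = grouped.reindex(genes).fillna({"n_edges": 0, "mean_rho": 0.0})
    out["score"] = out["n_edges"] * out["mean_rho"]
    out = out.reset_index(names="gene_id").sort_values(
        ["score", "mean_rho", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)[["gene_id", "score", "n_edges", "mean_rho"]]
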
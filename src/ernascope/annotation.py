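"""Enhancer catalog construction and genic-context classification.

Enhancer candidates come from two independent annotation sources (a broad
histone-mark-derived set and a smaller transcription-defined set).  Only
enhancers supported by both sources enter the catalog; each is then
classified as exonic, intronic or intergenic against a gene model, with
precedence exonic > intronic > intergenic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import enrichment_2x2

GENIC_CLASSES = ("exonic", "intergenic", "intronic")


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    return trees


def _overlaps(trees, chrom, start, end) -> list:
    tree = trees.get(chrom)
    return sorted(tree.overlap(start, end)) if tree is not None else []


def build_catalog(
    source_a: pd.DataFrame,
    source_b: pd.DataFrame,
    min_overlap_frac: float = 0.0,
) -> pd.DataFrame:
    """Retain source-B enhancers supported by at least one source-A region.

    Support means reciprocal overlap of at least ``min_overlap_frac`` of
    each interval's length; the default 0.0 means any overlap (>= 1 bp).
    Retained enhancers keep source-B coordinates and identity and carry
    ``n_sources`` (always 2 in the output, by construction).  Output is
    sorted by (chrom, start).
    """
    if source_a.empty or source_b.empty:
        raise ValueError("both enhancer sources must be non-empty")
    trees = _trees(source_a)
    keep = []
    for row in source_b.itertuples(index=False):
        blen = row.end - row.start
        for iv in _overlaps(trees, row.chrom, row.start, row.end):
            olen = min(row.end, iv.end) - max(row.start, iv.begin)
            alen = iv.end - iv.begin
            if olen >= min_overlap_frac * blen and olen >= min_overlap_frac * alen:
                keep.append(True)
                break
        else:
            keep.append(False)
    cat = source_b.loc[list(keep)].copy()
    cat["n_sources"] = 2
    return cat.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def classify_genic_context(catalog: pd.DataFrame, gene_model: dict) -> pd.DataFrame:
    """Attach ``genic_class`` to each catalog enhancer.

    exonic if the enhancer overlaps any exon by >= 1 bp; else intronic if it
    overlaps any gene body; else intergenic.  Genes lacking exon records are
    still usable for the intronic test (with a warning).
    """
    genes, exons = gene_model["genes"], gene_model["exons"]
    missing = set(genes.gene_id) - set(exons.gene_id)
    if missing:
        warnings.warn(
            f"{len(missing)} genes have no exon records; "
            "gene bodies still used for the intronic test"
        )
    exon_trees = _trees(exons)
    gene_trees = _trees(genes)
    classes = []
    for row in catalog.itertuples(index=False):
        if _overlaps(exon_trees, row.chrom, row.start, row.end):
            classes.append("exonic")
        elif _overlaps(gene_trees, row.chrom, row.start, row.end):
            classes.append("intronic")
        else:
            classes.append("intergenic")
    out = catalog.copy()
    out["genic_class"] = classes
    return out


def class_counts(catalog: pd.DataFrame) -> dict[str, int]:
    """Per-class enhancer counts plus their total."""
    counts = {c: int((catalog["genic_class"] == c).sum()) for c in GENIC_CLASSES}
    counts["total"] = len(catalog)
    return counts


def track_overlap_enrichment(
    set1: pd.DataFrame, set2: pd.DataFrame, track: pd.DataFrame
) -> dict:
    """Overlap enrichment of interval set1 vs set2 against a feature track.

    Builds the 2x2 table of (member of set1 / set2) x (overlaps track
    yes/no) and reports the rate-ratio enrichment, odds ratio and two-sided
    Fisher p.  The two sets must not share interval IDs.
    """
    shared = set(set1["id"]) & set(set2["id"])
    if shared:
        raise ValueError(f"sets share {len(shared)} interval IDs; must be disjoint")
    trees = _trees(track)

    def hits(df):
        return sum(
            bool(_overlaps(trees, r.chrom, r.start, r.end))
            for r in df.itertuples(index=False)
        )

    h1, h2 = hits(set1), hits(set2)
    table = np.array([[h1, len(set1) - h1], [h2, len(set2) - h2]])
    return enrichment_2x2(table)
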
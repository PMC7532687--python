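"""Stage orchestration: simulate -> annotate -> quantify -> de -> network
-> gsea -> call -> cna -> cluster -> survive.

Every stage is a function over a working directory: it reads the declared
artifacts earlier stages wrote there and writes its own, so stages can be
run individually from the CLI or all at once with a manifest.  Following
the source study's design, only *intergenic* transcribed eRNAs enter the
expression analyses (exonic/intronic enhancer signal is confounded by the
host gene's transcription).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .annotation import build_catalog, class_counts, classify_genic_context
from .clustering import characterize_clusters, consensus_cluster
from .coexpression import (annotate_distance, build_network, cis_enrichment,
                           geneset_overrepresentation, rank_genes)
from .differential import (correlate_global_with_burden, genome_fraction_altered,
                           global_paired_test, mutation_burden, paired_de,
                           subgroup_test)
from .functional import call_cna_activated, call_functional
from .gsea import preranked_gsea
from .quantification import (CountMatrix, filter_expressed, global_erna_expression,
                             normalize_rpm, normalize_tpm)
from .simulate import SimConfig, generate_cohort, write_cohort
from .survival import cox_contrasts, km_logrank, prepare_records


@dataclass
class RunConfig:
    min_count: int = 1
    min_frac: float = 0.10
    rho_min: float = 0.2
    alpha: float = 0.05
    lfc_min: float = 2.0
    tpm_min: float = 0.5
    window: float = 1e6
    amp_ratio_min: float = 0.10
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    pseudocount: float = 0.01
    reps: int = 1000
    p_item: float = 0.7
    p_feature: float = 0.7
    k_range: tuple = (2, 3, 4, 5)
    chosen_k: int | None = None
    n_perm: int = 1000
    min_overlap_frac: float = 0.0
    expression_floor_tpm: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_frac", "alpha", "p_item", "p_feature",
                     "amp_ratio_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.reps < 1 or self.n_perm < 1:
            raise ValueError("reps and n_perm must be positive")


STAGES = ("annotate", "quantify", "de", "network", "gsea", "call", "cna",
          "cluster", "survive")


def _cohort_dir(workdir) -> Path:
    return Path(workdir) / "cohort"


def _load_counts(cdir: Path, which: str) -> CountMatrix:
    samples = eio.read_table(cdir / "samples.tsv").set_index("sample_id")
    return CountMatrix(
        eio.read_matrix(cdir / f"{which}_counts.tsv"),
        samples["library_size"],
        samples[["patient_id", "tissue", "age", "gender", "smoking"]],
    )


# ------------------------------------------------------------------ stages


def stage_simulate(workdir, sim_config: SimConfig) -> None:
    cohort = generate_cohort(sim_config)
    write_cohort(cohort, _cohort_dir(workdir))


def stage_annotate(workdir, cfg: RunConfig) -> None:
    cdir = _cohort_dir(workdir)
    a = eio.read_bed(cdir / "enhancers_A.bed")
    b = eio.read_bed(cdir / "enhancers_B.bed")
    gm = eio.read_gtf(cdir / "genes.gtf")
    catalog = build_catalog(a, b, min_overlap_frac=cfg.min_overlap_frac)
    catalog = classify_genic_context(catalog, gm)
    out = Path(workdir)
    eio.write_bed(catalog, out / "catalog.bed",
                  extra_columns=["genic_class", "n_sources"])
    (out / "annotation_summary.json").write_text(
        json.dumps(class_counts(catalog), indent=2))


def read_catalog(workdir) -> pd.DataFrame:
    cat = eio.read_bed(Path(workdir) / "catalog.bed")
    raw = pd.read_csv(Path(workdir) / "catalog.bed", sep="\t", header=None)
    cat["genic_class"] = raw[6].to_numpy()
    cat["n_sources"] = raw[7].to_numpy()
    return cat


def stage_quantify(workdir, cfg: RunConfig) -> None:
    cdir = _cohort_dir(workdir)
    out = Path(workdir)
    catalog = read_catalog(workdir)
    erna = _load_counts(cdir, "erna")
    gene = _load_counts(cdir, "gene")
    # restrict eRNA counts to catalog enhancers
    keep = [i for i in catalog["id"] if i in erna.values.index]
    erna = CountMatrix(erna.values.loc[keep], erna.library_sizes, erna.sample_meta)
    expressed = filter_expressed(erna, cfg.min_count, cfg.min_frac)
    intergenic = set(catalog.loc[catalog["genic_class"] == "intergenic", "id"])
    expressed_intergenic = [e for e in expressed if e in intergenic]
    if not expressed_intergenic:
        raise RuntimeError("no transcribed intergenic eRNAs survive the filter")
    rpm = normalize_rpm(erna)
    gm = eio.read_gtf(cdir / "genes.gtf")
    exon_len = gm["exons"].assign(l=lambda d: d.end - d.start) \
        .groupby("gene_id")["l"].sum()
    tpm = normalize_tpm(gene, exon_len)
    glob = global_erna_expression(rpm, expressed_intergenic)
    eio.write_matrix(rpm, out / "erna_rpm.tsv", float_format="%.6g")
    eio.write_matrix(tpm, out / "gene_tpm.tsv", float_format="%.6g")
    (out / "expressed_ernas.txt").write_text("\n".join(expressed) + "\n")
    (out / "expressed_intergenic_ernas.txt").write_text(
        "\n".join(expressed_intergenic) + "\n")
    eio.write_table(glob.rename("global_erna_rpm").rename_axis("sample")
                    .reset_index(), out / "global_erna.tsv",
                    float_format="%.6g")


def _quant_state(workdir):
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm = eio.read_matrix(out / "erna_rpm.tsv")
    tpm = eio.read_matrix(out / "gene_tpm.tsv")
    expressed = (out / "expressed_intergenic_ernas.txt").read_text().split()
    glob = eio.read_table(out / "global_erna.tsv").set_index("sample")[
        "global_erna_rpm"]
    counts = _load_counts(cdir, "erna")
    return rpm, tpm, expressed, glob, counts


def stage_de(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm, tpm, expressed, glob, counts = _quant_state(workdir)
    pairs = counts.pairs()
    de_ernas = paired_de(rpm.loc[expressed], pairs, cfg.pseudocount)
    de_genes = paired_de(tpm, pairs, cfg.pseudocount)
    eio.write_table(de_ernas.rename_axis("feature").reset_index(),
                    out / "de_ernas.tsv", float_format="%.6g")
    eio.write_table(de_genes.rename_axis("feature").reset_index(),
                    out / "de_genes.tsv", float_format="%.6g")

    stat, p = global_paired_test(glob, pairs)
    rows = [dict(test="global_tumor_vs_normal", tissue="paired",
                 statistic=stat, p=p)]
    meta = counts.sample_meta
    for tissue in ("tumor", "normal"):
        sub = meta[meta["tissue"] == tissue]
        groupings = {
            "age_median": (sub["age"] > sub["age"].median()).map(
                {True: "older", False: "younger"}),
            "gender": sub["gender"].map({1: "male", 0: "female"}),
            "smoking": sub["smoking"].map({1: "smoker", 0: "non-smoker"}),
        }
        for name, g in groupings.items():
            try:
                stat, p = subgroup_test(glob[sub.index], g)
            except ValueError:
                continue
            rows.append(dict(test=name, tissue=tissue, statistic=stat, p=p))
    eio.write_table(pd.DataFrame(rows), out / "group_tests.tsv",
                    float_format="%.6g")

    segments = eio.read_seg(cdir / "cn_segments.seg")
    summary = genome_fraction_altered(segments, cfg.gain_threshold,
                                      cfg.loss_threshold)
    mutations = eio.read_table(cdir / "mutations.tsv")
    summary["n_nonsilent"] = mutation_burden(mutations, list(summary.index))
    eio.write_table(summary.reset_index(), out / "genome_alteration.tsv",
                    float_format="%.6g")
    tumor_glob = glob[[s for s in summary.index if s in glob.index]]
    burden_rows = []
    for col in ("frac_amplified", "frac_deleted", "n_nonsilent"):
        rho, p = correlate_global_with_burden(tumor_glob, summary[col])
        burden_rows.append(dict(burden=col, rho=rho, p=p))
    eio.write_table(pd.DataFrame(burden_rows), out / "burden_correlation.tsv",
                    float_format="%.6g")


def stage_network(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm, tpm, expressed, _, counts = _quant_state(workdir)
    catalog = read_catalog(workdir)
    gm = eio.read_gtf(cdir / "genes.gtf")
    tumor = counts.samples_of("tumor")
    genes_ok = tpm.index[tpm[tumor].mean(axis=1) >= cfg.expression_floor_tpm]
    edges = build_network(rpm.loc[expressed], tpm.loc[genes_ok], tumor,
                          cfg.rho_min, cfg.alpha)
    edges = annotate_distance(edges, catalog, gm["genes"])
    eio.write_table(edges, out / "edges.tsv", float_format="%.6g")

    rows = [dict(analysis="cis_1mbp", **cis_enrichment(edges, cfg.window))]
    correlated = set(edges.loc[edges["coexpressed"], "gene_id"])
    genesets = eio.read_gmt(cdir / "genesets.gmt")
    universe = set(genes_ok)
    for name, members in genesets.items():
        res = geneset_overrepresentation(correlated, set(members), universe)
        rows.append(dict(analysis=f"overrep_{name}", **res))
    for r in rows:
        r["table"] = json.dumps(r["table"])
    eio.write_table(pd.DataFrame(rows), out / "enrichment.tsv",
                    float_format="%.6g")
    ranking = rank_genes(edges, universe=sorted(universe))
    eio.write_table(ranking, out / "gene_ranking.tsv", float_format="%.6g")


def stage_gsea(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    ranking = eio.read_table(out / "gene_ranking.tsv")
    genesets = eio.read_gmt(_cohort_dir(workdir) / "genesets.gmt")
    res = preranked_gsea(ranking, genesets, n_perm=cfg.n_perm, seed=cfg.seed)
    eio.write_table(res, out / "gsea_results.tsv", float_format="%.6g")


def stage_call(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm, tpm, expressed, _, counts = _quant_state(workdir)
    catalog = read_catalog(workdir)
    gm = eio.read_gtf(cdir / "genes.gtf")
    de_ernas = eio.read_table(out / "de_ernas.tsv").set_index("feature")
    de_genes = eio.read_table(out / "de_genes.tsv").set_index("feature")
    calls, pairs = call_functional(
        de_ernas, de_genes, rpm.loc[expressed], tpm,
        catalog, gm["genes"],
        counts.samples_of("tumor"), counts.samples_of("normal"),
        de_genes["mean_tumor"], de_genes["mean_normal"],
        lfc_min=cfg.lfc_min, alpha=cfg.alpha, tpm_min=cfg.tpm_min,
        window=cfg.window, rho_min=cfg.rho_min,
    )
    eio.write_table(calls, out / "functional_calls.tsv", float_format="%.6g")
    eio.write_table(pairs, out / "functional_pairs.tsv", float_format="%.6g")


def stage_cna(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm, tpm, expressed, _, counts = _quant_state(workdir)
    catalog = read_catalog(workdir)
    gm = eio.read_gtf(cdir / "genes.gtf")
    calls = eio.read_table(out / "functional_calls.tsv")
    segments = eio.read_seg(cdir / "cn_segments.seg")
    annotated = call_cna_activated(
        calls, segments, catalog, gm["genes"], rpm, tpm,
        counts.samples_of("tumor"),
        amp_ratio_min=cfg.amp_ratio_min, rho_min=cfg.rho_min,
        alpha=cfg.alpha, gain_threshold=cfg.gain_threshold,
    )
    eio.write_table(annotated, out / "functional_calls_cna.tsv",
                    float_format="%.6g")


def stage_cluster(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    rpm, _, _, _, counts = _quant_state(workdir)
    calls = eio.read_table(out / "functional_calls_cna.tsv")
    features = [e for e in calls["erna_id"] if e in rpm.index]
    if len(features) < 2:
        raise RuntimeError("fewer than 2 functional eRNAs; cannot cluster")
    tumor = counts.samples_of("tumor")
    # log2(RPM+1): Pearson profile correlation on raw RPM is dominated by
    # the few highest-expressed eRNAs; log stabilises the variance first
    X = np.log2(rpm.loc[features, tumor] + 1.0)
    res = consensus_cluster(
        X, k_range=cfg.k_range, reps=cfg.reps,
        p_item=cfg.p_item, p_feature=cfg.p_feature, seed=cfg.seed,
    )
    k = cfg.chosen_k or res.chosen_k
    # relabel clusters by increasing copy-number burden so "cluster k" is
    # always the most-altered subtype, whatever order Ward emitted
    segments_summary = eio.read_table(out / "genome_alteration.tsv") \
        .set_index("sample")
    raw = res.assignments[k]
    burden_by_cluster = segments_summary.reindex(raw.index) \
        .groupby(raw)["frac_amplified"].mean().sort_values()
    remap = {old: new + 1 for new, old in enumerate(burden_by_cluster.index)}
    res.assignments[k] = raw.map(remap)
    for kk in res.k_range:
        eio.write_matrix(
            pd.DataFrame(res.consensus[kk], index=tumor, columns=tumor),
            out / f"consensus_k{kk}.tsv", float_format="%.4g")
    eio.write_table(
        pd.DataFrame({"k": res.k_range,
                      "cdf_area": [res.cdf_area[kk] for kk in res.k_range],
                      "delta_area": [res.delta_area[kk] for kk in res.k_range],
                      "chosen": [kk == k for kk in res.k_range]}),
        out / "kselect.tsv", float_format="%.6g")
    assign = res.assignments[k].rename_axis("sample").reset_index()
    eio.write_table(assign, out / "assignments.tsv")

    # characterization: mutations, CN burden, demographics
    mutations = eio.read_table(cdir / "mutations.tsv")
    labels = res.assignments[k]
    top_genes = mutations[mutations["non_silent"] == 1]["gene"] \
        .value_counts().head(10).index
    binary = pd.DataFrame(index=labels.index)
    for g in top_genes:
        mutated = set(mutations.loc[(mutations["gene"] == g)
                                    & (mutations["non_silent"] == 1), "sample"])
        binary[f"mut_{g}"] = [s in mutated for s in labels.index]
    meta = counts.sample_meta.loc[labels.index]
    binary["smoker"] = meta["smoking"].astype(bool)
    binary["male"] = meta["gender"].astype(bool)
    cont = segments_summary.loc[labels.index,
                                ["frac_amplified", "frac_deleted",
                                 "n_nonsilent"]]
    char = characterize_clusters(labels, binary, cont)
    eio.write_table(char, out / "characterization.tsv", float_format="%.6g")


def stage_survive(workdir, cfg: RunConfig) -> None:
    out = Path(workdir)
    cdir = _cohort_dir(workdir)
    clinical = eio.read_table(cdir / "clinical.tsv")
    samples = eio.read_table(cdir / "samples.tsv").set_index("sample_id")
    assign = eio.read_table(out / "assignments.tsv").set_index("sample")["cluster"]
    patient_cluster = pd.Series(
        {samples.loc[s, "patient_id"]: c for s, c in assign.items()})
    covs = samples[samples["tissue"] == "tumor"].set_index("patient_id")[
        ["age", "gender", "smoking"]]
    cox_rows, km_rows, lr_rows = [], [], []
    ref = int(patient_cluster.min())
    for ep in ("os", "dfi", "pfi"):
        rec = prepare_records(clinical, patient_cluster, ep, covs)
        try:
            adj = cox_contrasts(rec, ref)
            crude = cox_contrasts(rec, ref, adjust=())
        except ValueError as exc:
            cox_rows.append(dict(endpoint=ep, contrast="error", note=str(exc)))
            continue
        for frame, kind in ((adj, "adjusted"), (crude, "crude")):
            frame = frame.assign(endpoint=ep, model=kind)
            cox_rows.extend(frame.to_dict("records"))
        curves, stat, p = km_logrank(rec)
        km_rows.append(curves.assign(endpoint=ep))
        lr_rows.append(dict(endpoint=ep, statistic=stat, p=p))
    eio.write_table(pd.DataFrame(cox_rows), out / "survival_results.tsv",
                    float_format="%.6g")
    if km_rows:
        eio.write_table(pd.concat(km_rows, ignore_index=True),
                        out / "km_curves.tsv", float_format="%.6g")
    eio.write_table(pd.DataFrame(lr_rows), out / "logrank.tsv",
                    float_format="%.6g")


# ---------------------------------------------------------------- pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    workdir,
    run_config: RunConfig | None = None,
    sim_config: SimConfig | None = None,
    simulate: bool = True,
) -> dict:
    """Run every stage in dependency order and write a run manifest.

    With ``simulate`` the cohort is generated under ``workdir/cohort``;
    otherwise that directory must already hold the input artifacts.
    Returns the manifest dict.
    """
    cfg = run_config or RunConfig()
    cfg.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if simulate:
        sc = sim_config or SimConfig(seed=cfg.seed)
        stage_simulate(workdir, sc)
    cdir = _cohort_dir(workdir)
    required = ["enhancers_A.bed", "enhancers_B.bed", "genes.gtf",
                "erna_counts.tsv", "gene_counts.tsv", "samples.tsv",
                "cn_segments.seg", "mutations.tsv", "clinical.tsv",
                "genesets.gmt"]
    for name in required:
        if not (cdir / name).exists():
            raise FileNotFoundError(cdir / name)
    stage_fns = {
        "annotate": stage_annotate, "quantify": stage_quantify,
        "de": stage_de, "network": stage_network, "gsea": stage_gsea,
        "call": stage_call, "cna": stage_cna, "cluster": stage_cluster,
        "survive": stage_survive,
    }
    for name in STAGES:
        stage_fns[name](workdir, cfg)
    manifest = {
        "package": "ernascope",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "sim_config": asdict(sim_config or SimConfig(seed=cfg.seed))
        if simulate else None,
        "inputs": {name: _sha256(cdir / name) for name in required},
        "stages": list(STAGES),
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
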
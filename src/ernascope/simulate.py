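"""Synthetic paired tumor/normal cohort with planted, recoverable truth.

The generator emulates the statistical structure the pipeline is built to
detect: negative-binomial read counts over a toy genome; globally elevated
tumor eRNA expression; smoking-elevated eRNA expression in normal tissue;
planted differentially-expressed eRNAs whose cis target genes (TSS within
1 Mbp) share a log-normal latent activity factor, inducing a positive rank
correlation with a configurable target; a subset of up-eRNAs driven by
locus copy-number amplification; three sample clusters differing in
functional-eRNA expression signature, mutation load, copy-number burden
and survival.

The latent-factor strength is solved analytically from the target Spearman
(``cis_rho``) via the bivariate-normal Spearman/Pearson relation, taking
the known log-scale variance components (NB noise, cluster offsets, CN
scaling) into account, so the planted correlation lands near its target
without tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .quantification import CountMatrix


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


@dataclass
class SimConfig:
    n_pairs: int = 60
    n_chromosomes: int = 5
    chrom_length: int = 100_000_000
    n_genes: int = 400
    n_enhancers: int = 200
    frac_expressed_enhancers: float = 0.85
    n_functional_up: int = 20
    n_functional_down: int = 10
    n_cna_driven: int = 5
    n_clusters: int = 3
    planted_log2fc: float = 3.0
    cis_rho: float = 0.5
    smoking_effect: float = 1.5
    tumor_global_factor: float = 1.2
    library_size_mean: float = 5e6
    dispersion: float = 0.1
    hazard_ratio_cluster3: float = 2.0
    censoring_rate: float = 0.3
    frac_both_sources: float = 0.8
    cluster_signature_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_functional_up + self.n_functional_down > self.n_enhancers:
            raise ConfigError(
                "n_functional_up + n_functional_down exceeds n_enhancers"
            )
        if self.n_cna_driven > self.n_functional_up:
            raise ConfigError("n_cna_driven exceeds n_functional_up")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        for name in ("n_pairs", "n_chromosomes", "chrom_length", "n_genes",
                     "n_enhancers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("frac_expressed_enhancers", "frac_both_sources"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if not 0 <= self.cis_rho < 1:
            raise ConfigError("cis_rho must be in [0, 1)")


@dataclass
class TruthTables:
    planted_de_ernas: pd.DataFrame      # enhancer_id, direction
    planted_pairs: pd.DataFrame         # enhancer_id, gene_id
    planted_cna_ernas: pd.DataFrame     # enhancer_id
    cluster_labels: pd.Series           # tumor sample -> cluster
    smoking_labels: pd.Series           # patient -> smoker / non-smoker


@dataclass
class Cohort:
    config: SimConfig
    genes: pd.DataFrame
    exons: pd.DataFrame
    source_a: pd.DataFrame
    source_b: pd.DataFrame
    erna_counts: CountMatrix
    gene_counts: CountMatrix
    samples: pd.DataFrame
    segments: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    genesets: dict = field(default_factory=dict)
    truth: TruthTables | None = None


# ------------------------------------------------------------- calibration

_CN_PROBS = {2: 0.5, 3: 0.3, 4: 0.2}

#: sequencing depth at which the per-feature base means are defined; actual
#: per-sample means scale as library_size / _REFERENCE_DEPTH, so deeper
#: cohorts yield proportionally larger counts and unchanged RPM
_REFERENCE_DEPTH = 5e6


def _cn_log_variance() -> float:
    vals = np.log([k / 2 for k in _CN_PROBS])
    p = np.array(list(_CN_PROBS.values()))
    m = (p * vals).sum()
    return float((p * (vals - m) ** 2).sum())


def latent_sd_for_target_rho(
    target_spearman: float, extra_var_erna: float, extra_var_gene: float
) -> float:
    """Shared latent log-sd that yields the target Spearman correlation.

    Solves t / sqrt((t + A)(t + B)) = r for t = a^2, where A and B are the
    non-shared log-scale variances of the two features and r is the Pearson
    correlation corresponding to the target Spearman under bivariate
    normality (r = 2 sin(pi * rho_s / 6)).
    """
    if target_spearman <= 0:
        return 0.0
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    r2 = r * r
    A, B = extra_var_erna, extra_var_gene
    disc = r2 * r2 * (A + B) ** 2 + 4.0 * (1.0 - r2) * r2 * A * B
    t = (r2 * (A + B) + np.sqrt(disc)) / (2.0 * (1.0 - r2))
    return float(np.sqrt(t))


def _nb_log_variance(mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Approximate variance of log(count) for NB(mean, dispersion)."""
    return np.log1p(dispersion + 1.0 / np.maximum(mean, 1e-9))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    n = 1.0 / dispersion
    mean = np.maximum(mean, 1e-9)
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# --------------------------------------------------------------- generator


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort; identical seeds give identical
    cohorts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length

    genes, exons = _make_genes(config, rng, chroms, L)
    enhancers, pair_map = _make_enhancers(config, rng, genes, chroms, L)
    source_a, source_b = _make_sources(config, rng, enhancers, L)

    samples, clusters, patients = _make_samples(config, rng)
    tumor_samples = [s for s in samples.index if samples.loc[s, "tissue"] == "tumor"]

    cna_ids = pair_map["enhancer_id"].iloc[: config.n_cna_driven].tolist() \
        if config.n_cna_driven else []
    cn_states = _make_cn_states(config, rng, cna_ids, tumor_samples)
    segments = _make_segments(config, rng, enhancers, cna_ids, cn_states,
                              clusters, chroms, L)

    erna_counts, gene_counts = _make_counts(
        config, rng, enhancers, genes, pair_map, samples, clusters,
        cna_ids, cn_states,
    )

    mutations, marker_gene = _make_mutations(config, rng, genes, clusters,
                                             pair_map)
    clinical = _make_clinical(config, rng, samples, clusters, patients)
    genesets = _make_genesets(rng, genes, pair_map, marker_gene)

    truth = TruthTables(
        planted_de_ernas=pair_map[["enhancer_id", "direction"]].copy(),
        planted_pairs=pair_map[["enhancer_id", "gene_id"]].copy(),
        planted_cna_ernas=pd.DataFrame({"enhancer_id": cna_ids}),
        cluster_labels=clusters.copy(),
        smoking_labels=samples.drop_duplicates("patient_id")
        .set_index("patient_id")["smoking"]
        .map({1: "smoker", 0: "non-smoker"}),
    )
    meta = samples[["patient_id", "tissue", "age", "gender", "smoking"]]
    libs = samples["library_size"]
    return Cohort(
        config=config,
        genes=genes,
        exons=exons,
        source_a=source_a,
        source_b=source_b,
        erna_counts=CountMatrix(erna_counts, libs, meta),
        gene_counts=CountMatrix(gene_counts, libs, meta),
        samples=samples,
        segments=segments,
        mutations=mutations,
        clinical=clinical,
        genesets=genesets,
        truth=truth,
    )


def _make_genes(config, rng, chroms, L):
    n = config.n_genes
    chrom = rng.choice(len(chroms), size=n)
    length = rng.integers(5_000, 100_000, size=n)
    start = rng.integers(0, L - 200_000, size=n)
    strand = rng.choice(["+", "-"], size=n)
    df = pd.DataFrame(
        {"chrom": [chroms[c] for c in chrom], "start": start,
         "end": start + length, "strand": strand}
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    df["gene_id"] = [f"g{i + 1:04d}" for i in range(n)]
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    exon_rows = []
    for r in df.itertuples(index=False):
        if r.end - r.start <= 3000:
            exon_rows.append((r.chrom, r.start, r.end, r.gene_id))
        else:
            exon_rows.append((r.chrom, r.start, r.start + 1000, r.gene_id))
            exon_rows.append((r.chrom, r.end - 1000, r.end, r.gene_id))
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])
    return df, exons


def _intergenic(genes, chrom, start, end) -> bool:
    sub = genes[genes["chrom"] == chrom]
    return not ((sub["start"] < end) & (sub["end"] > start)).any()


def _make_enhancers(config, rng, genes, chroms, L):
    """Place enhancers; planted functional ones sit intergenic within 1 Mbp
    of a distinct target gene's TSS."""
    n_planted = config.n_functional_up + config.n_functional_down
    target_idx = rng.choice(len(genes), size=n_planted, replace=False)
    rows = []
    for j, gi in enumerate(target_idx):
        g = genes.iloc[gi]
        for _ in range(200):
            d = int(rng.integers(50_000, 700_000))
            side = 1 if rng.random() < 0.5 else -1
            length = int(rng.integers(300, 2000))
            mid = int(g["tss"]) + side * d
            s, e = mid - length // 2, mid + length // 2
            if s < 0 or e > L:
                continue
            if _intergenic(genes, g["chrom"], s, e):
                rows.append((g["chrom"], s, e,
                             "up" if j < config.n_functional_up else "down",
                             g["gene_id"]))
                break
        else:
            raise RuntimeError("could not place a planted intergenic enhancer")
    n_bg = config.n_enhancers - n_planted
    for _ in range(n_bg):
        c = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(300, 2000))
        s = int(rng.integers(0, L - 2000))
        rows.append((c, s, s + length, "none", ""))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "planted_role",
                                     "target_gene"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["id"] = [f"e{i + 1:04d}" for i in range(len(df))]
    planted = df[df["planted_role"] != "none"]
    pair_map = pd.DataFrame(
        {"enhancer_id": planted["id"], "gene_id": planted["target_gene"],
         "direction": planted["planted_role"]}
    )
    # CNA-driven eRNAs are the first up pairs in id order (deterministic)
    pair_map = pd.concat(
        [pair_map[pair_map.direction == "up"],
         pair_map[pair_map.direction == "down"]]
    ).reset_index(drop=True)
    return df, pair_map


def _make_sources(config, rng, enhancers, L):
    source_b = enhancers[["chrom", "start", "end", "id"]].copy()
    source_b["score"] = "."
    source_b["strand"] = "."
    planted = enhancers["planted_role"] != "none"
    supported = planted | (rng.random(len(enhancers)) < config.frac_both_sources)
    rows = []
    for i, r in enumerate(enhancers.itertuples(index=False)):
        if not supported.iloc[i]:
            continue
        j1, j2 = rng.integers(-100, 100, size=2)
        s = max(0, r.start + int(j1))
        e = min(L, r.end + int(j2))
        if e - s < 50:
            s, e = r.start, r.end
        rows.append((r.chrom, s, e, f"a_{r.id}"))
    # distractor A-only regions
    n_extra = config.n_enhancers // 2
    for j in range(n_extra):
        c = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        s = int(rng.integers(0, L - 5000))
        rows.append((c, s, s + int(rng.integers(500, 5000)), f"a_extra{j}"))
    source_a = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    source_a["score"] = "."
    source_a["strand"] = "."
    source_a = source_a.sort_values(["chrom", "start"]).reset_index(drop=True)
    return source_a, source_b


def _make_samples(config, rng):
    n = config.n_pairs
    patients = [f"P{i + 1:03d}" for i in range(n)]
    base = np.repeat(np.arange(1, config.n_clusters + 1),
                     int(np.ceil(n / config.n_clusters)))[:n]
    cluster_of_patient = rng.permuted(base)
    smoker_cluster = min(2, config.n_clusters)
    p_smoke = np.where(cluster_of_patient == smoker_cluster, 0.8, 0.35)
    smoking = (rng.random(n) < p_smoke).astype(int)
    age = np.clip(np.round(rng.normal(62, 8, size=n)), 35, 85).astype(int)
    gender = (rng.random(n) < 0.5).astype(int)
    rows = []
    for i, pat in enumerate(patients):
        for tissue in ("tumor", "normal"):
            lib = float(np.exp(rng.normal(np.log(config.library_size_mean), 0.15)))
            rows.append((f"{pat}{'T' if tissue == 'tumor' else 'N'}", pat,
                         tissue, age[i], gender[i], smoking[i], lib))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "age", "gender",
                       "smoking", "library_size"]
    ).set_index("sample_id")
    clusters = pd.Series(
        {f"{pat}T": int(c) for pat, c in zip(patients, cluster_of_patient)},
        name="cluster",
    )
    return samples, clusters, patients


def _make_cn_states(config, rng, cna_ids, tumor_samples):
    """Integer copy number per (CNA-driven eRNA, tumor sample)."""
    states = {}
    vals = np.array(list(_CN_PROBS))
    probs = np.array(list(_CN_PROBS.values()))
    for eid in cna_ids:
        states[eid] = pd.Series(
            rng.choice(vals, size=len(tumor_samples), p=probs),
            index=tumor_samples,
        )
    return states


def _make_segments(config, rng, enhancers, cna_ids, cn_states, clusters,
                   chroms, L):
    """Per-tumor-sample segmentation with cluster-graded gain/loss rates.

    Background gains and losses avoid a ±2.5 Mbp zone around every planted
    functional enhancer, so locus-level amplification at non-CNA functional
    eRNAs is structurally absent; CNA-driven loci get their own ±2 Mbp
    segment carrying the sample's integer copy number.
    """
    p_gain = {1: 0.03, 2: 0.10, 3: 0.30}
    p_loss = {1: 0.02, 2: 0.07, 3: 0.18}
    planted = enhancers[enhancers["planted_role"] != "none"]
    exclusion = {
        c: [((r.start + r.end) // 2 - 2_500_000, (r.start + r.end) // 2 + 2_500_000)
            for r in sub.itertuples(index=False)]
        for c, sub in planted.groupby("chrom")
    }
    cna_windows: dict[str, list[tuple[int, int, str]]] = {}
    enh_idx = enhancers.set_index("id")
    for eid in cna_ids:
        e = enh_idx.loc[eid]
        mid = (int(e["start"]) + int(e["end"])) // 2
        cna_windows.setdefault(e["chrom"], []).append(
            (max(0, mid - 2_000_000), min(L, mid + 2_000_000), eid)
        )
    rows = []
    for sample in clusters.index:
        cl = int(clusters[sample])
        pg = p_gain.get(cl, p_gain[max(p_gain)])
        pl = p_loss.get(cl, p_loss[max(p_loss)])
        for chrom in chroms:
            cuts = {0, L}
            pos = 0
            while True:
                pos += int(rng.uniform(5e6, 15e6))
                if pos >= L:
                    break
                cuts.add(pos)
            for s, e, _ in cna_windows.get(chrom, []):
                cuts.update((s, e))
            bounds = sorted(cuts)
            for s, e in zip(bounds[:-1], bounds[1:]):
                state = "neutral"
                int_cn = 2
                locus = next(
                    (eid for ws, we, eid in cna_windows.get(chrom, [])
                     if s >= ws and e <= we), None)
                in_excl = any(s < xe and e > xs
                              for xs, xe in exclusion.get(chrom, []))
                u = rng.random()
                if locus is not None:
                    cn = int(cn_states[locus][sample])
                    int_cn = cn
                    state = "gain" if cn > 2 else "neutral"
                    lr = np.log2(cn / 2) + rng.normal(0, 0.02)
                elif in_excl:
                    lr = rng.normal(0, 0.03)
                elif u < pg:
                    state = "gain"
                    int_cn = 3
                    lr = rng.normal(0.6, 0.1)
                elif u < pg + pl:
                    state = "loss"
                    int_cn = 1
                    lr = rng.normal(-0.6, 0.1)
                else:
                    lr = rng.normal(0, 0.03)
                rows.append((sample, chrom, s, e, round(float(lr), 4), int_cn))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "log2ratio",
                       "integer_cn"]
    )


def _make_counts(config, rng, enhancers, genes, pair_map, samples, clusters,
                 cna_ids, cn_states):
    n_e, n_g = len(enhancers), len(genes)
    sample_ids = list(samples.index)
    tumor_mask = (samples["tissue"] == "tumor").to_numpy()
    smoker = samples["smoking"].to_numpy().astype(bool)
    planted_role = enhancers["planted_role"].to_numpy()
    is_planted = planted_role != "none"

    expressed = is_planted | (rng.random(n_e) < config.frac_expressed_enhancers)
    base_e = np.where(
        is_planted,
        np.clip(np.exp(rng.normal(np.log(60), 0.25, n_e)), 30, 150),
        np.clip(np.exp(rng.normal(np.log(30), 1.0, n_e)), 3, 500),
    )
    base_e = np.where(expressed, base_e, 0.02)

    target_ids = set(pair_map["gene_id"])
    is_target = genes["gene_id"].isin(target_ids).to_numpy()
    base_g = np.where(
        is_target,
        np.clip(np.exp(rng.normal(np.log(200), 0.5, n_g)), 50, 1000),
        np.clip(np.exp(rng.normal(np.log(150), 1.0, n_g)), 1, 3000),
    )

    fc = 2.0 ** config.planted_log2fc
    # feature x sample mean matrices
    mu_e = np.tile(base_e[:, None], (1, len(sample_ids)))
    mu_g = np.tile(base_g[:, None], (1, len(sample_ids)))
    # global tumor elevation of expressed, non-planted eRNAs
    glob = expressed & ~is_planted
    mu_e[np.ix_(glob, tumor_mask)] *= config.tumor_global_factor
    # smoking elevation of expressed eRNAs in normal samples of smokers
    smoke_cols = (~tumor_mask) & smoker
    mu_e[np.ix_(expressed, smoke_cols)] *= config.smoking_effect

    eid_pos = {e: i for i, e in enumerate(enhancers["id"])}
    gid_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    for r in pair_map.itertuples(index=False):
        ei, gi = eid_pos[r.enhancer_id], gid_pos[r.gene_id]
        if r.direction == "up":
            mu_e[ei, tumor_mask] = base_e[ei] * fc
            mu_g[gi, tumor_mask] = base_g[gi] * fc
        else:
            mu_e[ei, ~tumor_mask] = base_e[ei] * fc
            mu_g[gi, ~tumor_mask] = base_g[gi] * fc

    # cluster expression signatures on planted functional eRNAs (tumor only)
    cluster_of_col = np.zeros(len(sample_ids), dtype=int)
    for j, s in enumerate(sample_ids):
        if s in clusters.index:
            cluster_of_col[j] = clusters[s]
    # CNA-driven eRNAs carry a copy-number signal instead of a subtype
    # signature; mixing both would leave neither recoverable at toy scale
    sig = rng.normal(0.0, config.cluster_signature_sd,
                     size=(n_e, config.n_clusters + 1))
    # centre each feature's signature across clusters so subtype structure
    # does not shift the overall tumor mean (and hence the fold change)
    sig[:, 1:] -= sig[:, 1:].mean(axis=1, keepdims=True)
    for eid in pair_map["enhancer_id"]:
        if eid in cna_ids:
            continue
        ei = eid_pos[eid]
        mu_e[ei, tumor_mask] *= np.exp(sig[ei, cluster_of_col[tumor_mask]])

    # copy-number scaling of CNA-driven eRNAs
    for eid in cna_ids:
        ei = eid_pos[eid]
        for j, s in enumerate(sample_ids):
            if tumor_mask[j]:
                mu_e[ei, j] *= cn_states[eid][s] / 2.0

    # shared latent activity factors for planted pairs
    cn_var = _cn_log_variance()
    for r in pair_map.itertuples(index=False):
        ei, gi = eid_pos[r.enhancer_id], gid_pos[r.gene_id]
        high_e = base_e[ei] * fc
        high_g = base_g[gi] * fc
        extra_e = float(_nb_log_variance(np.array(high_e), config.dispersion))
        extra_g = float(_nb_log_variance(np.array(high_g), config.dispersion))
        if r.direction == "up":
            if r.enhancer_id in cna_ids:
                extra_e += cn_var
            else:
                extra_e += config.cluster_signature_sd**2
        else:
            # down-pair correlation is read in normal samples, where the
            # smoker/non-smoker multiplier adds unshared eRNA variance
            extra_e += 0.25 * float(np.log(config.smoking_effect)) ** 2
        a = latent_sd_for_target_rho(config.cis_rho, extra_e, extra_g)
        z = rng.normal(0.0, 1.0, size=len(sample_ids))
        factor = np.exp(a * z - a * a / 2.0)
        mu_e[ei] *= factor
        mu_g[gi] *= factor

    # library-size scaling and NB draw
    libs = samples["library_size"].to_numpy()
    scale = libs / _REFERENCE_DEPTH
    counts_e = _nb_draw(rng, mu_e * scale[None, :], config.dispersion)
    counts_g = _nb_draw(rng, mu_g * scale[None, :], config.dispersion)
    erna_counts = pd.DataFrame(counts_e, index=enhancers["id"].to_numpy(),
                               columns=sample_ids)
    gene_counts = pd.DataFrame(counts_g, index=genes["gene_id"].to_numpy(),
                               columns=sample_ids)
    return erna_counts, gene_counts


def _make_mutations(config, rng, genes, clusters, pair_map):
    burden_mean = {1: 4.0, 2: 12.0, 3: 25.0}
    candidates = [g for g in genes["gene_id"]
                  if g not in set(pair_map["gene_id"])]
    marker_gene = candidates[0]  # mutated only in cluster 1
    pool = np.array(candidates[1:])
    rows = []
    for sample in clusters.index:
        cl = int(clusters[sample])
        lam = burden_mean.get(cl, burden_mean[max(burden_mean)])
        k = min(int(rng.poisson(lam)), len(pool))
        for g in rng.choice(pool, size=k, replace=False):
            rows.append((sample, g, int(rng.random() < 0.85)))
        if cl == 1 and rng.random() < 0.5:
            rows.append((sample, marker_gene, 1))
    return (
        pd.DataFrame(rows, columns=["sample", "gene", "non_silent"]),
        marker_gene,
    )


def _make_clinical(config, rng, samples, clusters, patients):
    cluster_of_patient = {p: int(clusters[f"{p}T"]) for p in patients}
    hi_cluster = config.n_clusters  # the high-alteration cluster
    rows = []
    baselines = {"os": np.log(2) / 40.0, "dfi": np.log(2) / 30.0,
                 "pfi": np.log(2) / 25.0}
    for p in patients:
        hr = config.hazard_ratio_cluster3 \
            if cluster_of_patient[p] == hi_cluster else 1.0
        rec = {"patient_id": p}
        for ep, h0 in baselines.items():
            h = h0 * hr
            t_event = rng.exponential(1.0 / h)
            if config.censoring_rate > 0:
                hc = h0 * config.censoring_rate / (1.0 - config.censoring_rate)
                t_cens = rng.exponential(1.0 / hc)
            else:
                t_cens = np.inf
            t_cens = min(t_cens, 120.0)
            rec[f"{ep}_time"] = round(min(t_event, t_cens), 2)
            rec[f"{ep}_event"] = int(t_event <= t_cens)
        rows.append(rec)
    return pd.DataFrame(rows)


def _make_genesets(rng, genes, pair_map, marker_gene):
    universe = list(genes["gene_id"])
    targets = sorted(set(pair_map["gene_id"]))
    others = [g for g in universe if g not in set(targets)]
    cgc = sorted(set(targets) | {marker_gene}
                 | set(rng.choice(others, size=20, replace=False)))
    cag = sorted(set(rng.choice(targets, size=max(3, len(targets) // 2),
                                replace=False))
                 | set(rng.choice(others, size=10, replace=False)))
    sets = {"CGC": cgc, "CAG": cag}
    for i in range(3):
        sets[f"PW_RANDOM_{i + 1}"] = sorted(
            rng.choice(universe, size=30, replace=False))
    return sets


# ------------------------------------------------------- survival-only sim


def simulate_survival(
    n: int, hazard_ratio: float, seed: int, censoring_rate: float = 0.3,
    frac_exposed: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Minimal survival cohort: exponential times, one binary exposure with
    the given hazard ratio, independent censoring, null covariates."""
    rng = np.random.default_rng(seed)
    exposed = rng.random(n) < frac_exposed
    h0 = np.log(2) / 40.0
    h = np.where(exposed, h0 * hazard_ratio, h0)
    t_event = rng.exponential(1.0 / h)
    hc = h0 * censoring_rate / (1.0 - censoring_rate) if censoring_rate else 0
    t_cens = rng.exponential(1.0 / hc, size=n) if hc else np.full(n, np.inf)
    t_cens = np.minimum(t_cens, 120.0)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens) + 1.0,  # keep above 1 month
            "event": (t_event <= t_cens).astype(int),
            "cluster": np.where(exposed, 3, 1),
            "age": np.round(rng.normal(62, 8, n)),
            "gender": (rng.random(n) < 0.5).astype(float),
            "smoking": (rng.random(n) < 0.5).astype(float),
        }
    )


# ------------------------------------------------------------------ output


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every cohort artifact as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_bed(cohort.source_a, out / "enhancers_A.bed")
    eio.write_bed(cohort.source_b, out / "enhancers_B.bed")
    eio.write_gtf(cohort.genes, cohort.exons, out / "genes.gtf")
    eio.write_matrix(cohort.erna_counts.values, out / "erna_counts.tsv")
    eio.write_matrix(cohort.gene_counts.values, out / "gene_counts.tsv")
    samples = cohort.samples.reset_index()
    samples["library_size"] = samples["library_size"].round(1)
    eio.write_table(samples, out / "samples.tsv")
    eio.write_seg(cohort.segments, out / "cn_segments.seg")
    eio.write_table(cohort.mutations, out / "mutations.tsv")
    eio.write_table(cohort.clinical, out / "clinical.tsv")
    eio.write_gmt(cohort.genesets, out / "genesets.gmt")
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    t = cohort.truth
    eio.write_table(t.planted_de_ernas, tdir / "planted_de_ernas.tsv")
    eio.write_table(t.planted_pairs, tdir / "planted_pairs.tsv")
    eio.write_table(t.planted_cna_ernas, tdir / "planted_cna_ernas.tsv")
    eio.write_table(
        t.cluster_labels.rename_axis("sample").reset_index(),
        tdir / "cluster_labels.tsv",
    )
    eio.write_table(
        t.smoking_labels.rename("smoking").rename_axis("patient").reset_index(),
        tdir / "smoking_labels.tsv",
    )


def read_cohort(indir) -> Cohort:
    """Load a written cohort back (truth included if present)."""
    ind = Path(indir)
    gm = eio.read_gtf(ind / "genes.gtf")
    samples = eio.read_table(ind / "samples.tsv").set_index("sample_id")
    meta = samples[["patient_id", "tissue", "age", "gender", "smoking"]]
    libs = samples["library_size"]
    erna = CountMatrix(eio.read_matrix(ind / "erna_counts.tsv"), libs, meta)
    gene = CountMatrix(eio.read_matrix(ind / "gene_counts.tsv"), libs, meta)
    truth = None
    tdir = ind / "truth"
    if tdir.exists():
        cl = eio.read_table(tdir / "cluster_labels.tsv")
        sm = eio.read_table(tdir / "smoking_labels.tsv")
        truth = TruthTables(
            planted_de_ernas=eio.read_table(tdir / "planted_de_ernas.tsv"),
            planted_pairs=eio.read_table(tdir / "planted_pairs.tsv"),
            planted_cna_ernas=eio.read_table(tdir / "planted_cna_ernas.tsv"),
            cluster_labels=cl.set_index("sample")["cluster"],
            smoking_labels=sm.set_index("patient")["smoking"],
        )
    return Cohort(
        config=SimConfig(),
        genes=gm["genes"],
        exons=gm["exons"],
        source_a=eio.read_bed(ind / "enhancers_A.bed"),
        source_b=eio.read_bed(ind / "enhancers_B.bed"),
        erna_counts=erna,
        gene_counts=gene,
        samples=samples,
        segments=eio.read_seg(ind / "cn_segments.seg"),
        mutations=eio.read_table(ind / "mutations.tsv"),
        clinical=eio.read_table(ind / "clinical.tsv"),
        genesets=eio.read_gmt(ind / "genesets.gmt"),
        truth=truth,
    )
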
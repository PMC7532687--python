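"""Generator contracts: determinism, validation, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ernascope.simulate import (ConfigError, SimConfig, generate_cohort,
                                latent_sd_for_target_rho, simulate_survival,
                                write_cohort)


def test_same_seed_identical_outputs(tmp_path):
    c1 = generate_cohort(SimConfig(seed=5))
    c2 = generate_cohort(SimConfig(seed=5))
    pd.testing.assert_frame_equal(c1.erna_counts.values, c2.erna_counts.values)
    pd.testing.assert_frame_equal(c1.gene_counts.values, c2.gene_counts.values)
    pd.testing.assert_frame_equal(c1.segments, c2.segments)
    write_cohort(c1, tmp_path / "a")
    write_cohort(c2, tmp_path / "b")
    for f in sorted((tmp_path / "a").rglob("*")):
        if f.is_file():
            other = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == other.read_bytes(), f.name


def test_different_seeds_differ():
    c1 = generate_cohort(SimConfig(seed=5))
    c2 = generate_cohort(SimConfig(seed=6))
    assert not c1.erna_counts.values.equals(c2.erna_counts.values)


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(n_functional_up=150, n_functional_down=100), "n_enhancers"),
        (dict(n_clusters=1), "n_clusters"),
        (dict(n_cna_driven=25, n_functional_up=20), "n_cna_driven"),
        (dict(dispersion=0.0), "dispersion"),
        (dict(frac_expressed_enhancers=0.0), "frac_expressed_enhancers"),
        (dict(censoring_rate=1.5), "censoring_rate"),
    ],
)
def test_invalid_config_names_field(kwargs, field):
    with pytest.raises(ConfigError, match=field):
        generate_cohort(SimConfig(**kwargs))


def test_planted_pairs_within_one_mbp_and_truth_consistency(cohort):
    truth = cohort.truth
    enh = cohort.source_b.set_index("id")
    genes = cohort.genes.set_index("gene_id")
    for r in truth.planted_pairs.itertuples(index=False):
        e = enh.loc[r.enhancer_id]
        mid = (e["start"] + e["end"]) // 2
        g = genes.loc[r.gene_id]
        assert e["chrom"] == g["chrom"]
        assert abs(g["tss"] - mid) <= 1e6
    # every planted pair's enhancer appears among the planted DE eRNAs
    assert set(truth.planted_pairs["enhancer_id"]) <= \
        set(truth.planted_de_ernas["enhancer_id"])
    # cluster labels cover all tumor samples
    tumor = cohort.samples.index[cohort.samples["tissue"] == "tumor"]
    assert set(tumor) == set(truth.cluster_labels.index)


def test_planted_cis_rho_near_target():
    """Monte-Carlo check of the latent-factor construction: mean Spearman
    over planted pairs in the correlation-bearing tissue is 0.5 +/- 0.15."""
    cfg = SimConfig(n_pairs=60, n_functional_up=20, cis_rho=0.5, seed=7)
    co = generate_cohort(cfg)
    tumor = [s for s in co.samples.index if co.samples.loc[s, "tissue"] == "tumor"]
    normal = [s for s in co.samples.index if co.samples.loc[s, "tissue"] == "normal"]
    merged = co.truth.planted_pairs.merge(co.truth.planted_de_ernas,
                                          on="enhancer_id")
    rhos = []
    for r in merged.itertuples(index=False):
        cols = tumor if r.direction == "up" else normal
        rhos.append(spearmanr(co.erna_counts.values.loc[r.enhancer_id, cols],
                              co.gene_counts.values.loc[r.gene_id, cols]).statistic)
    assert np.mean(rhos) == pytest.approx(0.5, abs=0.15)


def test_planted_fold_change_magnitude(cohort):
    """Planted up-eRNAs average ~2^3 x the normal-sample mean."""
    pairs = cohort.erna_counts.pairs()
    rpm = cohort.erna_counts.values / (cohort.erna_counts.library_sizes / 1e6)
    ups = cohort.truth.planted_de_ernas.query("direction == 'up'")["enhancer_id"]
    lfc = np.log2(
        (rpm.loc[ups, pairs["tumor"]].mean(axis=1) + 0.01)
        / (rpm.loc[ups, pairs["normal"]].mean(axis=1) + 0.01)
    )
    assert lfc.mean() == pytest.approx(3.0, abs=0.5)
    assert (lfc >= 2.0).all()


def test_cna_erna_amplification_ratio(cohort):
    """Planted CNA loci are amplified in >= 10% of tumor samples."""
    segs = cohort.segments
    enh = cohort.source_b.set_index("id")
    tumor_n = (cohort.samples["tissue"] == "tumor").sum()
    for eid in cohort.truth.planted_cna_ernas["enhancer_id"]:
        e = enh.loc[eid]
        over = segs[(segs["chrom"] == e["chrom"]) & (segs["start"] < e["end"])
                    & (segs["end"] > e["start"]) & (segs["integer_cn"] > 2)]
        assert over["sample"].nunique() / tumor_n >= 0.10


def test_library_size_invariance_of_rpm():
    """Doubling the mean library size leaves RPM expectations unchanged."""
    a = generate_cohort(SimConfig(seed=9))
    b = generate_cohort(SimConfig(seed=9, library_size_mean=1e7))
    rpm_a = a.erna_counts.values / (a.erna_counts.library_sizes / 1e6)
    rpm_b = b.erna_counts.values / (b.erna_counts.library_sizes / 1e6)
    expressed = rpm_a.mean(axis=1) > 1
    ratio = rpm_b.mean(axis=1)[expressed] / rpm_a.mean(axis=1)[expressed]
    assert ratio.mean() == pytest.approx(1.0, abs=0.05)


def test_latent_sd_solver_inverts_correlation():
    # with variances A and B, the solved t reproduces the requested Pearson
    for rho_s, A, B in [(0.5, 0.9, 0.3), (0.3, 0.2, 0.2), (0.7, 0.5, 1.0)]:
        a = latent_sd_for_target_rho(rho_s, A, B)
        t = a * a
        r = 2 * np.sin(np.pi * rho_s / 6)
        assert t / np.sqrt((t + A) * (t + B)) == pytest.approx(r, rel=1e-9)
    assert latent_sd_for_target_rho(0.0, 1.0, 1.0) == 0.0


def test_survival_generator_hazard_and_censoring():
    rec = simulate_survival(4000, 2.0, seed=1, censoring_rate=0.3)
    assert rec["time"].min() >= 1.0
    exposed = rec["cluster"] == 3
    # crude event-rate ratio tracks the hazard ratio
    assert 0.3 < rec.loc[~exposed, "event"].mean() < 0.9
    assert rec.loc[exposed, "event"].mean() > rec.loc[~exposed, "event"].mean()
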
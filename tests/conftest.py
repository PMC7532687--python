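"""Shared fixtures: one default synthetic cohort and one full pipeline run
per session, so integration-level tests don't regenerate them."""

import numpy as np
import pandas as pd
import pytest

from ernascope import RunConfig, SimConfig, generate_cohort, run_pipeline

#: single session seed for every seeded fixture
SEED = 1


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(SimConfig(seed=SEED))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect switched off."""
    return generate_cohort(
        SimConfig(seed=3, planted_log2fc=0.0, smoking_effect=1.0, cis_rho=0.0,
                  tumor_global_factor=1.0, cluster_signature_sd=0.0,
                  n_cna_driven=0)
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline on the default cohort (consensus reps reduced to 200)."""
    workdir = tmp_path_factory.mktemp("pipeline")
    run_pipeline(workdir, RunConfig(seed=SEED, reps=200), simulate=True)
    return workdir


@pytest.fixture()
def toy_gene_model():
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [1000, 8000, 2000],
            "end": [5000, 12000, 6000],
            "strand": ["+", "-", "+"],
            "gene_id": ["gA", "gB", "gC"],
        }
    )
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    exons = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [1000, 4000, 8000, 2000],
            "end": [2000, 5000, 9000, 3000],
            "gene_id": ["gA", "gA", "gB", "gC"],
        }
    )
    return {"genes": genes, "exons": exons}


def intervals(rows):
    """Helper: build an interval frame from (chrom, start, end[, id])."""
    out = []
    for i, r in enumerate(rows):
        chrom, start, end = r[:3]
        name = r[3] if len(r) > 3 else f"iv{i}"
        out.append((chrom, start, end, name, ".", "."))
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "id", "score", "strand"]
    )
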
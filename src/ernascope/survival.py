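"""Cluster-outcome association: Cox proportional hazards and Kaplan-Meier.

Cox models contrast each cluster against a reference cluster with
adjustment for age, gender and smoking (Efron tie handling); both adjusted
and unadjusted (crude) contrasts are reported.  Patients followed for less
than one month are excluded before any fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

ENDPOINTS = ("os", "dfi", "pfi")
MIN_FOLLOWUP_MONTHS = 1.0


def prepare_records(
    clinical: pd.DataFrame,
    clusters: pd.Series,
    endpoint: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge follow-up, cluster labels and covariates for one endpoint.

    Drops patients with follow-up below one month or missing endpoint data.
    """
    endpoint = endpoint.lower()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    df = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    rec = pd.DataFrame(
        {
            "time": df[f"{endpoint}_time"].astype(float),
            "event": df[f"{endpoint}_event"].astype(float),
            "cluster": clusters.reindex(df.index),
        }
    )
    if covariates is not None:
        rec = rec.join(covariates.reindex(df.index))
    rec = rec.dropna(subset=["time", "event", "cluster"])
    rec = rec[rec["time"] >= MIN_FOLLOWUP_MONTHS]
    rec["cluster"] = rec["cluster"].astype(int)
    return rec


def cox_contrasts(
    records: pd.DataFrame,
    reference_cluster: int,
    adjust: tuple[str, ...] = ("age", "gender", "smoking"),
) -> pd.DataFrame:
    """HR, 95% CI and Wald p for each non-reference cluster.

    ``records`` needs time, event, cluster and any adjustment covariates.
    Raises when a cluster has no events (the partial likelihood cannot
    identify its contrast).
    """
    clusters = sorted(records["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    for c in clusters:
        if records.loc[records["cluster"] == c, "event"].sum() == 0:
            raise ValueError(f"cluster {c} has no events; contrast not estimable")
    X = pd.DataFrame({"time": records["time"], "event": records["event"]})
    contrast_cols = []
    for c in clusters:
        if c == reference_cluster:
            continue
        col = f"cluster_{c}"
        X[col] = (records["cluster"] == c).astype(float)
        contrast_cols.append((c, col))
    covs = [c for c in adjust if c in records.columns]
    for c in covs:
        X[c] = pd.to_numeric(records[c], errors="raise").astype(float)
    cph = CoxPHFitter()
    cph.fit(X, duration_col="time", event_col="event",
            fit_options={"precision": 1e-12})
    summ = cph.summary
    rows = []
    for c, col in contrast_cols:
        s = summ.loc[col]
        rows.append(
            dict(
                contrast=f"cluster {c} vs {reference_cluster}",
                cluster=c,
                hr=float(np.exp(s["coef"])),
                ci_low=float(np.exp(s["coef lower 95%"])),
                ci_high=float(np.exp(s["coef upper 95%"])),
                p=float(s["p"]),
                n=len(X),
                n_events=int(records["event"].sum()),
                adjusted=",".join(covs) if covs else "none",
            )
        )
    return pd.DataFrame(rows)


def km_logrank(records: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curves per cluster plus the multigroup log-rank test.

    Returns (curves, chi-square statistic, p); curves carry group, time,
    at-risk count and survival probability.
    """
    curves = []
    for c, sub in records.groupby("cluster"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(c))
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves.append(
            pd.DataFrame(
                {
                    "group": c,
                    "time": surv.index,
                    "at_risk": tbl["at_risk"].reindex(surv.index).to_numpy(),
                    "survival": surv.to_numpy(),
                }
            )
        )
    res = multivariate_logrank_test(
        records["time"], records["cluster"], records["event"]
    )
    return (
        pd.concat(curves, ignore_index=True),
        float(res.test_statistic),
        float(res.p_value),
    )
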
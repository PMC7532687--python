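"""Resampling consensus clustering of samples over eRNA expression.

Each repetition subsamples a fraction of samples and features without
replacement, computes 1 - Pearson correlation distances between sample
profiles over the drawn features, and cuts a Ward dendrogram at each k.
The consensus matrix entry for a sample pair is the number of times the
pair co-clustered over the number of times it was co-sampled.  k is
selected by the elbow of the consensus CDF area (largest relative gain in
area), and final assignments come from Ward clustering of 1 - consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import fisher_2x2


@dataclass
class ConsensusResult:
    k_range: list[int]
    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    assignments: dict[int, pd.Series]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    cluster_consensus: dict[int, dict[int, float]] = field(default_factory=dict)

    def assignment(self, k: int | None = None) -> pd.Series:
        return self.assignments[self.chosen_k if k is None else k]


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (sample profiles)."""
    Z = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt((Z**2).sum(axis=0))
    norms[norms == 0] = 1.0
    C = (Z / norms).T @ (Z / norms)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    x = np.sort(values)
    n = len(x)
    if n == 0:
        return 0.0
    grid = np.concatenate([x, [1.0]])
    cdf = np.arange(1, n + 1) / n
    return float(np.sum(np.diff(grid) * cdf))


def consensus_cluster(
    X: pd.DataFrame,
    k_range=range(2, 7),
    reps: int = 1000,
    p_item: float = 0.7,
    p_feature: float = 0.7,
    seed: int = 0,
    mean_center: bool = True,
) -> ConsensusResult:
    """Consensus clustering of the columns (samples) of ``X``.

    Features (rows) are mean-centred across samples before resampling.
    Per-repetition RNG substreams are derived from (seed, rep) so the
    repetitions are order-independent.
    """
    k_range = sorted(k_range)
    n_feat, n = X.shape
    if n_feat < 2:
        raise ValueError("need at least 2 features")
    if n < max(k_range) + 2:
        raise ValueError("need at least max(k_range)+2 samples")
    M = X.to_numpy(dtype=float)
    if mean_center:
        M = M - M.mean(axis=1, keepdims=True)
    n_item = ceil(p_item * n)
    n_sub_feat = max(2, ceil(p_feature * n_feat))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for rep in range(reps):
        for attempt in range(10):
            rng = np.random.default_rng([seed, rep, attempt])
            items = np.sort(rng.choice(n, size=n_item, replace=False))
            feats = rng.choice(n_feat, size=n_sub_feat, replace=False)
            if n_item >= max(k_range):
                break
        else:
            raise RuntimeError("could not draw a subsample large enough for max(k)")
        D = _pearson_distance(M[np.ix_(feats, items)])
        Z = linkage(squareform(D, checks=False), method="ward")
        co_sampled[np.ix_(items, items)] += 1
        for k in k_range:
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(items, items)] += same

    with np.errstate(invalid="ignore"):
        consensus = {
            k: np.where(co_sampled > 0, co_cluster[k] / np.maximum(co_sampled, 1), 0.0)
            for k in k_range
        }

    assignments, cdf_area, cluster_consensus = {}, {}, {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        Ck = consensus[k]
        Z = linkage(squareform(1.0 - Ck, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
        assignments[k] = pd.Series(labels, index=X.columns, name="cluster")
        cdf_area[k] = _cdf_area(Ck[iu])
        cluster_consensus[k] = {
            int(c): float(Ck[np.ix_(labels == c, labels == c)][
                np.triu_indices((labels == c).sum(), k=1)
            ].mean()) if (labels == c).sum() > 1 else 1.0
            for c in np.unique(labels)
        }

    delta = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta[k] = cdf_area[k]
        else:
            prev = cdf_area[k_range[i - 1]]
            delta[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    chosen_k = max(k_range, key=lambda k: delta[k])

    return ConsensusResult(
        k_range=list(k_range),
        sample_ids=list(X.columns),
        consensus=consensus,
        assignments=assignments,
        cdf_area=cdf_area,
        delta_area=delta,
        chosen_k=chosen_k,
        cluster_consensus=cluster_consensus,
    )


def characterize_clusters(
    assignments: pd.Series,
    binary_attrs: pd.DataFrame | None = None,
    continuous_attrs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-vs-rest Fisher tests for binary attributes and
    Kruskal-Wallis tests across clusters for continuous burdens.

    Constant attributes are skipped with a note row (test='skipped').
    """
    rows = []
    clusters = sorted(assignments.unique())
    if binary_attrs is not None:
        B = binary_attrs.reindex(assignments.index)
        for attr in B.columns:
            v = B[attr].astype(bool)
            if v.nunique() < 2:
                rows.append(dict(attribute=attr, cluster=None, test="skipped",
                                 statistic=np.nan, p=np.nan,
                                 note="constant attribute"))
                continue
            for c in clusters:
                inc = assignments == c
                table = [
                    [int((v & inc).sum()), int((~v & inc).sum())],
                    [int((v & ~inc).sum()), int((~v & ~inc).sum())],
                ]
                odds, p = fisher_2x2(table)
                rows.append(dict(attribute=attr, cluster=c, test="fisher",
                                 statistic=odds, p=p, note=""))
    if continuous_attrs is not None:
        C = continuous_attrs.reindex(assignments.index)
        for attr in C.columns:
            groups = [C.loc[assignments == c, attr].dropna() for c in clusters]
            if C[attr].nunique() < 2:
                rows.append(dict(attribute=attr, cluster=None, test="skipped",
                                 statistic=np.nan, p=np.nan,
                                 note="constant attribute"))
                continue
            stat, p = sps.kruskal(*groups)
            rows.append(dict(attribute=attr, cluster=None, test="kruskal",
                             statistic=float(stat), p=float(p), note=""))
    return pd.DataFrame(rows)
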
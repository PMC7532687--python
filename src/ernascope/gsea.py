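"""Preranked gene-set enrichment analysis, implemented from scratch.

The enrichment score walks the ranked gene list: hitting a set member
increments the running sum by that gene's weight (|score|^p, normalised
over set members), missing decrements by 1/(N - set size); ES is the
signed maximum deviation from zero.  Significance comes from gene-label
permutations: NES divides ES by the mean |null ES| of matching sign, p is
(1 + #null of the same sign at least as extreme) / (n_perm + 1), and FDR
follows the positive/negative NES-pooling procedure of the original
method.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_total: int):
    """ES for each row of hit ``positions`` (0-based, sorted ascending).

    ``weights`` holds the per-hit weights in ranking order for each row.
    Returns (es, argmax position of the extreme deviation) per row.
    """
    n_perm, k = positions.shape
    miss = 1.0 / (n_total - k)
    weights = np.asarray(weights, dtype=float)
    zero_rows = weights.sum(axis=1) == 0
    if zero_rows.any():            # all-zero scores: fall back to equal weights
        weights = np.where(zero_rows[:, None], 1.0, weights)
    cumw = np.cumsum(weights, axis=1)
    cumw = cumw / cumw[:, -1:]
    j = np.arange(k)[None, :]
    after = cumw - (positions - j) * miss          # just after each hit
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cumw[:, :-1]], axis=1
    ) - (positions - j) * miss                     # just before each hit
    pos_ext = after.max(axis=1)
    neg_ext = before.min(axis=1)
    es = np.where(pos_ext >= -neg_ext, pos_ext, neg_ext)
    arg_pos = after.argmax(axis=1)
    arg_neg = before.argmin(axis=1)
    arg = np.where(pos_ext >= -neg_ext, arg_pos, arg_neg)
    return es, arg


def enrichment_score(
    ranked: pd.DataFrame, geneset, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set along a ranked list, plus the full running sum.

    ``ranked`` has columns gene_id and score, ordered best-first.
    """
    genes = list(ranked["gene_id"])
    scores = np.abs(ranked["score"].to_numpy(dtype=float)) ** weight
    members = set(geneset) & set(genes)
    n = len(genes)
    if not members:
        raise ValueError("gene set has no overlap with the ranking")
    if len(members) == n:
        raise ValueError("gene set covers the whole ranking; ES is degenerate")
    hit = np.array([g in members for g in genes])
    w = scores[hit]
    if w.sum() == 0:
        w = np.ones(hit.sum())  # all-zero scores: unweighted walk
    running = np.where(hit, 0.0, -1.0 / (n - hit.sum()))
    running[hit] = w / w.sum()
    running = np.cumsum(running)
    positions = np.nonzero(hit)[0][None, :]
    es, _ = _es_from_positions(positions, w[None, :], n)
    return float(es[0]), running


def preranked_gsea(
    ranked: pd.DataFrame,
    genesets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation-based preranked enrichment over a collection of sets."""
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable FDR estimates")
    rng = np.random.default_rng(seed)
    genes = list(ranked["gene_id"])
    n = len(genes)
    absw = np.abs(ranked["score"].to_numpy(dtype=float)) ** weight
    if absw.sum() == 0:
        absw = np.ones(n)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in genesets.items():
        idx = sorted(gene_pos[g] for g in set(members) if g in gene_pos)
        k = len(idx)
        if k < min_size or k > max_size or k == n:
            warnings.warn(f"gene set {name!r} skipped (effective size {k})")
            continue
        positions = np.array(idx)[None, :]
        es, arg = _es_from_positions(positions, absw[positions], n)
        es, arg = float(es[0]), int(arg[0])
        if es >= 0:
            leading = [genes[i] for i in idx[: arg + 1]]
        else:
            leading = [genes[i] for i in idx[arg:]]
        # null: random hit positions of the same size
        perm_pos = np.sort(
            np.argsort(rng.random((n_perm, n)), axis=1)[:, :k], axis=1
        )
        null_es, _ = _es_from_positions(perm_pos, absw[perm_pos], n)
        pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        norm = pos_mean if es >= 0 else neg_mean
        nes = es / norm if norm and not np.isnan(norm) else np.nan
        same_sign = null_es >= 0 if es >= 0 else null_es <= 0
        extreme = same_sign & (np.abs(null_es) >= abs(es))
        p = (1 + int(extreme.sum())) / (n_perm + 1)
        null_nes = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
        null_nes_pool.append(null_nes[~np.isnan(null_nes)])
        rows.append(
            dict(set_name=name, size=k, es=es, nes=nes, p=p,
                 leading_edge=",".join(leading))
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res.reindex(columns=["set_name", "size", "es", "nes", "p", "fdr",
                                    "leading_edge"])
    pool = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()
    fdrs = []
    for nes in obs:
        if np.isnan(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            null_frac = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
            obs_frac = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_frac = (pool <= nes).sum() / max((pool <= 0).sum(), 1)
            obs_frac = (obs <= nes).sum() / max((obs <= 0).sum(), 1)
        fdrs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan)
    res["fdr"] = fdrs
    return res[["set_name", "size", "es", "nes", "p", "fdr", "leading_edge"]]
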
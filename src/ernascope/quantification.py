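"""Expression filtering and normalisation for eRNA and gene count matrices.

A feature counts as transcribed when its raw read count exceeds
``min_count`` in strictly more than ``min_frac`` of tumor samples or of
normal samples (both comparisons strict).  Counts are normalised to RPM
(reads per million mapped) for eRNAs; TPM is used where a length- and
depth-normalised threshold is needed for genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Raw counts (features x samples) with per-sample depth and metadata.

    ``sample_meta`` is indexed by sample ID and must carry at least
    ``patient_id`` and ``tissue`` ('tumor' / 'normal'); ``library_sizes``
    is total mapped reads per sample.
    """

    values: pd.DataFrame
    library_sizes: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.values = self.values.loc[:, list(self.values.columns)]
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        self.sample_meta = self.sample_meta.reindex(self.values.columns)
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValueError(f"missing library sizes for samples: {missing[:5]}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        dup = self.sample_meta.groupby(["patient_id", "tissue"]).size()
        if (dup > 1).any():
            raise ValueError("a patient may have at most one tumor and one normal sample")

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["tissue"] == tissue])

    def pairs(self) -> pd.DataFrame:
        """Complete tumor/normal pairs: patient_id -> (tumor, normal) sample IDs."""
        wide = (
            self.sample_meta.reset_index(names="sample_id")
            .pivot(index="patient_id", columns="tissue", values="sample_id")
        )
        return wide.dropna(subset=["tumor", "normal"])[["tumor", "normal"]]


def filter_expressed(
    counts: CountMatrix, min_count: int = 1, min_frac: float = 0.10
) -> list[str]:
    """IDs of features transcribed in either tissue group.

    Kept iff the fraction of tumor samples with count > ``min_count`` is
    strictly greater than ``min_frac``, or the same holds among normal
    samples.
    """
    tumor = counts.samples_of("tumor")
    normal = counts.samples_of("normal")
    if not tumor or not normal:
        raise ValueError("both tumor and normal samples are required")
    frac_t = (counts.values[tumor] > min_count).sum(axis=1) / len(tumor)
    frac_n = (counts.values[normal] > min_count).sum(axis=1) / len(normal)
    keep = (frac_t > min_frac) | (frac_n > min_frac)
    return list(counts.values.index[keep])


def normalize_rpm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per million mapped reads: count / (library_size / 1e6)."""
    return counts.values / (counts.library_sizes / 1e6)


def normalize_tpm(counts: CountMatrix, feature_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million over the given features.

    Per-kilobase rates are renormalised so every sample column sums to 1e6;
    an all-zero sample stays all-zero (with a warning).
    """
    lengths = feature_lengths.reindex(counts.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("feature lengths must be present and positive")
    rate = counts.values.div(lengths / 1e3, axis=0)
    total = rate.sum(axis=0)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s) left all-zero in TPM")
        total = total.replace(0, np.nan)
    tpm = rate / total * 1e6
    return tpm.fillna(0.0)


def global_erna_expression(rpm: pd.DataFrame, expressed: list[str]) -> pd.Series:
    """Per-sample global eRNA expression.

    Total RPM over all expressed eRNAs, scaled by the number of expressed
    eRNAs — i.e. the mean RPM over the expressed set.
    """
    if len(expressed) == 0:
        raise ValueError("expressed eRNA set is empty")
    missing = set(expressed) - set(rpm.index)
    if missing:
        raise ValueError(f"expressed features absent from matrix: {sorted(missing)[:5]}")
    return rpm.loc[list(expressed)].sum(axis=0) / len(expressed)
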
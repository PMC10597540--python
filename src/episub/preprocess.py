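"""Batch-wise standardization and near-zero-variance feature filtering.

Quantified expression (CPM/TPM) is scaled and centred within each
processing batch to absorb batch effects, low-information features are
removed by a frequency-ratio / unique-percent rule, and the retained
matrix is scaled and centred once more across the whole cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CohortMetadata, ExpressionMatrix

log = logging.getLogger(__name__)


def scale_center(
    matrix: ExpressionMatrix,
    metadata: CohortMetadata | None = None,
    by_batch: bool = False,
) -> ExpressionMatrix:
    """Standardize each feature to mean 0, SD 1 (n-1 denominator).

    With ``by_batch`` the transform is applied separately within each
    processing batch. A feature with zero variance within a stratum — or a
    stratum holding a single sample, where the SD is undefined — maps to 0
    there.
    """
    values = matrix.values
    if by_batch:
        if metadata is None:
            raise ValueError("by_batch scaling requires metadata with batch labels")
        batches = metadata.table.loc[values.columns, "batch"]
        out = pd.DataFrame(
            np.zeros_like(values, dtype=float), index=values.index, columns=values.columns
        )
        for batch, cols in values.columns.to_series().groupby(batches, observed=True):
            if len(cols) == 1:
                log.warning(
                    "batch %r holds a single sample; its stratum is set to 0", batch
                )
                out.loc[:, cols] = 0.0
                continue
            out.loc[:, cols] = _standardize(values.loc[:, cols])
        scaled = out
    else:
        scaled = _standardize(values)
    return ExpressionMatrix(scaled, matrix.modality, "scaled")


def _standardize(block: pd.DataFrame) -> pd.DataFrame:
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    centered = block.sub(mean, axis=0)
    out = centered.div(sd.where(sd > 0), axis=0)
    return out.fillna(0.0)


def near_zero_variance_filter(
    matrix: ExpressionMatrix,
    freq_cut: float = 19.0,
    unique_cut: float = 10.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop features whose value distribution is nearly degenerate.

    A feature is removed iff the count of its most frequent value divided
    by the count of its second most frequent value is >= ``freq_cut`` AND
    its percentage of distinct values among samples is <= ``unique_cut``.
    A feature with a single distinct value is always removed. Continuous
    values are rounded to 8 significant digits before counting so float
    noise cannot defeat the rule.
    """
    values = matrix.values
    n = values.shape[1]
    removed: list[str] = []
    keep: list[str] = []
    arr = np.asarray(values, dtype=float)
    for i, fid in enumerate(values.index):
        row = _round_sig(arr[i], 8)
        _, counts = np.unique(row, return_counts=True)
        if counts.size == 1:
            removed.append(fid)
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_pct = counts.size / n * 100.0
        if freq_ratio >= freq_cut and unique_pct <= unique_cut:
            removed.append(fid)
        else:
            keep.append(fid)
    filtered = ExpressionMatrix(values.loc[keep], matrix.modality, matrix.unit)
    return filtered, removed


def _round_sig(x: np.ndarray, digits: int) -> np.ndarray:
    out = x.copy()
    nz = out != 0
    mag = np.floor(np.log10(np.abs(out[nz])))
    out[nz] = np.round(out[nz] / 10.0**mag, digits - 1) * 10.0**mag
    return out


def preprocess_pipeline(
    matrix: ExpressionMatrix,
    metadata: CohortMetadata,
    freq_cut: float = 19.0,
    unique_cut: float = 10.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Batch-wise scaling, variance filtering, then cohort-wide rescaling.

    Returns the final scaled matrix and the removed feature ids.
    """
    scaled = scale_center(matrix, metadata, by_batch=True)
    filtered, removed = near_zero_variance_filter(scaled, freq_cut, unique_cut)
    final = scale_center(filtered, metadata, by_batch=False)
    return final, removed
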
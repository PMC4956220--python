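"""Naive change-vector ranking used as the comparison baseline.

The baseline skips neighbourhood normalization entirely: change vectors are
column-standardized across all genes (subtract the mean, divide by the sample
standard deviation of each feature), scored by RMS over the localization
features, and ranked descending.  It is sensitive to global effects — a
feature shift that hits one localization cluster inflates every gene in that
cluster — which is exactly the failure mode the kNN method corrects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import ChangeMatrix, _lex_rank
from .profiles import localization_mask

logger = logging.getLogger(__name__)


@dataclass
class StandardizedChangeMatrix:
    """Column-standardized change values plus the per-column statistics used."""

    gene_ids: list[str]
    values: np.ndarray
    feature_labels: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray  # sample SD, n-1 denominator


def standardize_change(change: ChangeMatrix) -> StandardizedChangeMatrix:
    """Standardize each feature column to mean 0 and sample SD 1.

    A zero-SD column carries no between-gene signal; its standardized values
    are set to 0 (logged) rather than raising.
    """
    if len(change.gene_ids) < 2:
        raise ValueError("need at least 2 genes for a sample standard deviation")
    means = change.values.mean(axis=0)
    sds = change.values.std(axis=0, ddof=1)
    # relative tolerance: a numerically constant column has SD ~ eps * |mean|
    zero = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
    if zero.any():
        logger.warning("%d zero-variance feature column(s) contribute 0 after standardization",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, sds)
    values = (change.values - means) / safe
    values[:, zero] = 0.0
    return StandardizedChangeMatrix(
        gene_ids=list(change.gene_ids),
        values=values,
        feature_labels=list(change.feature_labels),
        column_means=means,
        column_sds=sds,
    )


def naive_rank(change: ChangeMatrix, all_features: bool = False) -> pd.DataFrame:
    """Rank genes by RMS of standardized change values, descending.

    By default the RMS runs over the same 50 localization features as the kNN
    method, for a like-for-like comparison; ``all_features=True`` uses all 60.
    Returns a DataFrame with columns ``gene_id``, ``rank``, ``rms`` sorted by
    rank (RMS ties broken by lexicographic gene id).
    """
    std = standardize_change(change)
    if all_features:
        mask = np.ones(len(std.feature_labels), dtype=bool)
    else:
        mask = localization_mask(std.feature_labels)
    rms = np.sqrt(np.mean(std.values[:, mask] ** 2, axis=1))
    lex = _lex_rank(std.gene_ids)
    order = np.lexsort((lex, -rms))
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    out = pd.DataFrame({"gene_id": std.gene_ids, "rank": ranks, "rms": rms})
    return out.sort_values("rank", ignore_index=True)
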
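"""Compositional preprocessing of genus-level microbiome profiles.

Amplicon feature tables are aggregated to genus relative abundances
(dropping features without a genus label), filtered by the
prevalence/abundance rule — a genus is kept if it is present in at
least 10% of samples at 0.01% relative abundance, or reaches 10%
relative abundance in any sample — and centered-log-ratio (CLR)
transformed:

    clr(x)_g = ln x_g - mean_g ln x_g

so each sample row sums to zero.  Zeros are handled by a multiplicative
pseudocount before the log (default: half the smallest nonzero relative
abundance in the matrix, added to every entry, rows renormalized).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def genus_aggregate(
    feature_table: pd.DataFrame, genus_labels: pd.Series
) -> pd.DataFrame:
    """Aggregate a sample x feature count table to genus relative
    abundances.

    ``genus_labels`` maps feature ids (the table's columns) to genus
    names; features with a missing/empty label are discarded before
    aggregation.  Counts are summed per genus and each row renormalized
    to sum to 1.  Samples with no retained counts are excluded with a
    warning.
    """
    labels = genus_labels.reindex(feature_table.columns)
    keep = labels.notna() & (labels.astype(str).str.len() > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("discarding %d features without genus identification", dropped)
    sub = feature_table.loc[:, keep.to_numpy()]
    if (sub.to_numpy() < 0).any():
        raise ValueError("negative counts in feature table")
    agg = sub.T.groupby(labels[keep]).sum().T
    totals = agg.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "excluding %d samples with all-zero retained counts", int(empty.sum())
        )
        agg = agg[~empty]
        totals = totals[~empty]
    rel = agg.div(totals, axis=0)
    rel.columns.name = "genus"
    return rel


def genus_filter(
    matrix: pd.DataFrame,
    prevalence_abundance: float = 1e-4,
    min_prevalence: float = 0.10,
    max_abundance: float = 0.10,
) -> list[str]:
    """Genera retained for association modeling.

    Keep a genus iff the fraction of samples where its relative
    abundance is at least ``prevalence_abundance`` (0.01% by default)
    reaches ``min_prevalence`` (10%), OR its abundance reaches
    ``max_abundance`` (10%) in any single sample.
    """
    if len(matrix) < 1:
        raise ValueError("need at least one sample")
    vals = matrix.to_numpy(dtype=float)
    prev = (vals >= prevalence_abundance).mean(axis=0)
    mx = vals.max(axis=0)
    keep = (prev >= min_prevalence) | (mx >= max_abundance)
    return [g for g, k in zip(matrix.columns, keep) if k]


def clr_transform(
    matrix: pd.DataFrame, pseudocount: Optional[float] = None
) -> pd.DataFrame:
    """CLR-transform a relative abundance matrix (samples x genera).

    ``pseudocount=None`` uses the default policy: add half the smallest
    nonzero relative abundance in the whole matrix to every entry and
    renormalize rows; a fixed positive value applies that instead.  A
    row of all zeros is an error.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("matrix contains an all-zero sample row")
    if (vals == 0).any():
        if pseudocount is None:
            pc = vals[vals > 0].min() / 2.0
        else:
            if pseudocount <= 0:
                raise ValueError("pseudocount must be positive")
            pc = float(pseudocount)
        vals = vals + pc
    vals = vals / vals.sum(axis=1, keepdims=True)
    logs = np.log(vals)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


def standardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """z-score a vector with the sample standard deviation (n-1).

    Raises on fewer than 2 values or zero spread.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector of >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot standardize")
    return (x - x.mean()) / sd
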
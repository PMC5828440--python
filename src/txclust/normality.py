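"""Per-gene skewness / excess-kurtosis summaries across simulated batches.

Moment estimators use the population divisor n (g1 = m3 / m2^1.5 and
g2 = m4 / m2^2 - 3); bias-corrected variants are available by flag.
Aggregation runs genes-within-dataset first, then datasets, so the
reported standard error reflects Monte-Carlo replicate variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .transforms import TransformedMatrix


@dataclass(frozen=True)
class NormalitySummary:
    """Scenario-level mean (SE) skewness and excess kurtosis."""

    transform_tag: str
    category: str
    K: int
    mean_skewness: float
    se_skewness: float
    mean_kurtosis: float
    se_kurtosis: float
    n_datasets: int
    n_excluded_genes: int = 0


def sample_skewness(v, bias: bool = True) -> float:
    """Moment skewness g1 = m3 / m2^1.5 (divisor-n central moments)."""
    arr = np.asarray(v, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(arr) == 0:
        raise ValueError("skewness undefined for a constant vector")
    return float(stats.skew(arr, bias=bias))

def sample_excess_kurtosis(v, bias: bool = True) -> float:
    """Excess kurtosis g2 = m4 / m2^2 - 3 (normal -> 0)."""
    arr = np.asarray(v, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 observations")
    if np.var(arr) == 0:
        raise ValueError("kurtosis undefined for a constant vector")
    return float(stats.kurtosis(arr, fisher=True, bias=bias))


def _dataset_moments(values: np.ndarray) -> tuple[float, float, int]:
    """Mean per-gene (skewness, excess kurtosis) across a dataset's samples.

    Zero-variance genes are excluded from the average; their count is
    returned so callers can log it.
    """
    variances = values.var(axis=1)
    keep = variances > 0
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("every gene is constant; no moments to summarize")
    sk = stats.skew(values[keep], axis=1, bias=True)
    kt = stats.kurtosis(values[keep], axis=1, fisher=True, bias=True)
    return float(np.mean(sk)), float(np.mean(kt)), n_excluded


def summarize_normality(
    batch: Sequence[TransformedMatrix],
    category: str = "",
    K: int = 1,
) -> NormalitySummary:
    """Aggregate a batch into a table-row summary.

    Per dataset, skewness/kurtosis are computed per gene across samples and
    averaged over genes; the reported mean averages those dataset values and
    the SE is their standard deviation divided by sqrt(n_datasets).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    shapes = {m.values.shape for m in batch}
    if len(shapes) != 1:
        raise ValueError("all matrices in a batch must share a shape")
    per_dataset_sk, per_dataset_kt = [], []
    n_excluded = 0
    for m in batch:
        sk, kt, excl = _dataset_moments(m.values)
        per_dataset_sk.append(sk)
        per_dataset_kt.append(kt)
        n_excluded += excl
    if n_excluded:
        warnings.warn(
            f"{n_excluded} constant gene slices excluded from moment averages",
            stacklevel=2,
        )
    n = len(batch)
    if n == 1:
        warnings.warn("single-dataset batch: standard errors are undefined",
                      stacklevel=2)
        se_sk = se_kt = float("nan")
    else:
        se_sk = float(np.std(per_dataset_sk, ddof=1) / np.sqrt(n))
        se_kt = float(np.std(per_dataset_kt, ddof=1) / np.sqrt(n))
    return NormalitySummary(
        transform_tag=batch[0].transform_tag,
        category=category,
        K=K,
        mean_skewness=float(np.mean(per_dataset_sk)),
        se_skewness=se_sk,
        mean_kurtosis=float(np.mean(per_dataset_kt)),
        se_kurtosis=se_kt,
        n_datasets=n,
        n_excluded_genes=n_excluded,
    )
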
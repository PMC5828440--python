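"""Partition-agreement scores: Rand, adjusted Rand, error rate, concordance.

All scores compare a ground-truth sample partition with an estimated one
via unordered sample pairs. Note that the error rate here is defined as
1 - Rand index exactly (the study's convention); the permutation-minimized
misclassification rate is provided separately as
:func:`min_matching_error` to avoid ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np


@dataclass(frozen=True)
class PartitionPair:
    """A (truth, estimate) pair of per-sample cluster labels."""

    truth: np.ndarray
    estimate: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.truth)
        e = np.asarray(self.estimate)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("truth and estimate must be equal-length vectors")
        if t.size < 2:
            raise ValueError("need at least 2 samples")
        object.__setattr__(self, "truth", t)
        object.__setattr__(self, "estimate", e)


@dataclass(frozen=True)
class EvaluationScores:
    ari: float
    cer: float
    ci: float


def _as_pair(pair_or_truth, estimate=None) -> PartitionPair:
    if estimate is None:
        return pair_or_truth
    return PartitionPair(np.asarray(pair_or_truth), np.asarray(estimate))


def _pair_counts(pair: PartitionPair) -> tuple[int, int, int, int]:
    """Counts over unordered sample pairs.

    Returns (both co-clustered, truth-only, estimate-only, both separated).
    """
    t, e = pair.truth, pair.estimate
    iu = np.triu_indices(t.size, k=1)
    same_t = (t[:, None] == t[None, :])[iu]
    same_e = (e[:, None] == e[None, :])[iu]
    n11 = int(np.sum(same_t & same_e))
    n10 = int(np.sum(same_t & ~same_e))
    n01 = int(np.sum(~same_t & same_e))
    n00 = int(np.sum(~same_t & ~same_e))
    return n11, n10, n01, n00


def rand_index(pair_or_truth, estimate=None) -> float:
    """Fraction of sample pairs on which the two partitions agree."""
    pair = _as_pair(pair_or_truth, estimate)
    n11, n10, n01, n00 = _pair_counts(pair)
    return (n11 + n00) / (n11 + n10 + n01 + n00)


def adjusted_rand_index(pair_or_truth, estimate=None) -> float:
    """Hubert-Arabie chance-corrected Rand index.

    (Index - E[Index]) / (Max - E[Index]) over pair counts from the
    contingency table. When the denominator degenerates (both partitions
    all-singleton or all-one), returns 1 for identical partitions else 0.
    """
    pair = _as_pair(pair_or_truth, estimate)
    t, e = pair.truth, pair.estimate
    n = t.size
    _, t_codes = np.unique(t, return_inverse=True)
    _, e_codes = np.unique(e, return_inverse=True)
    contingency = np.zeros((t_codes.max() + 1, e_codes.max() + 1), dtype=np.int64)
    np.add.at(contingency, (t_codes, e_codes), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(contingency).sum()
    sum_rows = comb2(contingency.sum(axis=1)).sum()
    sum_cols = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        # degenerate only when both partitions are all-singletons or both
        # all-one; compare as partitions (relabeling-invariant)
        same_partition = np.array_equal(
            t_codes[:, None] == t_codes[None, :],
            e_codes[:, None] == e_codes[None, :],
        )
        return 1.0 if same_partition else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def cer(pair_or_truth, estimate=None) -> float:
    """Clustering error rate: exactly 1 - Rand index."""
    return 1.0 - rand_index(_as_pair(pair_or_truth, estimate))


def concordance_index(pair_or_truth, estimate=None) -> float:
    """Pairwise co-membership AUC.

    Over all combinations of one within-truth-cluster pair and one
    between-truth-cluster pair, the fraction where the estimate co-clusters
    the within pair and separates the between pair, with half credit for
    ties. 1 for perfect recovery, 0.5 for an uninformative estimate, NaN
    when the truth has no between-cluster (or no within-cluster) pairs.
    """
    pair = _as_pair(pair_or_truth, estimate)
    n11, n10, n01, n00 = _pair_counts(pair)
    n_within = n11 + n10       # truth co-clustered pairs
    n_between = n01 + n00      # truth separated pairs
    if n_within == 0 or n_between == 0:
        return float("nan")
    # binary co-membership scores: wins are (within co-clustered, between
    # separated); ties occur when both sides share a score
    wins = n11 * n00
    ties = n11 * n01 + n10 * n00
    return (wins + 0.5 * ties) / (n_within * n_between)


def min_matching_error(pair_or_truth, estimate=None) -> float:
    """Misclassification rate minimized over cluster-label permutations.

    This is the *other* definition of clustering error rate found in the
    literature; kept under a distinct name. Exhaustive over the smaller
    partition's labels, so intended for small cluster counts.
    """
    pair = _as_pair(pair_or_truth, estimate)
    t, e = pair.truth, pair.estimate
    t_labels = np.unique(t)
    e_labels = np.unique(e)
    if len(e_labels) > 8:
        raise ValueError("too many clusters for exhaustive matching")
    best = 0
    for perm in permutations(t_labels, r=min(len(t_labels), len(e_labels))):
        mapping = dict(zip(e_labels, perm))
        correct = sum(mapping.get(ei) == ti for ti, ei in zip(t, e))
        best = max(best, correct)
    return 1.0 - best / t.size


def evaluate(pair_or_truth, estimate=None) -> EvaluationScores:
    """All three study scores for one (truth, estimate) pair."""
    pair = _as_pair(pair_or_truth, estimate)
    return EvaluationScores(
        ari=adjusted_rand_index(pair),
        cer=cer(pair),
        ci=concordance_index(pair),
    )
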
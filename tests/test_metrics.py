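"""Partition-score tests against independent brute-force pair oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txclust as tc


# ---------------------------------------------------------------- oracles
def oracle_rand(truth, estimate):
    n = len(truth)
    agree = 0
    for i, j in combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_e = estimate[i] == estimate[j]
        agree += same_t == same_e
    return agree / (n * (n - 1) / 2)


def oracle_ari(truth, estimate):
    n = len(truth)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_e = estimate[i] == estimate[j]
        n11 += same_t and same_e
        n10 += same_t and not same_e
        n01 += same_e and not same_t
        n00 += not same_t and not same_e
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        same = all(
            (truth[i] == truth[j]) == (estimate[i] == estimate[j])
            for i, j in combinations(range(n), 2)
        )
        return 1.0 if same else 0.0
    return (n11 - expected) / (max_index - expected)


def oracle_ci(truth, estimate):
    n = len(truth)
    within, between = [], []
    for i, j in combinations(range(n), 2):
        score = 1 if estimate[i] == estimate[j] else 0
        (within if truth[i] == truth[j] else between).append(score)
    if not within or not between:
        return float("nan")
    total = 0.0
    for w in within:
        for b in between:
            total += 1.0 if w > b else (0.5 if w == b else 0.0)
    return total / (len(within) * len(between))


def all_partitions(n):
    """Every set partition of range(n), as label vectors."""
    if n == 1:
        yield [0]
        return
    for sub in all_partitions(n - 1):
        for lab in range(max(sub) + 2):
            yield sub + [lab]


# ---------------------------------------------------------------- examples
class TestRandIndex:
    def test_identical(self):
        assert tc.rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_example(self):
        assert tc.rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 / 6)

    def test_singletons_vs_all_one(self):
        assert tc.rand_index([1, 1, 1], [1, 2, 3]) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            tc.rand_index([1], [1])


class TestAdjustedRandIndex:
    def test_identical(self):
        assert tc.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_all_one_estimate_is_zero(self):
        assert tc.adjusted_rand_index([1, 1, 2, 2], [1, 1, 1, 1]) == pytest.approx(0.0)

    def test_brute_force_example(self):
        truth = [1, 1, 1, 2, 2, 2]
        est = [1, 1, 2, 2, 3, 3]
        assert tc.adjusted_rand_index(truth, est) == pytest.approx(
            oracle_ari(truth, est)
        )

    def test_degenerate_pair(self):
        assert tc.adjusted_rand_index([1, 2, 3], [1, 2, 3]) == 1.0
        assert tc.adjusted_rand_index([1, 1, 1], [1, 1, 1]) == 1.0


class TestCer:
    def test_identical_is_zero(self):
        assert tc.cer([1, 1, 2, 2], [1, 1, 2, 2]) == 0.0

    def test_crossed_example(self):
        assert tc.cer([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(4 / 6)

    def test_exact_complement(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 3, size=12)
            e = rng.integers(0, 4, size=12)
            assert tc.cer(t, e) == 1.0 - tc.rand_index(t, e)


class TestConcordanceIndex:
    def test_perfect(self):
        assert tc.concordance_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_constant_estimate_is_chance(self):
        assert tc.concordance_index([1, 1, 2, 2, 3], [1, 1, 1, 1, 1]) == 0.5

    def test_brute_force_example(self):
        truth = [1, 1, 2, 2]
        est = [1, 1, 1, 2]
        expected = oracle_ci(truth, est)
        assert expected == pytest.approx(0.5)  # frozen from the oracle
        assert tc.concordance_index(truth, est) == pytest.approx(expected)

    def test_single_cluster_truth_is_nan(self):
        assert np.isnan(tc.concordance_index([1, 1, 1], [1, 2, 1]))


# ---------------------------------------------------------- exhaustive sweep
class TestExhaustiveOracleAgreement:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_all_partition_pairs(self, n):
        parts = list(all_partitions(n))
        for t in parts:
            for e in parts:
                assert tc.rand_index(t, e) == pytest.approx(oracle_rand(t, e))
                assert tc.adjusted_rand_index(t, e) == pytest.approx(
                    oracle_ari(t, e)
                )
                assert tc.cer(t, e) == pytest.approx(1 - oracle_rand(t, e))
                ci = tc.concordance_index(t, e)
                ci_o = oracle_ci(t, e)
                if np.isnan(ci_o):
                    assert np.isnan(ci)
                else:
                    assert ci == pytest.approx(ci_o)

    def test_random_pairs_n8(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 4, size=8).tolist()
            e = rng.integers(0, 4, size=8).tolist()
            assert tc.rand_index(t, e) == pytest.approx(oracle_rand(t, e))
            assert tc.adjusted_rand_index(t, e) == pytest.approx(oracle_ari(t, e))
            ci, ci_o = tc.concordance_index(t, e), oracle_ci(t, e)
            assert (np.isnan(ci) and np.isnan(ci_o)) or ci == pytest.approx(ci_o)


# ---------------------------------------------------------------- properties
label_vectors = st.lists(st.integers(min_value=0, max_value=4), min_size=2,
                         max_size=12)


@given(data=st.data(), labels=label_vectors)
@settings(max_examples=60, deadline=None)
def test_relabeling_invariance(data, labels):
    other = data.draw(
        st.lists(
            st.integers(min_value=0, max_value=4),
            min_size=len(labels),
            max_size=len(labels),
        )
    )
    # bijective relabeling of the estimate must not change any score
    mapping = {lab: 10 + i for i, lab in enumerate(dict.fromkeys(other))}
    relabeled = [mapping[x] for x in other]
    assert tc.rand_index(labels, other) == tc.rand_index(labels, relabeled)
    assert tc.adjusted_rand_index(labels, other) == pytest.approx(
        tc.adjusted_rand_index(labels, relabeled)
    )
    ci_a = tc.concordance_index(labels, other)
    ci_b = tc.concordance_index(labels, relabeled)
    assert (np.isnan(ci_a) and np.isnan(ci_b)) or ci_a == pytest.approx(ci_b)


def test_ari_of_independent_partitions_near_zero():
    rng = np.random.default_rng(2)
    values = [
        tc.adjusted_rand_index(
            rng.integers(0, 3, size=55), rng.integers(0, 3, size=55)
        )
        for _ in range(2000)
    ]
    assert abs(np.mean(values)) < 0.02


def test_min_matching_error_differs_from_cer():
    truth = [1, 1, 2, 2]
    est = [2, 2, 1, 1]
    assert tc.metrics.min_matching_error(truth, est) == 0.0
    assert tc.cer(truth, est) == 0.0

    est2 = [1, 2, 1, 2]
    assert tc.metrics.min_matching_error(truth, est2) == 0.5


def test_evaluate_bundle():
    scores = tc.evaluate([1, 1, 2, 2], [1, 1, 2, 2])
    assert (scores.ari, scores.cer, scores.ci) == (1.0, 0.0, 1.0)
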
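"""Effort classification and ROC/DeLong/Youden/reference-interval statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respeffort.diagnostics import (classify_effort, compare_auc_delong,
                                    confusion_stats, cross_validate_tenfold,
                                    reference_interval, roc_auc,
                                    variance_explained, youden_cutoff,
                                    _delong_components)
from respeffort.errors import (DataError, DegenerateLabels, GroupingError,
                               SampleTooSmall)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("criterion,value,label", [
    ("pmus", 12.0, "high"), ("pmus", 4.9, "low"), ("pmus", 5.0, "intermediate"),
    ("pmus", 10.0, "intermediate"), ("pmus", 10.01, "high"),
    ("ptp_min", 30.0, "low"), ("ptp_min", 50.0, "intermediate"),
    ("ptp_min", 201.0, "high"), ("ptp_min", 200.0, "intermediate"),
])
def test_effort_bands_with_boundary_convention(criterion, value, label):
    assert classify_effort(value, criterion).label == label


def test_classify_requires_a_value():
    with pytest.raises(DataError):
        classify_effort(float("nan"), "pmus")


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _brute_auc(scores, labels):
    pos, neg = scores[labels == 1], scores[labels == 0]
    return float(np.mean((pos[:, None] > neg[None, :])
                         + 0.5 * (pos[:, None] == neg[None, :])))


def test_auc_separation_extremes():
    assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([1, 2, 1, 2], [1, 1, 0, 0]).auc == 0.5


def test_auc_worked_pair_count_example():
    # positives {3,2}, negatives {1,2}: 3.5 concordant of 4 pairs
    assert roc_auc([3, 2, 1, 2], [1, 1, 0, 0]).auc == pytest.approx(0.875)


def test_auc_equals_brute_force_and_sklearn_on_random_instances():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(8, 200))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(0, 1, n) + labels, 1)
        auc = roc_auc(scores, labels).auc
        assert auc == pytest.approx(_brute_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_direction_lesser_flips_the_curve():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(scores, labels, "lesser").auc == 1.0


def test_single_class_rejected():
    with pytest.raises(DegenerateLabels):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_delong_variance_matches_brute_force_small_n():
    rng = np.random.default_rng(3)

    def brute_var(scores, labels):
        x, y = scores[labels == 1], scores[labels == 0]
        psi = lambda a, b: 1.0 if a > b else (0.5 if a == b else 0.0)
        v10 = np.array([np.mean([psi(xi, yj) for yj in y]) for xi in x])
        v01 = np.array([np.mean([psi(xi, yj) for xi in x]) for yj in y])
        return np.var(v10, ddof=1) / len(x) + np.var(v01, ddof=1) / len(y)

    for _ in range(25):
        labels = np.array([1] * 4 + [0] * 6)
        scores = np.round(rng.normal(0, 1, 10), 1)
        _, v10, v01 = _delong_components(scores, labels)
        se2 = np.var(v10, ddof=1) / 4 + np.var(v01, ddof=1) / 6
        assert se2 == pytest.approx(brute_var(scores, labels), abs=1e-12)


def test_delong_paired_test_identical_and_monotone():
    labels = np.array([1, 1, 1, 0, 0, 0, 0])
    a = np.array([5.0, 4, 6, 1, 2, 3, 2.5])
    z, p = compare_auc_delong(a, a, labels)
    assert (z, p) == (0.0, 1.0)
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 60)
    labels[:5], labels[-5:] = 1, 0
    good = labels + rng.normal(0, 0.3, 60)
    bad = rng.normal(0, 1, 60)
    z1, _ = compare_auc_delong(good, bad, labels)
    worse = rng.normal(0, 1, 60)
    z2, _ = compare_auc_delong(good, 0.5 * good + worse, labels)
    assert abs(z1) > abs(z2)


# ---------------------------------------------------------------------------
# cutoffs and confusion statistics
# ---------------------------------------------------------------------------

def test_youden_perfect_separation():
    cutoff, j = youden_cutoff([2, 3, 0, 1], [1, 1, 0, 0])
    assert j == pytest.approx(1.0)
    assert 1.0 < cutoff < 2.0


def test_youden_degenerate_scores():
    _, j = youden_cutoff([2.0, 2.0, 2.0, 2.0], [1, 0, 1, 0])
    assert j == pytest.approx(0.0)


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 200
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.normal(0, 1, n) + 0.8 * labels, 1)
        _, j = youden_cutoff(scores, labels)
        best = -2.0
        for c in np.concatenate([np.unique(scores) - 1e-9,
                                 np.unique(scores) + 1e-9]):
            pred = scores >= c
            tp = (pred & (labels == 1)).sum()
            fn = (~pred & (labels == 1)).sum()
            tn = (~pred & (labels == 0)).sum()
            fp = (pred & (labels == 0)).sum()
            best = max(best, tp / (tp + fn) + tn / (tn + fp) - 1)
        assert j == pytest.approx(best, abs=1e-12)


def test_confusion_stats_reconstruct_published_row():
    # 17 high-effort levels all detected, 57 false positives among 229:
    # sensitivity 1.00, PPV 17/74, NPV 1.00
    scores = np.concatenate([np.full(17, 2.0), np.full(57, 2.0), np.zeros(172)])
    labels = np.concatenate([np.ones(17), np.zeros(229)]).astype(int)
    r = confusion_stats(scores, labels, 1.0, "greater")
    assert r.sensitivity == 1.0
    assert r.ppv == pytest.approx(17 / 74, abs=1e-9)
    assert r.npv == 1.0
    assert (r.tp, r.fp, r.tn, r.fn) == (17, 57, 172, 0)
    lo, hi = r.sensitivity_ci
    assert lo < 1.0 <= hi


def test_confusion_stats_undefined_proportions_absent():
    scores = np.array([1.0, 2.0, 3.0, 0.5])
    labels = np.array([0, 0, 0, 1])
    r = confusion_stats(scores, labels, 10.0, "greater")  # nobody positive
    assert r.ppv is None
    assert r.sensitivity == 0.0


def test_bayes_consistency_of_predictive_values():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 300)
    labels[0], labels[1] = 0, 1
    scores = rng.normal(0, 1, 300) + labels
    r = confusion_stats(scores, labels, 0.5, "greater")
    prev = labels.mean()
    ppv_bayes = (r.sensitivity * prev) / (
        r.sensitivity * prev + (1 - r.specificity) * (1 - prev))
    assert r.ppv == pytest.approx(ppv_bayes, abs=1e-9)


# ---------------------------------------------------------------------------
# cross-validation, reference intervals, association
# ---------------------------------------------------------------------------

def test_cv_is_deterministic_and_stable_when_separable():
    rng = np.random.default_rng(4)
    labels = np.array([0] * 50 + [1] * 50)
    # quantized, perfectly separated scores: every training fold contains
    # the extreme levels, so every fold lands on the same midpoint cutoff
    scores = np.concatenate([rng.choice([0.0, 0.5, 1.0], 50),
                             rng.choice([2.0, 2.5, 3.0], 50)])
    a = cross_validate_tenfold(scores, labels, seed=9)
    b = cross_validate_tenfold(scores, labels, seed=9)
    assert a == b
    assert a["pooled"]["sensitivity"] == 1.0
    assert len(set(np.round(a["fold_cutoffs"], 6))) == 1


def test_reference_interval_uniform_limits():
    rng = np.random.default_rng(6)
    ri = reference_interval(rng.uniform(0, 1, 1000), seed=6)
    assert ri.lower == pytest.approx(0.1, abs=0.02)
    assert ri.upper == pytest.approx(0.9, abs=0.02)
    assert ri.grey_zone_fraction == pytest.approx(0.2, abs=0.01)
    assert ri.lower_ci[0] <= ri.lower <= ri.lower_ci[1]


def test_reference_interval_constant_vector():
    ri = reference_interval(np.full(50, 3.3), seed=0)
    assert ri.lower == ri.upper == pytest.approx(3.3)
    assert ri.grey_zone_fraction == 0.0


def test_reference_interval_needs_20():
    with pytest.raises(SampleTooSmall):
        reference_interval(np.arange(10), seed=0)


def test_variance_explained_identity_and_offsets():
    rng = np.random.default_rng(8)
    ids = np.repeat(np.arange(10), 8)
    x = rng.normal(0, 1, 80)
    between, within = variance_explained(x, x.copy(), ids)
    assert between == pytest.approx(1.0)
    assert within == pytest.approx(1.0)
    offsets = np.repeat(rng.normal(0, 5, 10), 8)
    _, within2 = variance_explained(x, x + offsets, ids)
    assert within2 == pytest.approx(1.0)


def test_variance_explained_null_after_within_patient_permutation():
    rng = np.random.default_rng(10)
    ids = np.repeat(np.arange(28), 10)
    x = rng.normal(0, 1, 280)
    y = x + rng.normal(0, 0.1, 280)
    yp = y.copy()
    for g in np.unique(ids):
        sel = np.flatnonzero(ids == g)
        yp[sel] = yp[rng.permutation(sel)]
    _, within = variance_explained(x, yp, ids)
    assert within < 0.05


def test_variance_explained_rejects_degenerate_grouping():
    with pytest.raises(GroupingError):
        variance_explained([1, 2], [1, 2], ["a", "a"])


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60),
       st.integers(0, 2**31 - 1))
def test_auc_complementarity_under_direction_flip(values, seed):
    rng = np.random.default_rng(seed)
    scores = np.array(values)
    labels = rng.integers(0, 2, scores.size)
    if labels.sum() in (0, scores.size):
        labels[0], labels[-1] = 0, 1
    a = roc_auc(scores, labels, "greater").auc
    b = roc_auc(scores, labels, "lesser").auc
    assert a + b == pytest.approx(1.0, abs=1e-9)
    assert a == pytest.approx(_brute_auc(scores, labels), abs=1e-9)


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_grey_zone_near_two_tails_by_construction(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1, 400)
    ri = reference_interval(values, seed=0, n_boot=200)
    assert ri.grey_zone_fraction == pytest.approx(0.2, abs=0.02)
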
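"""Fold plans, metrics, AUC oracle equivalence and comparison statistics."""

import numpy as np
import pytest

from beatwise import train_eval as te


# ---------------------------------------------------------------------------
# Fold plan
# ---------------------------------------------------------------------------

def _labels(n_p=60, n_m=20, n_r=20):
    labels = {}
    for i in range(n_p):
        labels[f"p{i}"] = "pEF"
    for i in range(n_m):
        labels[f"m{i}"] = "mrEF"
    for i in range(n_r):
        labels[f"r{i}"] = "rEF"
    return labels


def test_fold_plan_stratified_partition():
    plan = te.make_fold_plan(_labels(), seed=0)
    sizes = [len(s) for s in plan.subsets]
    assert sizes == [20] * 5
    for subset in plan.subsets:
        by_cls = {"pEF": 0, "mrEF": 0, "rEF": 0}
        for cid in subset:
            by_cls[plan.labels[cid]] += 1
        assert by_cls == {"pEF": 12, "mrEF": 4, "rEF": 4}
    all_ids = [c for s in plan.subsets for c in s]
    assert sorted(all_ids) == sorted(_labels())  # exact partition


def test_fold_plan_fixed_test_and_no_leakage():
    plan = te.make_fold_plan(_labels(), seed=3)
    test_sets = []
    for fold, train, dev, test in plan.folds():
        assert not set(train) & set(dev)
        assert not set(train) & set(test)
        assert not set(dev) & set(test)
        test_sets.append(tuple(test))
    assert len(set(test_sets)) == 1  # identical test fold everywhere
    te.assert_no_leakage(plan)


def test_fold_plan_deterministic_and_rejects_tiny_classes():
    a = te.make_fold_plan(_labels(), seed=7)
    b = te.make_fold_plan(_labels(), seed=7)
    assert a.subsets == b.subsets
    with pytest.raises(ValueError, match="at least 5"):
        te.make_fold_plan(_labels(n_r=4), seed=0)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _auc_bruteforce(scores, labels):
    """O(n^2) Mann-Whitney oracle: pairwise comparisons, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_edge_cases():
    assert te.compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert te.compute_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
    with pytest.raises(ValueError):
        te.compute_auc([0.1, 0.2], [1, 1])


def test_auc_matches_pairwise_oracle_on_200_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(5, 40))
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert te.compute_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# Threshold metrics & case aggregation
# ---------------------------------------------------------------------------

def test_threshold_metrics_hand_table():
    # TP=8, FN=2, TN=7, FP=3
    scores = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 7 + [0.8] * 3)
    labels = np.array([1] * 10 + [0] * 10)
    acc, sens, spec = te.threshold_metrics(scores, labels, 0.5)
    assert (acc, sens, spec) == (0.75, 0.8, 0.7)


def test_threshold_metric_extremes_and_missing():
    scores = np.array([0.2, 0.4, 0.6, 0.99])
    labels = np.array([0, 1, 0, 1])
    _, sens, _ = te.threshold_metrics(scores, labels, 0.0)
    assert sens == 1.0
    _, _, spec = te.threshold_metrics(scores, labels, 1.0)
    assert spec == 1.0
    acc, sens, spec = te.threshold_metrics([0.3, 0.7], [1, 1], 0.5)
    assert spec is None and sens == 0.5


class _StubClf:
    classes_ = np.array([0, 1])

    def predict_proba(self, X):
        scores = np.asarray(X)[:, 0, 0]
        return np.stack([1 - scores, scores], axis=1)


def test_case_level_mean_aggregation():
    X = np.array([0.2, 0.8, 0.6])[:, None, None] * np.ones((3, 1, 4))
    cases = ["a", "a", "b"]
    agg = te.predict_case_level(_StubClf(), X, cases)
    assert agg["a"] == pytest.approx(0.5)
    assert agg["b"] == pytest.approx(0.6)
    # permutation invariance
    agg2 = te.predict_case_level(_StubClf(), X[[2, 0, 1]],
                                 ["b", "a", "a"])
    assert agg2["a"] == pytest.approx(agg["a"])


# ---------------------------------------------------------------------------
# Configuration comparisons
# ---------------------------------------------------------------------------

def test_identical_configurations_not_significant():
    res = {"a": [0.8, 0.81, 0.79, 0.8], "b": [0.8, 0.81, 0.79, 0.8]}
    report = te.compare_configurations(res)
    assert report["test"] == "t-test"
    assert report["p_value"] > 0.9
    assert report["summary"]["a"]["mean"] == \
        pytest.approx(report["summary"]["b"]["mean"])


def test_separated_configurations_significant():
    res = {"a": [0.80, 0.81, 0.80, 0.81], "b": [0.90, 0.91, 0.90, 0.91]}
    report = te.compare_configurations(res)
    assert report["p_value"] < 0.001
    assert report["significant"]


def test_tukey_flags_only_the_shifted_group():
    rng = np.random.default_rng(0)
    base = rng.normal(0.85, 0.005, size=(3, 6))
    res = {"a": list(base[0]), "b": list(base[1]),
           "c": list(base[2] + 0.05)}
    report = te.compare_configurations(res)
    assert report["test"] == "anova+tukey"
    flagged = {frozenset((p["group1"], p["group2"]))
               for p in report["tukey"] if p["reject"]}
    assert flagged == {frozenset(("a", "c")), frozenset(("b", "c"))}


def test_compare_rejects_unequal_fold_counts():
    with pytest.raises(ValueError, match="unequal"):
        te.compare_configurations({"a": [0.8, 0.9], "b": [0.8]})
    with pytest.raises(ValueError):
        te.compare_configurations({"a": [0.8, 0.9]})
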
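"""Cross-validation, training orchestration and evaluation metrics.

The study design is a modified stratified four-fold cross-validation: cases
are split (at case level, stratified by ejection-fraction class) into five
disjoint subsets; one subset is a fixed held-out test set shared by every
fold, the remaining four rotate as development set while the other three
train.  Metrics are AUC (the primary endpoint, equal to the Mann-Whitney
concordance probability with ties counted one half), accuracy, sensitivity
and specificity, computed at case level by averaging per-tensor
reduced-EF probabilities over each case's strips or beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import Conv1dNetClassifier


@dataclass
class FoldPlan:
    """Assignment of case ids to 4 rotating train/dev subsets and one
    fixed test subset, stratified by EF class."""

    subsets: list[list[str]]            # 5 disjoint case-id lists
    labels: dict[str, str]              # case_id -> EF class
    test_index: int = 4

    def __post_init__(self) -> None:
        if len(self.subsets) != 5:
            raise ValueError("a fold plan has exactly 5 subsets")
        all_ids = [c for s in self.subsets for c in s]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("subsets must be pairwise disjoint")
        if set(all_ids) != set(self.labels):
            raise ValueError("subsets must partition the labelled cases")

    @property
    def test_ids(self) -> list[str]:
        return list(self.subsets[self.test_index])

    def folds(self):
        """Yield (fold_number, train_ids, dev_ids, test_ids) for folds 1-4."""
        rotating = [i for i in range(5) if i != self.test_index]
        for fold, dev_i in enumerate(rotating, start=1):
            dev = list(self.subsets[dev_i])
            train = [c for i in rotating if i != dev_i
                     for c in self.subsets[i]]
            yield fold, train, dev, self.test_ids


@dataclass
class EvalResult:
    """Metrics for one (configuration, fold) pair."""

    configuration: str
    fold: int
    auc: float
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    level: str = "case"

    def __post_init__(self) -> None:
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def make_fold_plan(labels: dict[str, str] | pd.DataFrame,
                   seed: int = 0) -> FoldPlan:
    """Stratified 5-subset split at case level.

    ``labels`` maps case_id to EF class (or is a manifest frame with
    case_id/ef_class columns).  Within each class, cases are shuffled and
    dealt round-robin across the five subsets, so per-class proportions are
    equal within one case.  Requires at least 5 cases per class.
    """
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["case_id"], labels["ef_class"]))
    rng = np.random.default_rng(seed)
    subsets: list[list[str]] = [[] for _ in range(5)]
    for cls in sorted(set(labels.values())):
        ids = sorted(c for c, lab in labels.items() if lab == cls)
        if len(ids) < 5:
            raise ValueError(
                f"class {cls!r} has {len(ids)} cases; at least 5 required")
        rng.shuffle(ids)
        for i, cid in enumerate(ids):
            subsets[i % 5].append(cid)
    return FoldPlan(subsets=subsets, labels=dict(labels))


def assert_no_leakage(plan: FoldPlan) -> None:
    """Raise if any fold's train/dev/test case sets intersect."""
    for fold, train, dev, test in plan.folds():
        s_train, s_dev, s_test = set(train), set(dev), set(test)
        if s_train & s_dev or s_train & s_test or s_dev & s_test:
            raise AssertionError(f"case leakage detected in fold {fold}")


def train_fold(train_x, train_y, dev_x, dev_y, *,
               dev_case_ids=None, model_params: dict | None = None,
               seed: int = 0) -> Conv1dNetClassifier:
    """Train one fold's classifier and return the best-dev-AUC checkpoint.

    The standardiser must already have been fitted on the training tensors
    only and applied to every split; this function does not refit it.
    """
    params = dict(model_params or {})
    params.setdefault("random_state", seed)
    clf = Conv1dNetClassifier(**params)
    clf.fit(np.asarray(train_x), np.asarray(train_y),
            X_dev=np.asarray(dev_x), y_dev=np.asarray(dev_y),
            dev_case_ids=dev_case_ids)
    return clf


def predict_case_level(clf, X, case_ids, agg: str = "mean") -> pd.Series:
    """One reduced-EF probability per case, aggregated over the case's
    tensors (mean by default; median and majority available)."""
    scores = clf.predict_proba(np.asarray(X))[:, 1]
    s = pd.Series(scores, index=pd.Index(case_ids, name="case_id"))
    grouped = s.groupby(level=0)
    if agg == "mean":
        return grouped.mean()
    if agg == "median":
        return grouped.median()
    if agg == "majority":
        return grouped.apply(lambda g: float((g >= 0.5).mean() >= 0.5))
    raise ValueError(f"unknown aggregation {agg!r}")


def compute_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability, ties counted 1/2.

    Computed from midranks: AUC = (R1 - n1(n1+1)/2) / (n1 n0), with R1 the
    positive-class rank sum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def threshold_metrics(scores, labels, threshold: float = 0.5
                      ) -> tuple[float | None, float | None, float | None]:
    """(accuracy, sensitivity, specificity) at a probability threshold.

    Scores >= threshold call the positive (reduced-EF) class.  With a
    single-class label vector the undefined metric is returned as None.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    accuracy = (tp + tn) / len(labels) if len(labels) else None
    sensitivity = tp / n1 if n1 else None
    specificity = tn / n0 if n0 else None
    return accuracy, sensitivity, specificity


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity - 1 on the given set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        _, sens, spec = threshold_metrics(scores, labels, min(max(t, 0.0), 1.0))
        if sens is None or spec is None:
            continue
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_fold(clf, X, y, case_ids=None, *, configuration: str = "",
                  fold: int = 1, threshold: float = 0.5,
                  level: str | None = None) -> EvalResult:
    """Compute the full metric set for one fitted classifier.

    With ``case_ids`` the evaluation is at case level (mean probability per
    case); without, at data level.
    """
    y = np.asarray(y)
    pos = clf.classes_[1]
    if case_ids is not None:
        case_scores = predict_case_level(clf, X, case_ids)
        lab = pd.Series((y == pos).astype(int),
                        index=pd.Index(case_ids, name="case_id"))
        case_labels = lab.groupby(level=0).first()
        scores = case_scores.loc[case_labels.index].to_numpy()
        labels = case_labels.to_numpy()
        lvl = level or "case"
    else:
        scores = clf.predict_proba(np.asarray(X))[:, 1]
        labels = (y == pos).astype(int)
        lvl = level or "data"
    auc = compute_auc(scores, labels)
    acc, sens, spec = threshold_metrics(scores, labels, threshold)
    return EvalResult(configuration=configuration, fold=fold, auc=auc,
                      accuracy=acc, sensitivity=sens, specificity=spec,
                      level=lvl)


# ---------------------------------------------------------------------------
# Configuration comparison statistics
# ---------------------------------------------------------------------------

def compare_configurations(results: dict[str, list[float]], *,
                           alpha: float = 0.05,
                           require_equal_n: bool = True) -> dict:
    """Compare per-fold AUC lists across configurations.

    Two groups: Student's t-test.  Three or more: one-way ANOVA with
    Tukey-HSD post hoc contrasts.  Returns per-configuration mean and SD,
    the global p-value, and (for >=3 groups) the Tukey table with a
    significance flag per pair at the given alpha.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 configurations to compare")
    lengths = {k: len(v) for k, v in results.items()}
    if require_equal_n and len(set(lengths.values())) != 1:
        raise ValueError(f"unequal fold counts across configurations: {lengths}")
    if min(lengths.values()) < 2:
        raise ValueError("each configuration needs >= 2 fold results")
    summary = {k: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                   "n": len(v)}
               for k, v in results.items()}
    report = {"summary": summary, "alpha": alpha}
    groups = list(results.values())
    if len(results) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1])
        report.update({"test": "t-test", "statistic": float(t),
                       "p_value": float(p),
                       "significant": bool(p < alpha)})
    else:
        f, p = stats.f_oneway(*groups)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(groups)
        labels = np.concatenate([[k] * len(v) for k, v in results.items()])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        from itertools import combinations
        pairs = [
            {"group1": str(a), "group2": str(b), "meandiff": float(md),
             "p_adj": float(pa), "reject": bool(rej)}
            for (a, b), md, pa, rej in zip(
                combinations(tukey.groupsunique, 2), tukey.meandiffs,
                tukey.pvalues, tukey.reject)]
        report.update({"test": "anova+tukey", "statistic": float(f),
                       "p_value": float(p),
                       "significant": bool(p < alpha),
                       "tukey": pairs})
    return report


def chi_square(table) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table))
    return float(chi2), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H-test across groups of a non-normal variable."""
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
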
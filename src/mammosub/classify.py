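"""Patient-grouped cross-validated classification and evaluation.

Two classification rounds are used downstream: candidate regions are first
classified as normal tissue vs. true microcalcification, and the true
microcalcifications are then classified as benign vs. suspicious.  Both
rounds share this harness: leave-one-patient-out (LOPO) or grouped k-fold
cross-validation (all samples of a patient stay on one side of every
split), per-fold standardisation fitted on training patients only, pooled
out-of-fold scores, and an operating cutoff at the crossing point of the
positive and negative score distributions (|FP - FN| minimised).

Eight classical classifiers are provided: 9-nearest neighbours, decision
tree, random forest, multi-layer perceptron, adaptive boosting, bagging,
gradient boosting, and a soft-voting ensemble of the first seven.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    VotingClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

BASE_CLASSIFIERS = (
    "knn9",
    "decision_tree",
    "random_forest",
    "mlp",
    "adaboost",
    "bagging",
    "gradient_boosting",
)
CLASSIFIER_NAMES = BASE_CLASSIFIERS + ("ensemble_voting",)


@dataclass
class CVPlan:
    """Patient-level cross-validation folds; no patient ever appears on
    both sides of a split."""

    scheme: str  # "LOPO" | "grouped_kfold"
    folds: list[tuple[list[str], list[str]]]  # (train ids, test ids)

    def __post_init__(self) -> None:
        all_test: list[str] = []
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise ValueError(f"patient(s) {sorted(overlap)} in both train and test")
            all_test.extend(test)
        if len(all_test) != len(set(all_test)):
            raise ValueError("test folds overlap")


@dataclass
class EvalReport:
    """Counts and derived metrics for one classifier (one table row)."""

    tp: int
    fn: int
    tn: int
    fp: int
    auc: float
    cutoff: float

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "cutoff": self.cutoff,
        }


def build_cv(
    patient_ids: Sequence[str],
    scheme: str = "LOPO",
    k: int = 5,
    seed: int = 0,
) -> CVPlan:
    """LOPO: one fold per patient.  grouped_kfold: seed-shuffled partition
    of the patients into k near-equal folds."""
    patients = sorted(set(map(str, patient_ids)))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients")
    if scheme.upper() == "LOPO":
        folds = [([p for p in patients if p != q], [q]) for q in patients]
        return CVPlan(scheme="LOPO", folds=folds)
    if scheme == "grouped_kfold":
        if k > len(patients):
            raise ValueError(f"k={k} exceeds number of patients ({len(patients)})")
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(patients))
        parts = [list(chunk) for chunk in np.array_split(order, k)]
        folds = [
            (sorted(set(patients) - set(part)), sorted(part)) for part in parts
        ]
        return CVPlan(scheme="grouped_kfold", folds=folds)
    raise ValueError(f"unknown scheme {scheme!r}")


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the supported classifiers (standardisation is
    bundled in so per-fold fitting scales on training data only)."""
    builders = {
        "knn9": lambda: KNeighborsClassifier(n_neighbors=9),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=400, random_state=seed
        ),
        "adaboost": lambda: AdaBoostClassifier(n_estimators=50, random_state=seed),
        "bagging": lambda: BaggingClassifier(n_estimators=10, random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            n_estimators=100, random_state=seed
        ),
    }
    if name in builders:
        clf = builders[name]()
    elif name == "ensemble_voting":
        clf = VotingClassifier(
            estimators=[(n, builders[n]()) for n in BASE_CLASSIFIERS],
            voting="soft",
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def optimal_cutoff(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Operating threshold at the crossing point of the two score
    distributions: minimise |FP - FN| over all pooled candidate thresholds,
    breaking ties by minimal FP + FN, then by the lower threshold.

    Samples scoring >= threshold are called positive.
    """
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    cands = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([cands, [cands[-1] + 1.0]])  # all-negative option
    best = None
    for t in cands:
        fp = int((neg >= t).sum())
        fn = int((pos < t).sum())
        key = (abs(fp - fn), fp + fn, t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal, equal to the Mann-Whitney
    probability with ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def train_eval(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cv: CVPlan,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    seed: int = 0,
    return_scores: bool = False,
):
    """Fit each classifier per fold on training patients, score test
    patients, pool the out-of-fold scores, and report counts/metrics at the
    optimal cutoff.

    Folds whose training side lacks a class are skipped with a warning; if
    every fold is skipped the evaluation fails.  With ``return_scores`` the
    per-sample pooled scores (NaN for samples in skipped folds) are also
    returned, keyed by classifier.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups).astype(str)
    reports: dict[str, EvalReport] = {}
    all_scores: dict[str, np.ndarray] = {}
    for name in classifiers:
        scores_full = np.full(len(y), np.nan)
        for train_ids, test_ids in cv.folds:
            tr = np.isin(groups, train_ids)
            te = np.isin(groups, test_ids)
            if te.sum() == 0:
                continue
            if len(np.unique(y[tr])) < 2:
                logger.warning("skipping fold %s: single-class training set", test_ids)
                continue
            model = make_classifier(name, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
                scores_full[te] = model.predict_proba(X[te])[:, 1]
        scored = np.isfinite(scores_full)
        if not scored.any():
            raise RuntimeError(f"all folds skipped for classifier {name!r}")
        scores = scores_full[scored]
        labels = y[scored]
        cut = optimal_cutoff(scores[labels == 1], scores[labels == 0])
        pred = scores >= cut
        reports[name] = EvalReport(
            tp=int((pred & (labels == 1)).sum()),
            fn=int((~pred & (labels == 1)).sum()),
            tn=int((~pred & (labels == 0)).sum()),
            fp=int((pred & (labels == 0)).sum()),
            auc=auc(scores, labels),
            cutoff=cut,
        )
        all_scores[name] = scores_full
    if return_scores:
        return reports, all_scores
    return reports


def fisher_compare(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Two-sided Fisher exact test comparing two correct/incorrect rows,
    e.g. the classification outcomes of two pipeline variants."""
    a = [int(v) for v in counts_a]
    b = [int(v) for v in counts_b]
    if min(a + b) < 0:
        raise ValueError("counts must be non-negative")
    _, p = sstats.fisher_exact([a, b], alternative="two-sided")
    return float(p)
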
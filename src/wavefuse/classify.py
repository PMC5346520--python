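"""Single-modality binary classification under leave-one-out cross-validation.

Each subject is predicted by a linear soft-margin SVM trained on all other
subjects, with feature scaling estimated on the training fold only (no
leakage into the held-out row).  Performance is summarized as sensitivity,
specificity and balanced accuracy; significance comes from label-permutation
tests; linear weight vectors are averaged over folds and summarized per
anatomical region for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)

from .features import ModalityFeatures

__all__ = [
    "ClassificationProblem",
    "CASE_PROBLEM",
    "DISORDER_PROBLEM",
    "problem_labels",
    "FeatureScaler",
    "CVResult",
    "balanced_accuracy_from_rates",
    "confusion_metrics",
    "loocv_classify",
    "permutation_test",
    "summarize_region_weights",
]


@dataclass(frozen=True)
class ClassificationProblem:
    """One of the two binary problems.

    ``case``: any-disorder (GAD or MD, comorbidity included) vs. healthy
    controls; the disorder group is the positive (sensitivity) class.
    ``disorder``: GAD (with or without comorbid MD) vs. MD-only, healthy
    subjects excluded; GAD is the positive class.
    """

    name: str
    positive_groups: tuple
    negative_groups: tuple

    def label(self, group: str) -> int | None:
        """+1 for the positive class, -1 for the negative, None if excluded."""
        if group in self.positive_groups:
            return 1
        if group in self.negative_groups:
            return -1
        return None


CASE_PROBLEM = ClassificationProblem("case", ("GAD", "MD"), ("HC",))
DISORDER_PROBLEM = ClassificationProblem("disorder", ("GAD",), ("MD",))
_PROBLEMS = {"case": CASE_PROBLEM, "disorder": DISORDER_PROBLEM}


def get_problem(name: str) -> ClassificationProblem:
    try:
        return _PROBLEMS[name]
    except KeyError:
        raise ValueError(f"unknown problem {name!r}; expected 'case' or 'disorder'")


def problem_labels(subjects, problem: ClassificationProblem) -> tuple[list[str], np.ndarray]:
    """Subject ids and +/-1 labels for the subjects a problem includes."""
    ids, y = [], []
    for s in subjects:
        lab = problem.label(s.group)
        if lab is not None:
            ids.append(s.subject_id)
            y.append(lab)
    return ids, np.asarray(y, dtype=int)


class FeatureScaler:
    """Per-column mean centering and unit-variance scaling.

    Parameters are estimated on training rows only and applied unchanged to
    held-out rows.  Constant columns are centered and passed through with a
    zero-scale guard (divisor 1).
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaler on an empty matrix")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class CVResult:
    """Aggregated LOOCV output for one modality and one problem."""

    problem: str
    modality: str
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    weight_vector: np.ndarray
    correct: np.ndarray
    p_value: float | None = None
    null_distribution: np.ndarray | None = None

    def as_dict(self) -> dict:
        d = {
            "problem": self.problem,
            "modality": self.modality,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        return d


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy (percent) as the mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity, specificity and balanced accuracy (percent) from counts.

    Balanced accuracy is exactly (sensitivity + specificity) / 2, which makes
    it robust to unequal group sizes.
    """
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one subject in each class")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM primal solution (w, b), oriented toward +1.

    Thin wrapper around scikit-learn's libsvm binding: LOOCV inside
    permutation loops makes per-fit estimator validation the dominant cost,
    so the binding is called directly on pre-validated arrays.  The decision
    function ``X @ w + b`` agrees with
    ``SVC(kernel="linear", C=C).decision_function`` (positive means the +1
    class); the orientation of libsvm's raw output is recovered from the
    sign of the first support vector's dual coefficient, which always equals
    that vector's label under libsvm's internal class ordering.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    out = _libsvm.fit(
        X, y, svm_type=0, kernel="linear", C=C,
        class_weight=np.empty(0), sample_weight=np.ones(len(y)),
    )
    support, sv, _, dual_coef, intercept = out[:5]
    w = (dual_coef @ sv).ravel()
    b = float(intercept[0])
    sign = float(y[support[0]]) * (1.0 if dual_coef[0, 0] > 0 else -1.0)
    return sign * w, sign * b


def _loocv_predictions(
    X: np.ndarray, y: np.ndarray, C: float, scaling_fit_on: str
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out +/-1 predictions and the fold-averaged primal weight vector."""
    n = len(y)
    preds = np.empty(n, dtype=int)
    weights = np.zeros(X.shape[1])
    whole_scaler = FeatureScaler().fit(X) if scaling_fit_on == "all" else None
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if y_tr.max() == y_tr.min():
            raise ValueError("training fold contains a single class")
        scaler = whole_scaler if whole_scaler is not None else FeatureScaler().fit(X[train])
        w, b = fit_linear_svm(scaler.transform(X[train]), y_tr, C)
        # ties (decision exactly 0) go to the positive class
        score = float((scaler.transform(X[i : i + 1]) @ w)[0] + b)
        preds[i] = 1 if score >= 0.0 else -1
        weights += w
    return preds, weights / n


def loocv_classify(
    features: ModalityFeatures,
    problem: ClassificationProblem | str,
    subjects=None,
    y: np.ndarray | None = None,
    C: float = 1.0,
    scaling_fit_on: str = "train",
) -> CVResult:
    """Leave-one-out SVM classification of one modality.

    Labels come either from ``subjects`` (records with ``group`` fields,
    filtered by the problem definition) or directly from ``y`` (+/-1 per
    row of the feature matrix).  Each fold fits the scaler and a linear
    SVM (soft margin, default C=1) on n-1 subjects and predicts the one
    held out; confusion counts are aggregated over folds.
    """
    if isinstance(problem, str):
        problem = get_problem(problem)
    if y is None:
        if subjects is None:
            raise ValueError("provide either subjects or y")
        ids, y_all = problem_labels(subjects, problem)
        present = [sid for sid in ids if sid in set(features.subject_ids)]
        y = y_all[[i for i, sid in enumerate(ids) if sid in set(features.subject_ids)]]
        feats = features.select_subjects(present)
    else:
        y = np.asarray(y, dtype=int)
        feats = features
        if len(y) != feats.matrix.shape[0]:
            raise ValueError("y length must match feature rows")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +/-1")
    for cls in (-1, 1):
        if int(np.sum(y == cls)) < 2:
            raise ValueError("need at least 2 subjects per class for LOOCV")

    preds, weights = _loocv_predictions(feats.matrix, y, C, scaling_fit_on)
    tp = int(np.sum((preds == 1) & (y == 1)))
    fn = int(np.sum((preds == -1) & (y == 1)))
    tn = int(np.sum((preds == -1) & (y == -1)))
    fp = int(np.sum((preds == 1) & (y == -1)))
    metrics = confusion_metrics(tp, fn, tn, fp)
    return CVResult(
        problem=problem.name,
        modality=feats.modality,
        subject_ids=list(feats.subject_ids),
        y_true=y,
        y_pred=preds,
        tp=tp, fn=fn, tn=tn, fp=fp,
        weight_vector=weights,
        correct=(preds == y).astype(int),
        **metrics,
    )


def permutation_test(
    features: ModalityFeatures,
    problem: ClassificationProblem | str,
    subjects=None,
    y: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    scaling_fit_on: str = "train",
) -> CVResult:
    """Label-permutation significance of the LOOCV balanced accuracy.

    The full LOOCV is re-run on each of ``n_perm`` unstratified random
    permutations of the label vector.  The p-value uses the add-one
    estimator p = (#{null >= observed} + 1) / (n_perm + 1), which can never
    be exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = loocv_classify(
        features, problem, subjects=subjects, y=y, C=C, scaling_fit_on=scaling_fit_on
    )
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(observed.y_true)
        feats = features if y is not None else features.select_subjects(observed.subject_ids)
        res = loocv_classify(
            feats, problem, y=y_perm, C=C, scaling_fit_on=scaling_fit_on
        )
        null[b] = res.balanced_accuracy
    k = int(np.sum(null >= observed.balanced_accuracy))
    observed.p_value = (k + 1) / (n_perm + 1)
    observed.null_distribution = null
    return observed


def summarize_region_weights(
    weight_vector: np.ndarray, feature_meta: pd.DataFrame
) -> pd.DataFrame:
    """Rank regions by the mean absolute SVM weight of their features.

    For each region label, ``weight_abs`` is the mean of |w| over the
    region's columns and ``weight_perc`` is 100 * weight_abs over the sum of
    weight_abs across regions, so percentages total 100.  Rows are ranked
    descending by weight_abs; exact ties break alphabetically by region.
    """
    w = np.abs(np.asarray(weight_vector, dtype=float))
    if "region" not in feature_meta.columns:
        raise ValueError("feature_meta must carry a 'region' column")
    if feature_meta["region"].isna().any():
        raise ValueError("every feature column needs a region label")
    if len(w) != len(feature_meta):
        raise ValueError("weight vector and feature_meta length mismatch")
    df = pd.DataFrame({"region": feature_meta["region"].to_numpy(), "absw": w})
    grouped = df.groupby("region", sort=False).agg(
        weight_abs=("absw", "mean"), voxel_count=("absw", "size")
    )
    total = grouped["weight_abs"].sum()
    if total == 0:
        grouped["weight_perc"] = 0.0
    else:
        grouped["weight_perc"] = 100.0 * grouped["weight_abs"] / total
    out = (
        grouped.reset_index()
        .sort_values(["weight_abs", "region"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out[["rank", "region", "weight_abs", "weight_perc", "voxel_count"]]
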
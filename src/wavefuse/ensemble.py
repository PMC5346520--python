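"""Weight-adjusted voting ensembles (WAVE) under nested LOOCV.

WAVE fuses several binary classifiers by iterating a mutually reinforcing
pair of weight vectors on a binary performance matrix X (subjects x
classifiers, 1 = held-out prediction correct):

    case weights        q  ∝  (1 - X) p    (subjects missed by currently
                                            good classifiers are difficult)
    classifier weights  p  ∝  Xᵀ q         (classifiers correct on difficult
                                            subjects are good)

both L1-normalized each step, starting from uniform weights.  Because the
performance matrix must be estimated without touching the subject being
predicted, the fusion runs inside a nested leave-one-out scheme: for each
outer held-out subject, a full inner LOOCV on the remaining n-1 subjects
builds X and the classifier weights, the per-modality classifiers are
refit on those n-1 subjects, and their +/-1 votes on the outer subject are
combined as sign(sum_j p_j vote_j).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    ClassificationProblem,
    FeatureScaler,
    confusion_metrics,
    fit_linear_svm,
    get_problem,
    _loocv_predictions,
)
from .features import ModalityFeatures, restrict_to_common

__all__ = [
    "WaveWeights",
    "EnsembleResult",
    "wave_weights",
    "nested_loocv_ensemble",
    "ensemble_permutation_test",
    "compare_classifier_weights",
]


@dataclass
class WaveWeights:
    classifier_weights: np.ndarray  # p, length k, simplex
    case_weights: np.ndarray        # q, length n, simplex
    iterations: int
    converged: bool
    degenerate: bool = False


def wave_weights(
    X: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> WaveWeights:
    """Fixed point of the WAVE weight iteration on a performance matrix.

    ``X`` is subjects x classifiers with entries in {0, 1}.  Substituting
    one relation into the other shows a fixed point satisfies
    p ∝ Xᵀ(1 - X) p, i.e. p is the Perron (nonnegative dominant)
    eigenvector of A = Xᵀ(1 - X); q follows as the normalization of
    (1 - X) p.  The plain alternating update is power iteration on A and
    can oscillate when A's spectrum contains -λ_max (tiny matrices), so the
    iteration is damped to (I + A) p — which has exactly the same fixed
    points and always converges on nonnegative A.  Degenerate matrices
    (all correct or all wrong, where difficulty carries no information)
    return uniform weights with ``degenerate=True``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a nonempty 2D matrix")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("X must be binary")
    n, k = X.shape
    p = np.full(k, 1.0 / k)
    q = np.full(n, 1.0 / n)
    if np.all(X == 1.0) or np.all(X == 0.0):
        return WaveWeights(p, q, iterations=0, converged=True, degenerate=True)
    miss = 1.0 - X
    A = X.T @ miss
    iterations = max_iter
    converged = False
    for it in range(1, max_iter + 1):
        p_new = p + A @ p
        s = p_new.sum()
        p_new = np.full(k, 1.0 / k) if s == 0.0 else p_new / s
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            iterations, converged = it, True
            break
    q = miss @ p
    s = q.sum()
    q = np.full(n, 1.0 / n) if s == 0.0 else q / s
    return WaveWeights(p, q, iterations=iterations, converged=converged)


@dataclass
class EnsembleResult:
    """Nested-LOOCV fusion output for one classification problem."""

    problem: str
    modalities: list[str]
    subject_ids: list[str]
    y_true: np.ndarray
    votes: np.ndarray          # outer folds x modalities, +/-1
    fused_pred: np.ndarray     # +/-1 per outer fold
    weight_trace: pd.DataFrame  # outer folds x modalities, classifier weights
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    p_value: float | None = None
    null_distribution: np.ndarray | None = None

    @property
    def mean_weights(self) -> pd.Series:
        return self.weight_trace.mean(axis=0)

    def as_dict(self) -> dict:
        d = {
            "problem": self.problem,
            "modalities": self.modalities,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "mean_weights": {k: float(v) for k, v in self.mean_weights.items()},
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        return d


def _fit_and_vote(
    X: np.ndarray, y: np.ndarray, x_new: np.ndarray, C: float, scaling_fit_on: str
) -> int:
    """Train scaler+SVM on (X, y) and vote +/-1 on one new subject."""
    if scaling_fit_on == "all":
        scaler = FeatureScaler().fit(np.vstack([X, x_new]))
    else:
        scaler = FeatureScaler().fit(X)
    w, b = fit_linear_svm(scaler.transform(X), y, C)
    score = float((scaler.transform(x_new) @ w)[0] + b)
    return 1 if score >= 0.0 else -1


def nested_loocv_ensemble(
    modality_features: Mapping[str, ModalityFeatures],
    problem: ClassificationProblem | str,
    subjects=None,
    y: np.ndarray | None = None,
    C: float = 1.0,
    scaling_fit_on: str = "train",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> EnsembleResult:
    """WAVE fusion of per-modality SVMs under nested LOOCV.

    Every subject must be present in every modality (screen out subjects
    with incomplete data first, e.g. via :func:`restrict_to_common`).  For
    each outer held-out subject the remaining n-1 subjects supply, per
    modality, an inner LOOCV performance column; the WAVE classifier
    weights from that inner fold weight each modality's +/-1 vote on the
    outer subject, and the fused prediction is the sign of the weighted
    vote sum (ties go to the positive class).
    """
    if isinstance(problem, str):
        problem = get_problem(problem)
    names = list(modality_features)
    if not names:
        raise ValueError("no modalities provided")
    ids0 = modality_features[names[0]].subject_ids
    for name in names[1:]:
        if set(modality_features[name].subject_ids) != set(ids0):
            raise ValueError(
                "subject sets differ across modalities; apply restrict_to_common first"
            )
    aligned = restrict_to_common(modality_features)

    if y is None:
        if subjects is None:
            raise ValueError("provide either subjects or y")
        lab = {s.subject_id: problem.label(s.group) for s in subjects}
        keep = [sid for sid in aligned[names[0]].subject_ids if lab.get(sid) is not None]
        aligned = {name: m.select_subjects(keep) for name, m in aligned.items()}
        y = np.asarray([lab[sid] for sid in keep], dtype=int)
    else:
        y = np.asarray(y, dtype=int)
        if len(y) != len(aligned[names[0]].subject_ids):
            raise ValueError("y length must match subject count")
    sub_ids = aligned[names[0]].subject_ids
    n = len(y)
    k = len(names)
    mats = {name: aligned[name].matrix for name in names}

    votes = np.empty((n, k), dtype=int)
    fused = np.empty(n, dtype=int)
    trace = np.empty((n, k))
    for i in range(n):
        inner = np.ones(n, dtype=bool)
        inner[i] = False
        y_in = y[inner]
        perf = np.empty((n - 1, k))
        for j, name in enumerate(names):
            X_in = mats[name][inner]
            preds, _ = _loocv_predictions(X_in, y_in, C, scaling_fit_on)
            perf[:, j] = (preds == y_in).astype(float)
            votes[i, j] = _fit_and_vote(
                X_in, y_in, mats[name][i : i + 1], C, scaling_fit_on
            )
        ww = wave_weights(perf, tol=tol, max_iter=max_iter)
        trace[i] = ww.classifier_weights
        score = float(trace[i] @ votes[i])
        fused[i] = 1 if score >= 0.0 else -1

    tp = int(np.sum((fused == 1) & (y == 1)))
    fn = int(np.sum((fused == -1) & (y == 1)))
    tn = int(np.sum((fused == -1) & (y == -1)))
    fp = int(np.sum((fused == 1) & (y == -1)))
    metrics = confusion_metrics(tp, fn, tn, fp)
    return EnsembleResult(
        problem=problem.name,
        modalities=names,
        subject_ids=list(sub_ids),
        y_true=y,
        votes=votes,
        fused_pred=fused,
        weight_trace=pd.DataFrame(trace, columns=names),
        tp=tp, fn=fn, tn=tn, fp=fp,
        **metrics,
    )


def _balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    pos = y == 1
    neg = y == -1
    if not pos.any() or not neg.any():
        return np.nan
    sens = np.mean(pred[pos] == 1)
    spec = np.mean(pred[neg] == -1)
    return 100.0 * (sens + spec) / 2.0


def ensemble_permutation_test(
    result: EnsembleResult,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    scheme: str = "fixed",
    rerun_kwargs: dict | None = None,
) -> EnsembleResult:
    """Label-permutation significance of the fused balanced accuracy.

    ``scheme="fixed"`` (default) keeps the fused predictions and per-fold
    classifier weights from the completed run and rescoring them against
    each permuted label vector; the p-value is the strict-inequality count
    #{permuted accuracy > observed} / n_perm, which can be exactly zero.
    ``scheme="full"`` re-runs the entire nested ensemble on each permuted
    label vector (orders of magnitude slower; a sensitivity analysis).
    """
    if scheme not in ("fixed", "full"):
        raise ValueError("scheme must be 'fixed' or 'full'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = result.balanced_accuracy
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(result.y_true)
        if scheme == "fixed":
            null[b] = _balanced_accuracy(result.fused_pred, y_perm)
        else:
            kwargs = dict(rerun_kwargs or {})
            mods = kwargs.pop("modality_features")
            res = nested_loocv_ensemble(mods, result.problem, y=y_perm, **kwargs)
            null[b] = res.balanced_accuracy
    result.p_value = float(np.sum(null > obs)) / n_perm
    result.null_distribution = null
    return result


def compare_classifier_weights(weight_trace: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-tests on classifier weights across outer folds.

    Returns one row per modality pair with mean weights, the mean paired
    difference, t and p.  Pairs whose fold-wise differences have zero
    variance are flagged and get p = NaN.
    """
    if len(weight_trace) < 2:
        raise ValueError("need at least 2 outer folds to compare weights")
    rows = []
    for a, b in combinations(weight_trace.columns, 2):
        diff = weight_trace[a].to_numpy() - weight_trace[b].to_numpy()
        zero_var = np.allclose(diff, diff[0])
        if zero_var:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_rel(weight_trace[a], weight_trace[b])
        rows.append({
            "modality_a": a,
            "modality_b": b,
            "mean_a": weight_trace[a].mean(),
            "mean_b": weight_trace[b].mean(),
            "mean_diff": diff.mean(),
            "t": t,
            "p": p,
            "zero_variance": zero_var,
        })
    return pd.DataFrame(rows)
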
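"""WAVE fixed point and nested-LOOCV multimodal fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wavefuse as wf
from wavefuse.ensemble import (
    compare_classifier_weights,
    ensemble_permutation_test,
    nested_loocv_ensemble,
    wave_weights,
)

from conftest import separated_clouds


def eig_wave_oracle(X):
    """Independent route to the WAVE classifier weights: the Perron
    eigenvector of A = X'(1-X), via dense eigendecomposition."""
    A = X.T @ (1.0 - X)
    vals, vecs = np.linalg.eig(A)
    v = np.abs(np.real(vecs[:, np.argmax(np.real(vals))]))
    return v / v.sum()


class TestWaveWeights:
    def test_identical_columns_give_uniform_weights(self):
        X = np.array([[1, 1], [0, 0], [1, 1], [0, 0]], dtype=float)
        ww = wave_weights(X)
        assert np.allclose(ww.classifier_weights, 0.5)

    def test_always_correct_dominates_always_wrong(self):
        # A = X'(1-X) is nilpotent here, so convergence toward the
        # always-correct classifier is polynomial rather than geometric;
        # the ordering is what matters.
        X = np.array([[1, 0, 1], [1, 0, 0], [1, 0, 1], [1, 0, 0]], dtype=float)
        p = wave_weights(X, max_iter=5000).classifier_weights
        assert p[0] > p[2] > p[1]
        assert p[1] < 1e-3

    def test_three_subject_fixture_matches_eigen_oracle(self):
        X = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        ww = wave_weights(X, tol=1e-12)
        assert ww.converged
        # closed form: p ∝ (sqrt(2), 1)
        expect = np.array([np.sqrt(2), 1.0]) / (np.sqrt(2) + 1.0)
        assert np.allclose(ww.classifier_weights, expect, atol=1e-8)
        assert np.allclose(ww.classifier_weights, eig_wave_oracle(X), atol=1e-8)

    def test_degenerate_matrices_return_flagged_uniform(self):
        for X in (np.ones((4, 3)), np.zeros((4, 3))):
            ww = wave_weights(X)
            assert ww.degenerate
            assert np.allclose(ww.classifier_weights, 1 / 3)
            assert np.allclose(ww.case_weights, 1 / 4)

    def test_weights_stay_in_simplex_and_respect_reordering(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X = (rng.random((9, 4)) < 0.65).astype(float)
            if X.all() or not X.any():
                continue
            ww = wave_weights(X, tol=1e-12)
            p, q = ww.classifier_weights, ww.case_weights
            assert (p >= -1e-15).all() and p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (q >= -1e-15).all() and q.sum() == pytest.approx(1.0, abs=1e-12)
            rows = rng.permutation(9)
            cols = rng.permutation(4)
            ww2 = wave_weights(X[np.ix_(rows, cols)], tol=1e-12)
            assert np.allclose(ww2.classifier_weights, p[cols], atol=1e-8)
            assert np.allclose(ww2.case_weights, q[rows], atol=1e-8)

    def test_duplicated_column_preserves_order_of_untouched_columns(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            X = (rng.random((12, 4)) < 0.6).astype(float)
            if X.all() or not X.any():
                continue
            p = wave_weights(X, tol=1e-12).classifier_weights
            Xd = np.hstack([X, X[:, :1]])  # duplicate classifier 0
            pd_ = wave_weights(Xd, tol=1e-12).classifier_weights
            # pairwise order among the classifiers that were not duplicated
            for i in range(1, 4):
                for j in range(i + 1, 4):
                    if abs(p[i] - p[j]) > 1e-9:
                        assert np.sign(p[i] - p[j]) == np.sign(pd_[i] - pd_[j])
            # the two copies share the duplicated classifier's weight
            assert pd_[0] == pytest.approx(pd_[4], abs=1e-9)

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            wave_weights(np.array([[0.5, 1.0]]))


def test_identical_modalities_reduce_to_single_classifier(make_modality):
    """When every modality is the same matrix, the fused prediction for
    each outer subject equals the LOOCV prediction of that matrix alone."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(14, 3)) + np.array([1] * 7 + [-1] * 7)[:, None]
    y = np.array([1] * 7 + [-1] * 7)
    mods = {name: make_modality(X, modality=name) for name in "abcd"}
    res = nested_loocv_ensemble(mods, "case", y=y)
    single = wf.loocv_classify(make_modality(X), "case", y=y)
    assert np.array_equal(res.fused_pred, single.y_pred)
    assert np.allclose(res.weight_trace.to_numpy(), 0.25)


def test_perfect_modality_dominates_noise_modalities(make_modality):
    """Fused accuracy tracks the informative modality (within 5 points on
    average) when the other modalities are pure noise."""
    diffs = []
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        n = 16
        y = np.array([1] * 8 + [-1] * 8)
        good = y[:, None] * 5.0 + rng.normal(0, 0.5, size=(n, 2))
        mods = {
            "good": make_modality(good, modality="good"),
            "noise1": make_modality(rng.normal(size=(n, 3)), modality="noise1"),
            "noise2": make_modality(rng.normal(size=(n, 3)), modality="noise2"),
        }
        res = nested_loocv_ensemble(mods, "case", y=y)
        single = wf.loocv_classify(mods["good"], "case", y=y)
        diffs.append(res.balanced_accuracy - single.balanced_accuracy)
        assert res.mean_weights.idxmax() == "good"
    assert abs(np.mean(diffs)) < 5.0


def test_outer_subject_never_leaks_into_inner_fold(make_modality):
    """Replacing the outer held-out subject's features by extreme outliers
    must not change that fold's performance matrix, WAVE weights, or the
    other subjects' votes."""
    rng = np.random.default_rng(21)
    n = 12
    y = np.array([1] * 6 + [-1] * 6)
    base = {
        "m1": y[:, None] * 2.0 + rng.normal(0, 1.0, size=(n, 2)),
        "m2": rng.normal(size=(n, 3)),
    }
    mods_a = {k: make_modality(v, modality=k) for k, v in base.items()}
    tampered = {k: v.copy() for k, v in base.items()}
    tampered["m1"][0] = 1e6
    tampered["m2"][0] = -1e6
    mods_b = {k: make_modality(v, modality=k) for k, v in tampered.items()}
    res_a = nested_loocv_ensemble(mods_a, "case", y=y)
    res_b = nested_loocv_ensemble(mods_b, "case", y=y)
    assert np.allclose(res_a.weight_trace.iloc[0], res_b.weight_trace.iloc[0],
                       atol=1e-10)


def test_mismatched_subject_sets_rejected(make_modality):
    a = make_modality(np.zeros((4, 2)) + np.arange(4)[:, None], ids=list("wxyz"))
    b = make_modality(np.ones((4, 2)), ids=list("wxyQ"))
    with pytest.raises(ValueError, match="differ across modalities"):
        nested_loocv_ensemble({"a": a, "b": b}, "case", y=np.array([1, 1, -1, -1]))


class TestEnsemblePermutation:
    def test_perfect_observed_accuracy_gives_zero_p(self, make_modality):
        X, y = separated_clouds(8, 8, gap=10.0, noise=0.4, seed=2)
        mods = {n: make_modality(X, modality=n) for n in ("a", "b")}
        res = nested_loocv_ensemble(mods, "case", y=y)
        assert res.balanced_accuracy == 100.0
        res = ensemble_permutation_test(res, n_perm=99, seed=5)
        # strict ">" counting: nothing beats a perfect prediction
        assert res.p_value == 0.0

    def test_null_ensemble_shows_no_spurious_skill(self, make_modality):
        """On pure-noise modalities the fused classifier must not rise
        above chance.  Mean null accuracy sits below 50% (the LOOCV
        anti-correlation bias, mildly amplified by weighted voting), and
        the permutation p is not systematically small; occasional p = 0
        comes from the strict ">" counting when every permutation ties."""
        baccs, ps = [], []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            n = 16
            y = np.array([1] * 8 + [-1] * 8)
            mods = {
                nme: make_modality(rng.normal(size=(n, 3)), modality=nme)
                for nme in ("a", "b", "c")
            }
            res = nested_loocv_ensemble(mods, "case", y=y)
            res = ensemble_permutation_test(res, n_perm=99, seed=rep)
            baccs.append(res.balanced_accuracy)
            ps.append(res.p_value)
        assert 33.0 < np.mean(baccs) < 53.0
        assert np.mean(ps) > 0.3

    def test_full_rerun_scheme_runs(self, make_modality):
        X, y = separated_clouds(6, 6, gap=8.0, noise=0.5, seed=3)
        mods = {n: make_modality(X, modality=n) for n in ("a", "b")}
        res = nested_loocv_ensemble(mods, "case", y=y)
        res = ensemble_permutation_test(
            res, n_perm=5, seed=1, scheme="full",
            rerun_kwargs={"modality_features": mods},
        )
        assert 0.0 <= res.p_value <= 1.0


class TestCompareClassifierWeights:
    def test_identical_weights_flagged_zero_variance(self):
        trace = pd.DataFrame({"a": [0.5] * 6, "b": [0.5] * 6})
        out = compare_classifier_weights(trace)
        assert out.loc[0, "zero_variance"]
        assert np.isnan(out.loc[0, "p"])

    def test_matches_hand_computed_paired_t(self):
        rng = np.random.default_rng(9)
        a = 0.5 + rng.normal(0, 0.05, 15)
        b = 0.3 + rng.normal(0, 0.05, 15)
        trace = pd.DataFrame({"a": a, "b": b})
        out = compare_classifier_weights(trace)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), len(d) - 1)
        assert out.loc[0, "t"] == pytest.approx(t_hand, rel=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p_hand, rel=1e-10)
        assert out.loc[0, "mean_diff"] == pytest.approx(d.mean())

    def test_requires_two_folds(self):
        with pytest.raises(ValueError, match="2 outer folds"):
            compare_classifier_weights(pd.DataFrame({"a": [1.0], "b": [0.0]}))
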
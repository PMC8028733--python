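"""Feature selection, boosting classifier, LOOCV/external evaluation,
ROC/AUC, and the PCA batch diagnostic."""

import numpy as np
import pandas as pd
import pytest

import radiotme as rt
from radiotme.prediction import (
    fit_classifier,
    loocv_eval,
    external_eval,
    pca_batch_check,
    rfe_select,
    roc_auc,
)
from radiotme.synthetic import make_planted_classification

from oracles import oracle_auc

FAST_SIZES = (2, 3, 5, 8)


def test_roc_hand_examples():
    auc, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    assert roc[0] == pytest.approx([0.0, 0.0])
    assert roc[-1] == pytest.approx([1.0, 1.0])
    auc_t, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert auc_t == 0.5


@pytest.mark.parametrize("trial", range(25))
def test_auc_equals_mann_whitney_identity(trial):
    rng = np.random.default_rng(4000 + trial)
    n = int(rng.integers(6, 40))
    labels = np.zeros(n, dtype=int)
    labels[: max(1, n // 3)] = 1
    rng.shuffle(labels)
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    auc, roc = roc_auc(scores, labels)
    assert auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)
    # ROC monotone nondecreasing in both coordinates
    assert np.all(np.diff(roc[:, 0]) >= 0)
    assert np.all(np.diff(roc[:, 1]) >= 0)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.5).astype(int)
    labels[0], labels[1] = 1, 0
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(np.exp(3 * scores) + 7, labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_label_inversion_symmetry(rng):
    scores = rng.normal(size=30)
    labels = (rng.random(30) < 0.5).astype(int)
    labels[0], labels[1] = 1, 0
    a, _ = roc_auc(scores, labels)
    a_inv, _ = roc_auc(scores, 1 - labels)
    assert a_inv == pytest.approx(1.0 - a, abs=1e-12)


def test_rfe_forced_size_and_determinism():
    X, y = make_planted_classification(40, 3, 17, 1.5, seed=5)
    sel1 = rfe_select(X, y, candidate_sizes=(4,), seed=0, cv_repeats=1)
    assert len(sel1) == 4
    sel2 = rfe_select(X, y, candidate_sizes=(4,), seed=0, cv_repeats=1)
    assert sel1 == sel2


def test_rfe_recovers_informative_features():
    """5 informative + 95 noise features, n=200, d=1.5: the selected set
    contains at least 4 of the 5 informative features."""
    X, y = make_planted_classification(200, 5, 95, 1.5, seed=11)
    sel = rfe_select(X, y, candidate_sizes=FAST_SIZES, seed=0, cv_repeats=2)
    hits = sum(s.startswith("inf") for s in sel)
    assert hits >= 4


def test_rfe_rejects_single_class():
    X, _ = make_planted_classification(20, 2, 8, 1.0, seed=1)
    with pytest.raises(ValueError):
        rfe_select(X, np.ones(20, dtype=int), candidate_sizes=(2,))


def test_classifier_separable_and_constant_cases():
    X, y = make_planted_classification(40, 2, 0, 6.0, seed=3)
    model = fit_classifier(X, y, seed=0)
    auc, _ = roc_auc(model.predict_proba(X.to_numpy())[:, 1], y)
    assert auc == 1.0
    # constant features: every prediction equals the base rate
    Xc = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
    yc = np.array([0, 1] * 10)
    mc = fit_classifier(Xc, yc, seed=0)
    p = mc.predict_proba(Xc.to_numpy())[:, 1]
    assert np.allclose(p, p[0])
    assert p[0] == pytest.approx(0.5, abs=0.05)


def test_classifier_seed_reproducibility():
    X, y = make_planted_classification(30, 3, 10, 1.0, seed=8)
    p1 = fit_classifier(X, y, seed=4).predict_proba(X.to_numpy())[:, 1]
    p2 = fit_classifier(X, y, seed=4).predict_proba(X.to_numpy())[:, 1]
    np.testing.assert_array_equal(p1, p2)


def test_loocv_produces_n_scores_and_separates():
    X, y = make_planted_classification(30, 4, 6, 2.0, seed=2)
    res = loocv_eval(X, y, seed=0)
    assert len(res["scores"]) == 30
    assert res["auc"] >= 0.85
    # rerun determinism
    res2 = loocv_eval(X, y, seed=0)
    assert res2["auc"] == res["auc"]


def test_external_eval_matched_distribution():
    X, y = make_planted_classification(80, 4, 6, 2.0, seed=6)
    X_te, y_te = make_planted_classification(100, 4, 6, 2.0, seed=7)
    model = fit_classifier(X, y, seed=0)
    res = external_eval(model, X_te, y_te)
    assert res["auc"] >= 0.85
    # label inversion symmetry on the same scores
    inv = roc_auc(res["scores"], 1 - y_te)[0]
    assert inv == pytest.approx(1.0 - res["auc"], abs=1e-12)


def test_pca_batch_check_null_and_planted_shift(rng):
    a = pd.DataFrame(rng.normal(size=(40, 30)),
                     columns=[f"f{i}" for i in range(30)])
    b = pd.DataFrame(rng.normal(size=(40, 30)),
                     columns=[f"f{i}" for i in range(30)])
    _, sil0 = pca_batch_check(a, b)
    assert abs(sil0) <= 0.1
    shifted = b.copy()
    shifted.iloc[:, :15] += 5.0  # 5 pooled-SD shift on half the features
    coords, sil5 = pca_batch_check(a, shifted)
    assert sil5 > 0.5
    # deterministic up to per-component sign
    coords2, _ = pca_batch_check(a, shifted)
    for k in range(2):
        assert (np.allclose(coords[:, k], coords2[:, k])
                or np.allclose(coords[:, k], -coords2[:, k]))


def test_evaluate_population_record():
    X, y = make_planted_classification(40, 4, 16, 2.0, seed=9)
    labels = pd.Series(np.where(y == 1, "high", "low"), index=X.index)
    ev = rt.evaluate_population("Fibroblasts", X, labels,
                               candidate_sizes=FAST_SIZES, seed=0)
    assert ev.population == "Fibroblasts"
    assert len(ev.selected_features) in FAST_SIZES
    assert 0.0 <= ev.loocv_auc <= 1.0
    assert ev.roc_loocv[0] == pytest.approx([0.0, 0.0])
    assert ev.selection_mode == "selection_outside_loocv"
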
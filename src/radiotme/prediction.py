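"""High/low infiltration classification and evaluation.

Per cell population: recursive feature elimination (random-forest
importance, candidate subset sizes scored by repeated cross-validated
accuracy) selects a feature subset on the training cohort; a binary
logistic gradient-boosting classifier (xgboost) is then evaluated by
leave-one-out cross-validation (held-out scores pooled into a single ROC)
and, optionally, on an external cohort stratified by its own medians.

By default feature selection runs once on the full training cohort and
LOOCV is run on the selected features (matching a single reported feature
count per model); a strict mode that nests the selection inside every
LOOCV fold is available, and the evaluation record states which mode ran.

A PCA batch diagnostic is included: pooled z-scored features from two
cohorts are projected on the top two principal components and the
institution labels' silhouette coefficient quantifies batch separation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve, silhouette_score
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from xgboost import XGBClassifier

from .catalog import POPULATIONS
from .datatypes import AbundanceTable, ModelEval

DEFAULT_CANDIDATE_SIZES = (2, 3, 4, 6, 8, 10, 12, 16, 20)

DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
}


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y = (y == "high").astype(int)
    y = y.astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels are single-class; cannot classify")
    if set(classes.tolist()) - {0, 1}:
        raise ValueError("labels must be binary")
    return y


def rfe_select(
    X: pd.DataFrame,
    y,
    candidate_sizes=DEFAULT_CANDIDATE_SIZES,
    seed: int = 0,
    cv_folds: int = 5,
    cv_repeats: int = 5,
    n_trees: int = 100,
) -> list:
    """Backward feature elimination driven by random-forest importance.

    Features are eliminated down through the sorted candidate sizes,
    re-fitting the forest and re-ranking at each step; each candidate
    subset is scored by repeated stratified k-fold accuracy on the
    training set.  Returns the subset with maximal accuracy, ties broken
    toward fewer features.  Deterministic given the seed.
    """
    y = _check_binary(y)
    if len(y) < 10:
        raise ValueError("rfe_select needs >= 10 samples")
    sizes = sorted({s for s in candidate_sizes if s <= X.shape[1]}, reverse=True)
    if not sizes:
        raise ValueError("no candidate size <= number of features")

    subsets = {}
    current = list(X.columns)
    for k in sizes:
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[current], y)
        order = np.argsort(rf.feature_importances_)[::-1]
        current = [current[i] for i in order[:k]]
        subsets[k] = list(current)

    min_class = int(np.bincount(y).min())
    folds = min(cv_folds, min_class)
    cv = RepeatedStratifiedKFold(
        n_splits=max(2, folds), n_repeats=cv_repeats, random_state=seed)
    best_k, best_acc = None, -np.inf
    for k in sorted(subsets):  # ascending: ties keep the smaller size
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        acc = cross_val_score(rf, X[subsets[k]], y, scoring="accuracy", cv=cv).mean()
        if acc > best_acc + 1e-12:
            best_acc, best_k = acc, k
    return subsets[best_k]


def fit_classifier(X, y, hyper: dict | None = None, seed: int = 0) -> XGBClassifier:
    """Binary logistic gradient-boosted tree classifier."""
    y = _check_binary(y)
    params = dict(DEFAULT_HYPERPARAMS)
    if hyper:
        params.update(hyper)
    model = XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        **params,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def roc_auc(scores, labels):
    """Rank-based AUC (midrank tie handling) and the trapezoidal ROC curve.

    Returns (auc, roc_points) with roc_points an (n, 2) array of
    (FPR, TPR) from (0,0) to (1,1).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])


def loocv_eval(
    X: pd.DataFrame,
    y,
    hyper: dict | None = None,
    seed: int = 0,
):
    """Leave-one-out cross-validation with pooled held-out scores.

    Each sample is scored by a model trained on the remaining n-1; all
    held-out scores are pooled into one ROC/AUC.  Each held-out score is
    centered by the fold's mean predicted probability on its training
    set: leaving one sample out shifts the training class prior opposite
    to the held-out label, which biases the pooled AUC of permuted-label
    data below 0.5, and the per-fold centering removes that artifact
    without affecting a real signal.  Folds whose training labels
    collapse to a single class are scored at the center (0) and flagged.
    """
    y = _check_binary(y)
    Xa = np.asarray(X, dtype=float)
    n = len(y)
    scores = np.empty(n)
    flagged = []
    for i in range(n):
        idx = np.arange(n) != i
        y_tr = y[idx]
        if len(np.unique(y_tr)) < 2:
            scores[i] = 0.0
            flagged.append(i)
            continue
        model = fit_classifier(Xa[idx], y_tr, hyper, seed)
        scores[i] = (float(model.predict_proba(Xa[[i]])[0, 1])
                     - float(model.predict_proba(Xa[idx])[:, 1].mean()))
    auc, roc = roc_auc(scores, y)
    return {"scores": scores, "auc": auc, "roc": roc, "flagged_folds": flagged}


def external_eval(model: XGBClassifier, X_test, y_test):
    """Apply a trained model unchanged to an external cohort."""
    y = _check_binary(y_test)
    s = model.predict_proba(np.asarray(X_test, dtype=float))[:, 1]
    auc, roc = roc_auc(s, y)
    return {"scores": s, "auc": auc, "roc": roc}


def pca_batch_check(features_a: pd.DataFrame, features_b: pd.DataFrame):
    """PCA batch-separation diagnostic between two cohorts.

    Features are z-scored on the pooled table (zero-SD columns left
    centered), projected on the top two principal components, and the
    silhouette coefficient of the cohort labels on those coordinates is
    returned.  Near-zero silhouette means no batch structure; values
    toward 1 indicate separation.
    """
    common = [c for c in features_a.columns if c in features_b.columns]
    pooled = np.vstack([
        features_a[common].to_numpy(dtype=float),
        features_b[common].to_numpy(dtype=float),
    ])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    z = (pooled - mu) / sd
    coords = PCA(n_components=2, svd_solver="full").fit_transform(z)
    labels = np.array([0] * len(features_a) + [1] * len(features_b))
    sil = float(silhouette_score(coords, labels))
    return coords, sil


def evaluate_population(
    population: str,
    features_train: pd.DataFrame,
    labels_train,
    features_test: pd.DataFrame | None = None,
    labels_test=None,
    candidate_sizes=DEFAULT_CANDIDATE_SIZES,
    hyper: dict | None = None,
    seed: int = 0,
    nested_selection: bool = False,
    cv_folds: int = 5,
    cv_repeats: int = 5,
) -> ModelEval:
    """Full per-population evaluation: RFE selection, LOOCV AUC, and
    optional external-cohort AUC."""
    y_tr = _check_binary(labels_train)
    if nested_selection:
        n = len(y_tr)
        scores = np.empty(n)
        for i in range(n):
            idx = np.arange(n) != i
            sel_i = rfe_select(features_train.iloc[idx], y_tr[idx],
                               candidate_sizes, seed, cv_folds, cv_repeats)
            model = fit_classifier(features_train.iloc[idx][sel_i], y_tr[idx],
                                   hyper, seed)
            scores[i] = model.predict_proba(
                features_train.iloc[[i]][sel_i].to_numpy(dtype=float))[0, 1]
        loocv_auc, roc_l = roc_auc(scores, y_tr)
        selected = rfe_select(features_train, y_tr, candidate_sizes, seed,
                              cv_folds, cv_repeats)
        mode = "selection_nested_in_loocv"
    else:
        selected = rfe_select(features_train, y_tr, candidate_sizes, seed,
                              cv_folds, cv_repeats)
        res = loocv_eval(features_train[selected], y_tr, hyper, seed)
        loocv_auc, roc_l = res["auc"], res["roc"]
        mode = "selection_outside_loocv"

    ext_auc, roc_e = None, None
    if features_test is not None and labels_test is not None:
        model = fit_classifier(features_train[selected], y_tr, hyper, seed)
        ext = external_eval(model, features_test[selected], labels_test)
        ext_auc, roc_e = ext["auc"], ext["roc"]

    return ModelEval(
        population=population,
        selected_features=list(selected),
        loocv_auc=loocv_auc,
        external_auc=ext_auc,
        roc_loocv=roc_l,
        roc_external=roc_e,
        seed=seed,
        hyperparams=dict(DEFAULT_HYPERPARAMS, **(hyper or {})),
        selection_mode=mode,
    )


def evaluate_cohort(
    features_train: pd.DataFrame,
    stratified_train: AbundanceTable,
    features_test: pd.DataFrame | None = None,
    stratified_test: AbundanceTable | None = None,
    candidate_sizes=DEFAULT_CANDIDATE_SIZES,
    hyper: dict | None = None,
    seed: int = 0,
    nested_selection: bool = False,
    cv_folds: int = 5,
    cv_repeats: int = 5,
) -> list:
    """Run the per-population evaluation for all 10 cell populations."""
    evals = []
    for k, pop in enumerate(POPULATIONS):
        labels_tr = stratified_train.labels.loc[features_train.index, pop]
        labels_te = None
        feats_te = None
        if features_test is not None and stratified_test is not None:
            labels_te = stratified_test.labels.loc[features_test.index, pop]
            feats_te = features_test
        evals.append(evaluate_population(
            pop, features_train, labels_tr, feats_te, labels_te,
            candidate_sizes, hyper, seed + k, nested_selection,
            cv_folds, cv_repeats))
    return evals
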
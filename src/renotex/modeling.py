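"""Hierarchical stacked classifier for tumor-grade prediction.

The recipe treats a LASSO logistic signature and a random forest as weak
scorers within each feature block and fuses them with linear SVMs:

* texture block:     LASSO Rad-score (score 1) + RF probability (score 2)
                     -> SVM1 decision (score 3)
* traditional block: LASSO score (score 4)     + RF probability (score 5)
                     -> SVM2 decision (score 6)
* combiner:          SVM3 on (score 3, score 6) -> final score 7,
                     binarized at the training Youden threshold.

By default the first-level training scores fed to stacking are cross-fitted
(LASSO) and out-of-bag (RF) to avoid optimistic stacking; ``naive_stacking``
reproduces the literal in-sample recipe.  Every fitting statistic —
standardization, the regularization path, forests, SVMs and the threshold —
derives from training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import _binarize, auc, youden_threshold

import contextlib


@contextlib.contextmanager
def _quiet_sklearn():
    """Silence scikit-learn's l1-penalty API transition warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning,
                                module="sklearn")
        warnings.filterwarnings("ignore", message=".*penalty.*",
                                category=UserWarning)
        yield

__all__ = [
    "standardize_features", "fit_lasso_cv", "lasso_score",
    "fit_rf", "rf_score", "fit_block_svm",
    "StackedGradeClassifier", "fit_stacked_classifier", "predict",
    "TRADITIONAL_COLUMNS",
]

TRADITIONAL_COLUMNS = ["transverse_cm", "anteroposterior_cm",
                       "craniocaudal_cm", "ct_pre_hu", "ct_post_hu",
                       "enhancement_hu"]


# ---------------------------------------------------------------------------
# block-level operations

def standardize_features(X_train: pd.DataFrame,
                         X_apply: Optional[pd.DataFrame] = None
                         ) -> Tuple[pd.DataFrame, Optional[pd.DataFrame], dict]:
    """Z-score by training means/SDs; apply the same transform elsewhere.

    Zero-variance training columns are dropped with a warning; an all-constant
    matrix is an error.  Returns ``(X_train_std, X_apply_std, params)`` where
    ``params`` carries means, sds and the kept column list.
    """
    means = X_train.mean()
    sds = X_train.std(ddof=0)
    keep = sds.index[sds > 0].tolist()
    if not keep:
        raise ValueError("all training columns are constant")
    if len(keep) < X_train.shape[1]:
        dropped = [c for c in X_train.columns if c not in keep]
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    params = {"means": means[keep], "sds": sds[keep], "columns": keep}
    Xt = (X_train[keep] - params["means"]) / params["sds"]
    Xa = None
    if X_apply is not None:
        Xa = (X_apply[keep] - params["means"]) / params["sds"]
    return Xt, Xa, params


@dataclass
class LassoFit:
    model: LogisticRegression
    coefficients: pd.Series
    intercept: float
    selected: List[str]
    C: float


def fit_lasso_cv(X: pd.DataFrame, y, n_folds: int = 10,
                 lambda_rule: str = "min", seed: int = 0,
                 Cs: int = 30) -> LassoFit:
    """L1-penalized logistic regression with seeded stratified CV.

    The penalty is chosen at minimum mean CV deviance (``lambda_rule='min'``)
    or by the one-standard-error rule (``'1se'``: strongest penalty whose mean
    deviance is within one SE of the minimum).  The ``Cs``-point penalty grid
    spans C in [1e-3, 1e2]: from a fully sparse model to weak regularization.
    (Near-unpenalized fits are pointless for a sparse signature and make the
    coordinate-descent solver crawl on separable data.)
    """
    yb = _binarize(y)
    if len(X) < n_folds:
        raise ValueError("fewer samples than CV folds")
    # never ask for more folds than the rarer class can populate
    n_folds = max(2, min(n_folds, int(np.bincount(yb).min())))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    c_grid = np.logspace(-3, 2, Cs)
    lcv = LogisticRegressionCV(Cs=c_grid, cv=cv, penalty="l1",
                               solver="liblinear", scoring="neg_log_loss",
                               refit=True, max_iter=2000, random_state=seed)
    with _quiet_sklearn():
        lcv.fit(X.values, yb)
    if lambda_rule == "min":
        model = lcv
        C = float(lcv.C_[0])
        coef = lcv.coef_.ravel()
        intercept = float(lcv.intercept_[0])
    elif lambda_rule == "1se":
        scores = lcv.scores_[1]                  # folds x Cs (neg log loss)
        mean = scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean))
        ok = np.flatnonzero(mean >= mean[best] - se[best])
        C = float(lcv.Cs_[ok[0]])                # smallest C = strongest penalty
        model = LogisticRegression(penalty="l1", solver="liblinear", C=C,
                                   max_iter=2000, random_state=seed)
        with _quiet_sklearn():
            model.fit(X.values, yb)
        coef = model.coef_.ravel()
        intercept = float(model.intercept_[0])
    else:
        raise ValueError("lambda_rule must be 'min' or '1se'")
    coefficients = pd.Series(coef, index=X.columns)
    selected = coefficients.index[coefficients != 0].tolist()
    return LassoFit(model=model, coefficients=coefficients,
                    intercept=intercept, selected=selected, C=C)


def lasso_score(X: pd.DataFrame, fit: LassoFit) -> np.ndarray:
    """Linear predictor (Rad-score): intercept + sum(beta_i * x_i)."""
    missing = [c for c in fit.coefficients.index if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing[:5]}")
    Xa = X[fit.coefficients.index].values
    return fit.intercept + Xa @ fit.coefficients.values


def fit_rf(X: pd.DataFrame, y, n_trees: int = 500,
           seed: int = 0) -> RandomForestClassifier:
    """Seeded random forest with out-of-bag probability tracking."""
    yb = _binarize(y)
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1)
    rf.fit(X.values, yb)
    return rf


def rf_score(fit: RandomForestClassifier, X: pd.DataFrame,
             training: bool = False) -> np.ndarray:
    """Probability of the positive class; OOB probabilities on training rows."""
    if training:
        proba = fit.oob_decision_function_[:, 1].copy()
        bad = ~np.isfinite(proba)
        if bad.any():  # rows never out-of-bag (vanishingly rare)
            proba[bad] = fit.predict_proba(X.values[bad])[:, 1]
        return proba
    return fit.predict_proba(X.values)[:, 1]


def fit_block_svm(score_lasso: np.ndarray, score_rf: np.ndarray, y,
                  seed: int = 0):
    """Linear SVM fusing a block's two weak scores into one decision score."""
    yb = _binarize(y)
    S = np.column_stack([score_lasso, score_rf])
    if np.ptp(S, axis=0).max() == 0:
        raise ValueError("degenerate constant scores")
    # balanced class weights prevent the degenerate w ~= 0 "always majority"
    # hinge solution that imbalanced overlapping scores otherwise admit
    svm = make_pipeline(StandardScaler(),
                        SVC(kernel="linear", class_weight="balanced",
                            random_state=seed))
    svm.fit(S, yb)
    return svm


# ---------------------------------------------------------------------------
# the stacked estimator

@dataclass
class _Block:
    """Fitted state of one feature block (texture or traditional)."""

    std_params: dict
    lasso: LassoFit
    rf: RandomForestClassifier
    svm: object
    score1_train: np.ndarray = field(repr=False, default=None)
    score2_train: np.ndarray = field(repr=False, default=None)
    score3_train: np.ndarray = field(repr=False, default=None)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        p = self.std_params
        return (X[p["columns"]] - p["means"]) / p["sds"]

    def scores(self, X: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
        Xs = self.transform(X)
        s1 = lasso_score(Xs, self.lasso)
        s2 = rf_score(self.rf, Xs)
        s3 = self.svm.decision_function(np.column_stack([s1, s2]))
        return s1, s2, s3


class StackedGradeClassifier(BaseEstimator, ClassifierMixin):
    """Two-block LASSO+RF->SVM stack with an SVM combiner.

    Parameters
    ----------
    texture_cols, traditional_cols : sequence of str, optional
        Column names of the two blocks in the input frame.  If omitted, the
        canonical traditional column names are taken as the traditional block
        and every other column as texture.
    n_folds : CV folds for the LASSO penalty search and cross-fitting.
    n_trees : forest size.
    lambda_rule : ``'min'`` or ``'1se'`` penalty selection.
    naive_stacking : feed in-sample first-level scores to the stacking SVMs
        instead of cross-fitted/out-of-bag ones.
    random_state : master seed for every stochastic component.
    """

    def __init__(self, texture_cols: Optional[Sequence[str]] = None,
                 traditional_cols: Optional[Sequence[str]] = None,
                 n_folds: int = 10, n_trees: int = 500,
                 lambda_rule: str = "min", naive_stacking: bool = False,
                 random_state: Optional[int] = None):
        self.texture_cols = texture_cols
        self.traditional_cols = traditional_cols
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.lambda_rule = lambda_rule
        self.naive_stacking = naive_stacking
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    def _resolve_columns(self, X: pd.DataFrame):
        if self.traditional_cols is not None:
            trad = list(self.traditional_cols)
        else:
            trad = [c for c in TRADITIONAL_COLUMNS if c in X.columns]
        if self.texture_cols is not None:
            tex = list(self.texture_cols)
        else:
            tex = [c for c in X.columns if c not in trad]
        if not tex or not trad:
            raise ValueError("both a texture and a traditional block are "
                             "required")
        return tex, trad

    def _fit_block(self, X: pd.DataFrame, yb: np.ndarray, seed: int) -> _Block:
        Xs, _, std_params = standardize_features(X)
        lasso = fit_lasso_cv(Xs, yb, n_folds=self.n_folds,
                             lambda_rule=self.lambda_rule, seed=seed)
        rf = fit_rf(Xs, yb, n_trees=self.n_trees, seed=seed + 1)
        if self.naive_stacking:
            s1 = lasso_score(Xs, lasso)
            s2 = rf_score(rf, Xs)
        else:
            folds = max(2, min(self.n_folds, int(np.bincount(yb).min())))
            cv = StratifiedKFold(n_splits=folds, shuffle=True,
                                 random_state=seed + 2)
            refit = LogisticRegression(penalty="l1", solver="liblinear",
                                       C=lasso.C, max_iter=2000,
                                       random_state=seed)
            with _quiet_sklearn():
                s1 = cross_val_predict(refit, Xs.values, yb, cv=cv,
                                       method="decision_function")
            s2 = rf_score(rf, Xs, training=True)
        svm = fit_block_svm(s1, s2, yb, seed=seed + 3)
        s3 = svm.decision_function(np.column_stack([s1, s2]))
        return _Block(std_params=std_params, lasso=lasso, rf=rf, svm=svm,
                      score1_train=s1, score2_train=s2, score3_train=s3)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        yb = _binarize(y)
        y_arr = np.asarray(y)
        if y_arr.dtype.kind in "UOS":
            self.classes_ = np.array(sorted(np.unique(y_arr),
                                            key=lambda v: v != "high"))[::-1]
            # -> ['low', 'high'] ordering with positive class last
            self._positive_label, self._negative_label = "high", "low"
        else:
            self.classes_ = np.array([0, 1])
            self._positive_label, self._negative_label = 1, 0
        seed = 0 if self.random_state is None else int(self.random_state)
        tex_cols, trad_cols = self._resolve_columns(X)
        self.texture_cols_ = tex_cols
        self.traditional_cols_ = trad_cols

        self.texture_block_ = self._fit_block(X[tex_cols], yb, seed)
        self.traditional_block_ = self._fit_block(X[trad_cols], yb, seed + 100)

        s3 = self.texture_block_.score3_train
        s6 = self.traditional_block_.score3_train
        self.svm3_ = fit_block_svm(s3, s6, yb, seed=seed + 200)
        s7 = self.svm3_.decision_function(np.column_stack([s3, s6]))
        self.threshold_ = youden_threshold(s7, yb)
        self.train_scores_ = pd.DataFrame({
            "score1": self.texture_block_.score1_train,
            "score2": self.texture_block_.score2_train,
            "score3": s3,
            "score4": self.traditional_block_.score1_train,
            "score5": self.traditional_block_.score2_train,
            "score6": s6,
            "score7": s7,
        }, index=X.index)
        self.selected_texture_features_ = self.texture_block_.lasso.selected
        self.selected_traditional_features_ = \
            self.traditional_block_.lasso.selected
        self.n_features_in_ = X.shape[1]
        if auc(s7, yb) < 0.5:
            warnings.warn("training AUC of the final score is below 0.5; "
                          "check score orientation")
        return self

    def _check_fitted(self):
        if not hasattr(self, "svm3_"):
            raise RuntimeError("model is not fitted")

    def predict_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        """All seven stacking scores for new patients."""
        self._check_fitted()
        X = pd.DataFrame(X)
        s1, s2, s3 = self.texture_block_.scores(X)
        s4, s5, s6 = self.traditional_block_.scores(X)
        s7 = self.svm3_.decision_function(np.column_stack([s3, s6]))
        return pd.DataFrame({"score1": s1, "score2": s2, "score3": s3,
                             "score4": s4, "score5": s5, "score6": s6,
                             "score7": s7}, index=X.index)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_scores(X)["score7"].values

    def predict(self, X: pd.DataFrame):
        """Binary grade call: high when score 7 >= the training threshold."""
        s7 = self.decision_function(X)
        return np.where(s7 >= self.threshold_, self._positive_label,
                        self._negative_label)

    def save(self, path: str) -> None:
        """Serialize the fitted model to a single archive file."""
        self._check_fitted()
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "StackedGradeClassifier":
        return joblib.load(path)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_stacked_classifier(X_texture: pd.DataFrame,
                           X_traditional: pd.DataFrame, y,
                           config: Optional[Dict] = None,
                           seed: int = 0) -> StackedGradeClassifier:
    """Fit the full stacking recipe from the two aligned feature blocks."""
    if not X_texture.index.equals(X_traditional.index):
        raise ValueError("texture and traditional blocks are not aligned")
    X = pd.concat([X_texture, X_traditional], axis=1)
    cfg = dict(config or {})
    model = StackedGradeClassifier(
        texture_cols=list(X_texture.columns),
        traditional_cols=list(X_traditional.columns),
        random_state=seed, **cfg)
    return model.fit(X, y)


def predict(model: StackedGradeClassifier, X_texture: pd.DataFrame,
            X_traditional: pd.DataFrame) -> pd.DataFrame:
    """Score 7 and the binary grade call per patient."""
    X = pd.concat([X_texture, X_traditional], axis=1)
    scores = model.predict_scores(X)
    out = pd.DataFrame({"score7": scores["score7"]}, index=X.index)
    out["call"] = model.predict(X)
    return out
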
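"""Two-class linear discriminant with repeated stratified cross-validation.

The discriminant is Fisher's rule from class means and the pooled
within-class covariance, with a small ridge term for stability on the tiny,
possibly collinear feature panels this package evaluates (2-3 markers on a
few dozen patients).  Class priors are equal by default so that reported
sensitivity and specificity are not skewed by cohort prevalence.

Cross-validation is stratified k-fold, reshuffled on each repetition from a
single seed; confusion counts are pooled over all folds and repetitions
(stable with folds of only a few samples), and each sample's out-of-fold
decision score is kept so ROC analysis can be run on the same
generalization surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Fisher linear discriminant for two classes.

    Parameters
    ----------
    ridge : float or "auto"
        Ridge term added to the pooled covariance diagonal.  ``"auto"`` uses
        1e-6 times the mean of the covariance diagonal (falling back to 1e-6
        for an all-zero diagonal), enough to make duplicated features
        harmless without visibly moving well-conditioned solutions.
    priors : "equal" or array-like of two probabilities
        Priors entering the decision threshold.  ``"equal"`` places the
        boundary midway between the projected class means.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive class.
    means_ : ndarray of shape (2, n_features)
    covariance_ : ndarray
        Pooled within-class covariance, before the ridge term.
    coef_ : ndarray of shape (n_features,)
        ``solve(covariance_ + ridge * I, means_[1] - means_[0])``.
    intercept_ : float
    """

    def __init__(self, ridge="auto", priors="equal"):
        self.ridge = ridge
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(classes)}")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        mu0 = X[y_idx == 0].mean(axis=0)
        mu1 = X[y_idx == 1].mean(axis=0)
        self.means_ = np.vstack([mu0, mu1])
        n = len(y)
        sw = np.zeros((X.shape[1], X.shape[1]))
        for k in (0, 1):
            xc = X[y_idx == k] - self.means_[k]
            sw += xc.T @ xc
        self.covariance_ = sw / (n - 2)
        if self.ridge == "auto":
            diag_mean = float(np.mean(np.diag(self.covariance_)))
            lam = 1e-6 * diag_mean if diag_mean > 0 else 1e-6
        else:
            lam = float(self.ridge)
        self.ridge_ = lam
        shrunk = self.covariance_ + lam * np.eye(X.shape[1])
        self.coef_ = np.linalg.solve(shrunk, mu1 - mu0)
        self.intercept_ = -float(self.coef_ @ (mu0 + mu1)) / 2.0
        if isinstance(self.priors, str):
            if self.priors != "equal":
                raise ValueError(f"unknown priors {self.priors!r}")
        else:
            p = np.asarray(self.priors, dtype=float)
            if p.shape != (2,) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("priors must be two probabilities summing to 1")
            self.intercept_ += math.log(p[1] / p[0])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


@dataclass
class CVReport:
    """Pooled confusion counts from repeated stratified cross-validation."""

    k: int
    reps: int
    seed: int
    tp: int
    fp: int
    tn: int
    fn: int
    oof_scores: np.ndarray = field(repr=False)  # shape (reps, n_samples)
    lr_flagged: bool = False

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def lr_plus(self) -> float:
        return likelihood_ratio(self.sensitivity, self.specificity)

    @property
    def mean_scores(self) -> np.ndarray:
        """Per-sample out-of-fold decision score averaged over repetitions."""
        return self.oof_scores.mean(axis=0)


def likelihood_ratio(sensitivity: float, specificity: float) -> float:
    """Positive likelihood ratio LR+ = sensitivity / (1 - specificity).

    A perfect specificity makes the ratio infinite; that is reported as
    ``inf`` with a warning rather than an error, since it is a legitimate
    (if degenerate) outcome of pooled cross-validation counts.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError(f"sensitivity {sensitivity} outside [0, 1]")
    if not 0.0 <= specificity <= 1.0:
        raise ValueError(f"specificity {specificity} outside [0, 1]")
    if specificity == 1.0:
        warnings.warn("specificity = 1: LR+ is infinite", UserWarning, stacklevel=2)
        return math.inf
    return sensitivity / (1.0 - specificity)


def cross_validate(
    X,
    y,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    estimator: LinearDiscriminant | None = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of the discriminant.

    Folds are stratified and reshuffled each repetition from ``seed``; every
    sample is scored exactly once per repetition by a model trained without
    it.  Confusion counts are pooled over all repetitions.  If the smaller
    class has fewer than ``k`` members the fold count is reduced to that
    class size (with a warning), keeping at least one positive per fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    pos = classes[1]
    min_class = int(np.bincount(np.searchsorted(classes, y)).min())
    k_eff = k
    if min_class < k:
        k_eff = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; folds reduced {k} -> {k_eff}",
            UserWarning,
            stacklevel=2,
        )
    proto = estimator if estimator is not None else LinearDiscriminant()
    n = len(y)
    scores = np.full((reps, n), np.nan)
    tp = fp = tn = fn = 0
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps)
    for r in range(reps):
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(rep_seeds[r] % (2**31)))
        for train, test in skf.split(X, y):
            model = proto.__class__(**proto.get_params()).fit(X[train], y[train])
            s = model.decision_function(X[test])
            scores[r, test] = s
            pred = model.predict(X[test])
            truth = y[test]
            tp += int(np.sum((pred == pos) & (truth == pos)))
            fp += int(np.sum((pred == pos) & (truth != pos)))
            tn += int(np.sum((pred != pos) & (truth != pos)))
            fn += int(np.sum((pred != pos) & (truth == pos)))
    if np.isnan(scores).any():
        raise AssertionError("fold assignment did not cover every sample")
    return CVReport(
        k=k_eff,
        reps=reps,
        seed=seed,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        oof_scores=scores,
        lr_flagged=(tn + fp > 0 and fp == 0),
    )
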
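"""Conversion-risk and classification models.

Cox proportional hazards (Efron ties, via lifelines) on z-scored
covariates, a two-class linear discriminant with pooled within-class
covariance, leave-one-out cross-validation, and the classification metrics
reported alongside it: sensitivity, specificity, accuracy, the balanced
classification rate BCR = (sensitivity + specificity) / 2, and the AUC
computed by the trapezoidal rule over the ROC of held-out scores (with
midrank tie handling it equals the normalised Mann-Whitney U statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "CoxFit",
    "LdaModel",
    "ClassificationReport",
    "zscore_covariates",
    "fit_cox",
    "lda_fit",
    "loo_cv_classify",
    "classification_metrics",
    "roc_curve_points",
]


@dataclass
class CoxFit:
    """Per-covariate hazard-ratio table from a proportional-hazards fit."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, hr_ci_low, hr_ci_high, p
    n_events: int
    n: int
    ties_method: str = "efron"
    model: object = field(repr=False, default=None)

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


@dataclass
class LdaModel:
    """Two-class linear discriminant with pooled covariance.

    ``score(x) = w.(x - 0.5 (mu1 + mu0)) + log(pi1 / pi0)`` is the log
    posterior odds of class 1; predictions threshold it at 0 (posterior 0.5).
    """

    weights: np.ndarray
    offset: float
    class_means: np.ndarray  # (2, d)
    priors: np.ndarray  # (2,)
    ridge_used: bool = False

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.weights + self.offset

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    bcr: float
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)
    n_skipped_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "bcr": self.bcr,
            "auc": self.auc,
            "n_skipped_folds": self.n_skipped_folds,
        }


def zscore_covariates(
    cohort: pd.DataFrame, names: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the named columns over the full sample (sample SD, ddof=1).

    Returns the transformed copy and the (mean, sd) pairs used, so the same
    transform can be replayed on new data.
    """
    out = cohort.copy()
    params: dict[str, tuple[float, float]] = {}
    for name in names:
        col = out[name].astype(float)
        sd = float(col.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in column {name!r}; cannot z-score")
        mean = float(col.mean())
        out[name] = (col - mean) / sd
        params[name] = (mean, sd)
    return out, params


def fit_cox(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "event_time",
    event_col: str = "event_observed",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron ties handling."""
    df = cohort[[duration_col, event_col] + list(covariates)].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < 1:
        raise ValueError("no observed events; cannot fit a hazards model")
    if (df[duration_col] <= 0).any():
        raise ValueError("event/censoring times must be positive")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_ci_low": s["exp(coef) lower 95%"],
            "hr_ci_high": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxFit(summary=summary, n_events=n_events, n=len(df), ties_method="efron", model=cph)


def lda_fit(
    features: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> LdaModel:
    """Two-class LDA with pooled within-class covariance.

    Priors default to the empirical class proportions.  A singular pooled
    covariance is regularised by adding ``ridge * mean-diagonal`` to the
    diagonal; the fall-back is flagged on the returned model.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if set(classes.tolist()) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need >=2 subjects per class")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    X0c = X[y == 0] - mu0
    X1c = X[y == 1] - mu1
    pooled = (X0c.T @ X0c + X1c.T @ X1c) / (n0 + n1 - 2)
    ridge_used = False
    try:
        cov_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        ridge_used = True
        bump = ridge * max(np.trace(pooled) / pooled.shape[0], 1.0)
        cov_inv = np.linalg.inv(pooled + bump * np.eye(pooled.shape[0]))
    if priors is None:
        priors = np.array([n0, n1], dtype=float) / (n0 + n1)
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    w = cov_inv @ (mu1 - mu0)
    offset = float(-0.5 * (mu1 + mu0) @ w + np.log(priors[1] / priors[0]))
    return LdaModel(
        weights=w,
        offset=offset,
        class_means=np.stack([mu0, mu1]),
        priors=priors,
        ridge_used=ridge_used,
    )


def loo_cv_classify(
    features: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated LDA classification.

    Each subject is scored by a model fitted on the other n-1; the report is
    built exclusively from held-out scores and predictions.  Folds whose
    training set lacks a class are skipped and counted.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out cross-validation")
    scores, preds, kept = [], [], []
    n_skipped = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        ytr = y[keep]
        if len(np.unique(ytr)) < 2 or (ytr == 0).sum() < 2 or (ytr == 1).sum() < 2:
            n_skipped += 1
            continue
        model = lda_fit(X[keep], ytr, priors=priors)
        s = float(model.decision_scores(X[i : i + 1])[0])
        scores.append(s)
        preds.append(int(s > 0))
        kept.append(i)
    if not kept:
        raise ValueError("all leave-one-out folds were degenerate")
    report = classification_metrics(
        np.array(y[kept]), np.array(scores), np.array(preds)
    )
    report.n_skipped_folds = n_skipped
    return report


def roc_curve_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC (fpr, tpr) points over the distinct score thresholds, ties grouped."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tpr = np.r_[0.0, tps / max(n_pos, 1)]
    fpr = np.r_[0.0, fps / max(n_neg, 1)]
    return fpr, tpr


def classification_metrics(
    labels: np.ndarray, scores: np.ndarray, predictions: np.ndarray
) -> ClassificationReport:
    """Confusion-matrix metrics plus trapezoidal ROC AUC of the scores."""
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute sensitivity/specificity")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    fpr, tpr = roc_curve_points(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return ClassificationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float((tp + tn) / len(y)),
        bcr=float(0.5 * (sens + spec)),
        auc=auc,
        scores=np.asarray(scores, dtype=float),
        labels=y,
        predictions=pred,
    )
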
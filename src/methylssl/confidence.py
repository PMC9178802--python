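"""Score calibration and classifiable/non-classifiable threshold analysis.

Raw per-class SSL scores are not comparable across classes.  They are
mapped to class probabilities with an L2-penalized multinomial logistic
regression (ridge penalty chosen by 10-fold cross-validated deviance),
after which a single confidence threshold can be shared by all classes:
the multiclass problem is binarized as "classifiable" (argmax equals the
true class) vs "non-classifiable", scored by the row-maximal calibrated
probability, and the operating threshold is picked by maximizing the
Youden index (sensitivity + specificity - 1).  Samples at or above the
threshold are tiered high-confidence (HC), the rest low-confidence (LC).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "RawScoreMatrix",
    "CalibratedScoreMatrix",
    "CalibrationModel",
    "ThresholdReport",
    "ConfidenceConfig",
    "fit_calibration",
    "calibrate",
    "binarize_classifiable",
    "roc_auc",
    "threshold_analysis",
    "assign_confidence_tiers",
]


@dataclass
class RawScoreMatrix:
    """n x K raw class scores from an SSL fit (finite, K >= 2)."""

    sample_ids: np.ndarray
    class_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.class_ids = np.asarray(self.class_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.class_ids.size < 2:
            raise ValueError("need at least 2 classes")
        if self.scores.shape != (self.sample_ids.size, self.class_ids.size):
            raise ValueError("scores shape does not match ids")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


@dataclass
class CalibratedScoreMatrix:
    """n x K class probabilities; every row sums to 1."""

    sample_ids: np.ndarray
    class_ids: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size and not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("calibrated rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.sample_ids, columns=self.class_ids)


@dataclass
class CalibrationModel:
    """Fitted L2 multinomial logistic calibration map.

    Applies the stored feature standardization, then softmax(W x + b).
    Classes absent from the fit keep a -inf intercept (probability 0).
    """

    class_ids: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    weights: np.ndarray  # K x K (classes x raw-score features)
    intercepts: np.ndarray
    lam: float
    cv_deviance: Optional[pd.DataFrame] = None

    def transform(self, scores: np.ndarray) -> np.ndarray:
        x = (scores - self.feature_mean) / self.feature_scale
        logits = x @ self.weights.T + self.intercepts
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_ids": [str(c) for c in self.class_ids],
                "feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "weights": self.weights.tolist(),
                "intercepts": [
                    None if np.isneginf(b) else b for b in self.intercepts
                ],
                "lambda": self.lam,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            class_ids=np.asarray(d["class_ids"], dtype=object),
            feature_mean=np.asarray(d["feature_mean"]),
            feature_scale=np.asarray(d["feature_scale"]),
            weights=np.asarray(d["weights"]),
            intercepts=np.asarray(
                [-np.inf if b is None else b for b in d["intercepts"]]
            ),
            lam=float(d["lambda"]),
        )


@dataclass(frozen=True)
class ConfidenceConfig:
    """HC/LC cutoff on the maximal calibrated probability (boundary is HC)."""

    tau: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")


@dataclass
class ThresholdReport:
    """Sensitivity/specificity/precision grid with AUC and Youden optimum."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    auc: float
    youden_optimal: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
            }
        )


def _default_lambda_grid(x_std: np.ndarray, y: np.ndarray, classes, n_lambda: int):
    """Log-spaced grid below the gradient-based lambda_max."""
    n = x_std.shape[0]
    lam_max = 0.0
    for c in classes:
        r = (y == c).astype(float)
        r -= r.mean()
        lam_max = max(lam_max, np.abs(x_std.T @ r).max() / n)
    lam_max = max(lam_max, 1e-3)
    return np.logspace(np.log10(1e-4 * lam_max), np.log10(lam_max), n_lambda)


def _fit_multinomial(x_std, y, lam):
    n = x_std.shape[0]
    # ridge (L2) penalty is sklearn's default; objective is
    # (1/n)*NLL + lam/2 * ||W||^2  via  C = 1/(lam*n)
    est = LogisticRegression(C=1.0 / (lam * n), solver="lbfgs", max_iter=2000)
    return est.fit(x_std, y)


def fit_calibration(
    raw: RawScoreMatrix,
    truth: Sequence,
    n_folds: int = 10,
    lambda_grid: Optional[Sequence[float]] = None,
    n_lambda: int = 100,
    seed: int = 0,
) -> CalibrationModel:
    """Fit the ridge multinomial calibration model.

    Minimizes the multinomial negative log-likelihood plus an L2 penalty on
    standardized raw-score features; the penalty lambda is the grid value
    minimizing mean cross-validated deviance over class-stratified folds
    (stratified so rare classes appear in every fold; fold assignment is
    seeded).  Classes present in ``raw.class_ids`` but absent from
    ``truth`` receive probability 0 (logged).
    """
    truth = np.asarray(truth)
    classes = raw.class_ids
    extra = np.setdiff1d(np.unique(truth), classes.astype(str).astype(object))
    if np.setdiff1d(np.unique(truth), classes).size:
        raise ValueError(f"truth contains unknown classes: {extra}")
    n = raw.scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to calibrate")

    mean = raw.scores.mean(axis=0)
    scale = raw.scores.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    x_std = (raw.scores - mean) / scale

    present = np.asarray([c for c in classes if (truth == c).any()], dtype=object)
    absent = np.asarray([c for c in classes if not (truth == c).any()], dtype=object)
    if absent.size:
        logger.warning(
            "fit_calibration: %d classes absent from truth get probability 0: %s",
            absent.size,
            list(absent[:5]),
        )
    y = truth.astype(str)
    present_str = present.astype(str)

    if lambda_grid is None:
        lambda_grid = _default_lambda_grid(x_std, y, present_str, n_lambda)
    lambda_grid = np.asarray(sorted(lambda_grid))

    min_count = min(int((y == c).sum()) for c in present_str)
    k = max(2, min(n_folds, min_count))
    if k < n_folds:
        logger.warning("fit_calibration: reduced folds from %d to %d", n_folds, k)
    cv_rows: List[dict] = []
    mean_dev = np.zeros(lambda_grid.size)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, va) in enumerate(skf.split(x_std, y)):
        for li, lam in enumerate(lambda_grid):
            est = _fit_multinomial(x_std[tr], y[tr], lam)
            # expand onto every class present overall: a class missing from
            # this training fold scores probability ~0 on its members
            p = np.full((va.size, present_str.size), 1e-15)
            col = {c: i for i, c in enumerate(present_str)}
            p_est = est.predict_proba(x_std[va])
            for j, c in enumerate(est.classes_):
                p[:, col[c]] = np.maximum(p_est[:, j], 1e-15)
            dev = log_loss(y[va], p / p.sum(axis=1, keepdims=True),
                           labels=present_str)
            mean_dev[li] += dev / k
            cv_rows.append({"fold": fold, "lambda": lam, "deviance": dev})
    best = int(np.argmin(mean_dev))
    lam = float(lambda_grid[best])

    est = _fit_multinomial(x_std, y, lam)
    K = classes.size
    W = np.zeros((K, K))
    b = np.full(K, -np.inf)
    cls_index = {str(c): i for i, c in enumerate(classes)}
    coef = est.coef_
    icpt = est.intercept_
    if len(est.classes_) == 2 and coef.shape[0] == 1:
        coef = np.vstack([-coef[0] / 2.0, coef[0] / 2.0])
        icpt = np.asarray([-icpt[0] / 2.0, icpt[0] / 2.0])
    for row, c in enumerate(est.classes_):
        i = cls_index[str(c)]
        W[i] = coef[row]
        b[i] = icpt[row]
    return CalibrationModel(
        class_ids=classes,
        feature_mean=mean,
        feature_scale=scale,
        weights=W,
        intercepts=b,
        lam=lam,
        cv_deviance=pd.DataFrame(cv_rows),
    )


def calibrate(model: CalibrationModel, raw: RawScoreMatrix) -> CalibratedScoreMatrix:
    """Apply the stored standardization and softmax map to raw scores."""
    if raw.class_ids.size != model.class_ids.size or (
        raw.class_ids != model.class_ids
    ).any():
        raise ValueError("raw score columns do not match the calibration model")
    return CalibratedScoreMatrix(
        sample_ids=raw.sample_ids,
        class_ids=raw.class_ids,
        probs=model.transform(raw.scores),
    )


def binarize_classifiable(cal: CalibratedScoreMatrix, truth: Sequence):
    """Convert K-class calibrated scores to one binary ROC problem.

    Positive ("classifiable") iff the argmax class equals the truth; the
    score is the row-maximal calibrated probability.
    """
    truth = np.asarray(truth)
    if truth.size != cal.probs.shape[0]:
        raise ValueError("truth not aligned with calibrated scores")
    pred = cal.class_ids[np.argmax(cal.probs, axis=1)]
    positive = pred.astype(str) == truth.astype(str)
    score = cal.probs.max(axis=1)
    return positive, score


def roc_auc(binary: Sequence[bool], score: Sequence[float]) -> ThresholdReport:
    """ROC over all distinct score thresholds (predict positive iff >= tau).

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, ties counted 1/2.  The Youden-optimal threshold
    maximizes sensitivity + specificity - 1 (smallest threshold on ties).
    Precision at thresholds with no predicted positives is NaN.
    """
    binary = np.asarray(binary, dtype=bool)
    score = np.asarray(score, dtype=float)
    n_pos = int(binary.sum())
    n_neg = int((~binary).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "roc_auc needs both classes; use threshold_analysis for the "
            "degenerate single-class case"
        )
    ranks = rankdata(score)
    auc = (ranks[binary].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(score)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    prec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = score >= t
        tp = int((pred & binary).sum())
        fp = int((pred & ~binary).sum())
        tn = int((~pred & ~binary).sum())
        fn = int((~pred & binary).sum())
        sens[i] = tp / (tp + fn)
        spec[i] = tn / (tn + fp)
        prec[i] = tp / (tp + fp) if (tp + fp) else np.nan
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax returns the first (smallest) tie
    return ThresholdReport(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        auc=float(auc),
        youden_optimal=float(thresholds[best]),
    )


def threshold_analysis(cal: CalibratedScoreMatrix, truth: Sequence) -> ThresholdReport:
    """Binarize classifiable/non-classifiable, then run the ROC analysis.

    Degenerate case (every sample correct, or every sample wrong): the ROC
    is undefined; an all-positive input reports AUC 1 with a warning, an
    all-negative input AUC 0.
    """
    binary, score = binarize_classifiable(cal, truth)
    if binary.all() or (~binary).all():
        auc = 1.0 if binary.all() else 0.0
        logger.warning(
            "threshold_analysis: single-class input, reporting degenerate AUC %.0f",
            auc,
        )
        t = np.unique(score)
        ones = np.ones_like(t)
        return ThresholdReport(
            thresholds=t,
            sensitivity=ones if binary.all() else np.full_like(t, np.nan),
            specificity=np.full_like(t, np.nan) if binary.all() else ones,
            precision=ones if binary.all() else np.zeros_like(t),
            auc=auc,
            youden_optimal=float(t[0]),
            degenerate=True,
        )
    return roc_auc(binary, score)


def assign_confidence_tiers(
    cal: CalibratedScoreMatrix, cfg: ConfidenceConfig = ConfidenceConfig()
) -> pd.DataFrame:
    """HC iff the row-maximal calibrated probability >= tau (else LC).

    Returns a frame with the argmax pseudo-label, the maximal probability
    and the tier per sample.
    """
    score = cal.probs.max(axis=1)
    label = cal.class_ids[np.argmax(cal.probs, axis=1)]
    tier = np.where(score >= cfg.tau, "HC", "LC")
    return pd.DataFrame(
        {
            "sample_id": cal.sample_ids,
            "label": label,
            "max_calibrated_score": score,
            "tier": tier,
        }
    )
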
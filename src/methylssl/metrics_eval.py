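"""Bootstrapped partition design, one-vs-all metrics and the model benchmark.

The partition design mirrors the reference study: per bootstrap, 30% of
samples are held out as an inductive test set; the remaining 70% of the
data is split in half into a labeled pool and an unlabeled pool (the
latter doubles as the transductive test set).  All draws are stratified by
class so the pools preserve the severely imbalanced class distribution,
with a guaranteed minimum of one labeled sample per class.  The benchmark
runs each SSL model over every bootstrap at both label levels (subclass MC
and family MCF) and reports one-vs-all multiclass metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix
from .ssl_core import SSLModelSpec, fit_ssl, predict

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionPlan",
    "MultiClassMetrics",
    "BenchmarkReport",
    "make_bootstrap_partitions",
    "multiclass_metrics",
    "run_benchmark",
]


@dataclass
class PartitionPlan:
    """One bootstrap of the 30% inductive / 35% labeled / 35% unlabeled split."""

    bootstrap_id: int
    inductive_test_idx: np.ndarray
    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray
    seed: int

    def validate(self, n_samples: int) -> None:
        parts = [self.inductive_test_idx, self.labeled_idx, self.unlabeled_idx]
        joined = np.concatenate(parts)
        if joined.size != n_samples or np.unique(joined).size != n_samples:
            raise ValueError("partition sets must be disjoint and cover all samples")

    def to_dict(self) -> dict:
        return {
            "bootstrap_id": self.bootstrap_id,
            "inductive_test_idx": self.inductive_test_idx.tolist(),
            "labeled_idx": self.labeled_idx.tolist(),
            "unlabeled_idx": self.unlabeled_idx.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionPlan":
        return cls(
            bootstrap_id=int(d["bootstrap_id"]),
            inductive_test_idx=np.asarray(d["inductive_test_idx"], dtype=int),
            labeled_idx=np.asarray(d["labeled_idx"], dtype=int),
            unlabeled_idx=np.asarray(d["unlabeled_idx"], dtype=int),
            seed=int(d["seed"]),
        )


@dataclass
class MultiClassMetrics:
    """One-vs-all multiclass summary; balanced accuracy = macro recall."""

    accuracy: float
    balanced_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_specificity: float
    per_class_recall: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
        }


@dataclass
class BenchmarkReport:
    """Long-format metric table plus pooled transductive raw scores per model."""

    table: pd.DataFrame
    raw_scores: Dict[str, dict] = field(default_factory=dict)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total``, nearest to the real shares."""
    counts = np.floor(shares).astype(int)
    rem = shares - counts
    short = total - counts.sum()
    order = np.argsort(-rem, kind="stable")
    for i in order[: max(short, 0)]:
        counts[i] += 1
    return counts


def make_bootstrap_partitions(
    labels: Sequence,
    n_boot: int = 7,
    test_frac: float = 0.30,
    labeled_frac: float = 0.5,
    seed: int = 0,
) -> List[PartitionPlan]:
    """Stratified bootstrap partitions of the reference cohort.

    Per bootstrap and class: ``test_frac`` of the class goes to the
    inductive test set, and ``labeled_frac`` of the remainder to the
    labeled pool (rest unlabeled/transductive), with largest-remainder
    rounding toward the global targets and at least one labeled sample per
    class.  Classes too small to reach every pool trigger a warning.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        logger.warning(
            "make_bootstrap_partitions: %d classes have < 2 samples; they are "
            "pinned to the labeled pool",
            int((counts < 2).sum()),
        )
    rng = np.random.default_rng(seed)
    n = labels.size
    n_test_by_class = _largest_remainder(
        counts * test_frac, int(round(test_frac * n))
    )
    plans: List[PartitionPlan] = []
    for b in range(n_boot):
        boot_seed = int(rng.integers(0, 2**31 - 1))
        boot_rng = np.random.default_rng(boot_seed)
        test, lab, unlab = [], [], []
        train_counts = counts - n_test_by_class
        n_lab_by_class = _largest_remainder(
            train_counts * labeled_frac,
            int(round(labeled_frac * train_counts.sum())),
        )
        for ci, c in enumerate(classes):
            idx = boot_rng.permutation(np.flatnonzero(labels == c))
            n_test = int(n_test_by_class[ci])
            n_lab = max(1, int(n_lab_by_class[ci]))
            if counts[ci] - n_test < 1:  # tiny class: keep at least 1 in train
                n_test = counts[ci] - 1
            n_lab = min(n_lab, counts[ci] - n_test)
            test.extend(idx[:n_test])
            lab.extend(idx[n_test : n_test + n_lab])
            unlab.extend(idx[n_test + n_lab :])
        plan = PartitionPlan(
            bootstrap_id=b,
            inductive_test_idx=np.sort(np.asarray(test, dtype=int)),
            labeled_idx=np.sort(np.asarray(lab, dtype=int)),
            unlabeled_idx=np.sort(np.asarray(unlab, dtype=int)),
            seed=boot_seed,
        )
        plan.validate(n)
        plans.append(plan)
    return plans


def multiclass_metrics(
    truth: Sequence, predicted: Sequence, classes: Optional[Sequence] = None
) -> MultiClassMetrics:
    """One-vs-all recall/precision/specificity macro-averages.

    Macro averages run over classes present in ``truth``; a class with
    zero predicted positives is excluded from macro precision (logged).
    Balanced accuracy is the unweighted mean of per-class recall.
    """
    truth = np.asarray(truth).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if truth.size != predicted.size:
        raise ValueError("truth and predicted must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([truth, predicted]))
    classes = np.asarray(classes).astype(str)
    present = [c for c in classes if (truth == c).any()]

    recalls, precisions, specificities = {}, [], []
    for c in present:
        tp = int(((truth == c) & (predicted == c)).sum())
        fn = int(((truth == c) & (predicted != c)).sum())
        fp = int(((truth != c) & (predicted == c)).sum())
        tn = int(((truth != c) & (predicted != c)).sum())
        recalls[c] = tp / (tp + fn)
        specificities.append(tn / (tn + fp) if (tn + fp) else np.nan)
        if tp + fp:
            precisions.append(tp / (tp + fp))
        else:
            logger.debug("multiclass_metrics: class %s never predicted", c)
    rec = float(np.mean(list(recalls.values())))
    return MultiClassMetrics(
        accuracy=float((truth == predicted).mean()),
        balanced_accuracy=rec,
        macro_precision=float(np.mean(precisions)) if precisions else np.nan,
        macro_recall=rec,
        macro_specificity=float(np.nanmean(specificities)),
        per_class_recall=recalls,
    )


def run_benchmark(
    features: BetaMatrix,
    mc: Sequence,
    mcf: Sequence,
    plans: Sequence[PartitionPlan],
    models: Dict[str, SSLModelSpec],
    collect_raw_level: str = "mc",
) -> BenchmarkReport:
    """Fit every model on every bootstrap at both label levels.

    MCF-level rows come from a separate fit on family labels (refit rather
    than collapsing MC predictions).  Transductive metrics score the
    unlabeled pool via the fit's pseudo-labels; inductive metrics score the
    held-out test set.  Model failures are recorded per cell and the run
    continues.  Pooled transductive raw scores (with truths) are collected
    at ``collect_raw_level`` for downstream calibration.
    """
    X = features.values
    levels = {"mc": np.asarray(mc), "mcf": np.asarray(mcf)}
    rows: List[dict] = []
    pooled: Dict[str, dict] = {
        name: {"scores": [], "truth": [], "sample_ids": [], "classes": None}
        for name in models
    }
    for plan in plans:
        plan.validate(X.shape[0])
        for name, spec in models.items():
            for level, y in levels.items():
                try:
                    fit = fit_ssl(
                        spec,
                        X[plan.labeled_idx],
                        y[plan.labeled_idx],
                        X[plan.unlabeled_idx],
                    )
                    trans = multiclass_metrics(
                        y[plan.unlabeled_idx], fit.pseudo_labels, fit.classes_
                    )
                    ind_lab, _ = predict(fit, X[plan.inductive_test_idx])
                    ind = multiclass_metrics(
                        y[plan.inductive_test_idx], ind_lab, fit.classes_
                    )
                except Exception as exc:  # noqa: BLE001 - cell-level isolation
                    logger.error(
                        "benchmark cell failed (%s, boot %d, %s): %s",
                        name, plan.bootstrap_id, level, exc,
                    )
                    rows.append(
                        {
                            "model": name,
                            "bootstrap": plan.bootstrap_id,
                            "level": level,
                            "setting": "error",
                            "error": str(exc),
                        }
                    )
                    continue
                for setting, m in (("transductive", trans), ("inductive", ind)):
                    rows.append(
                        {
                            "model": name,
                            "bootstrap": plan.bootstrap_id,
                            "level": level,
                            "setting": setting,
                            **m.to_dict(),
                        }
                    )
                if level == collect_raw_level:
                    pooled[name]["scores"].append(fit.raw_scores)
                    pooled[name]["truth"].append(y[plan.unlabeled_idx])
                    pooled[name]["sample_ids"].append(
                        features.sample_ids[plan.unlabeled_idx]
                    )
                    pooled[name]["classes"] = fit.classes_
    raw = {}
    for name, d in pooled.items():
        if not d["scores"]:
            continue
        raw[name] = {
            "scores": np.vstack(d["scores"]),
            "truth": np.concatenate(d["truth"]),
            "sample_ids": np.concatenate(d["sample_ids"]),
            "classes": d["classes"],
        }
    return BenchmarkReport(table=pd.DataFrame(rows), raw_scores=raw)
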
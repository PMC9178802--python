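"""Pseudo-label augmentation of supervised classifiers.

The downstream experiment: train a random forest and a feed-forward neural
net on (a) the seed-labeled reference pool alone (BASELINE) and (b) the
same pool augmented with SSL pseudo-labels filtered by confidence tier —
high-confidence only (PLUS_HC), low-confidence only (PLUS_LC), or both
(PLUS_ALL).  Class imbalance is countered with balanced sample weights
w_c = n / (K * n_c).  Variants are compared by balanced accuracy under
repeated stratified cross-validation and on seven resampled hold-out sets
(drawn exclusively from seed-labeled samples), with Tukey HSD on the
hold-out accuracies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.utils.class_weight import compute_sample_weight
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .confidence import (
    ConfidenceConfig,
    RawScoreMatrix,
    assign_confidence_tiers,
    calibrate,
    fit_calibration,
)
from .metrics_eval import make_bootstrap_partitions, multiclass_metrics
from .preprocess import BetaMatrix, FeatureSelectConfig, select_features_by_sd
from .ssl_core import fit_ssl, model_grid, predict
from .synthetic_data import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "VariantName",
    "SamplePool",
    "TrainingVariant",
    "SupervisedModelSpec",
    "ComparisonReport",
    "build_training_variants",
    "train_supervised",
    "evaluate_variants",
    "balanced_sample_weights",
]

LOW_FREQUENCY_CUTOFF = 10  # classes with < 10 seed-labeled samples are "low frequency"


class VariantName(str, Enum):
    BASELINE = "BASELINE"
    PLUS_HC = "PLUS_HC"
    PLUS_LC = "PLUS_LC"
    PLUS_ALL = "PLUS_ALL"


@dataclass
class SamplePool:
    """A set of samples with (seed or pseudo) labels."""

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if not (self.ids.size == self.X.shape[0] == self.y.size):
            raise ValueError("pool ids, X and y must be aligned")

    @property
    def n(self) -> int:
        return int(self.ids.size)


@dataclass
class TrainingVariant:
    """One training composition: the extra pseudo-labeled samples to add.

    BASELINE carries no extras.  ``counts`` breaks the composition down by
    source and frequency stratum (low frequency = class has fewer than 10
    seed-labeled samples).
    """

    name: VariantName
    extra_ids: np.ndarray
    extra_X: np.ndarray
    extra_y: np.ndarray
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_extra(self) -> int:
        return int(self.extra_ids.size)


@dataclass(frozen=True)
class SupervisedModelSpec:
    """A downstream supervised classifier.

    ``kind='rf'``: a 500-tree random forest.  ``kind='nn'``: a dense
    feed-forward net; full-scale layer sizes are (1000, 500) with
    He-uniform init, ReLU, softmax output, batch size 6 and 20 epochs —
    ``nn_hidden`` may be reduced for small cohorts.
    """

    kind: str = "rf"
    rf_n_trees: int = 500
    nn_hidden: Tuple[int, int] = (1000, 500)
    nn_batch_size: int = 6
    nn_epochs: int = 20
    nn_learning_rate: float = 1e-3
    seed: int = 123456

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "nn"):
            raise ValueError("kind must be 'rf' or 'nn'")


def balanced_sample_weights(y: Sequence) -> np.ndarray:
    """Per-sample weight n / (K * n_c) of each sample's class."""
    return compute_sample_weight("balanced", np.asarray(y))


# ---------------------------------------------------------------------
# neural net (numpy; deterministic given the seed)
# ---------------------------------------------------------------------


class _DenseNet:
    """Two-hidden-layer softmax classifier trained by Adam.

    He-uniform initialization, ReLU activations, weighted categorical
    cross-entropy; mini-batches are reshuffled per epoch from the seeded
    generator, so training is bit-reproducible.
    """

    def __init__(self, n_in, hidden, n_out, seed, lr=1e-3, batch_size=6, epochs=20):
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, n_out]
        self.W, self.b = [], []
        for a, c in zip(sizes[:-1], sizes[1:]):
            limit = math.sqrt(6.0 / a)
            self.W.append(rng.uniform(-limit, limit, size=(a, c)))
            self.b.append(np.zeros(c))
        self.lr, self.batch_size, self.epochs = lr, batch_size, epochs
        self._rng = rng

    def _forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
            acts.append(h)
        logits = acts[-1] - acts[-1].max(axis=1, keepdims=True)
        p = np.exp(logits)
        return acts, p / p.sum(axis=1, keepdims=True)

    def fit(self, X, y_onehot, sample_weight):
        n = X.shape[0]
        m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        v = [np.zeros_like(g) for g in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                acts, probs = self._forward(X[idx])
                w = sample_weight[idx][:, None]
                delta = (probs - y_onehot[idx]) * w / idx.size
                grads_W, grads_b = [], []
                for layer in range(len(self.W) - 1, -1, -1):
                    grads_W.insert(0, acts[layer].T @ delta)
                    grads_b.insert(0, delta.sum(axis=0))
                    if layer:
                        delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
                t += 1
                params = self.W + self.b
                grads = grads_W + grads_b
                for i, (p_, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    p_ -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, X):
        return self._forward(np.asarray(X, dtype=float))[1]


class _NNClassifier:
    """sklearn-style wrapper around :class:`_DenseNet`."""

    def __init__(self, spec: SupervisedModelSpec, seed: int):
        self._spec = spec
        self._seed = seed

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        if sample_weight is None:
            sample_weight = np.ones(X.shape[0])
        self._net = _DenseNet(
            X.shape[1],
            self._spec.nn_hidden,
            self.classes_.size,
            seed=self._seed,
            lr=self._spec.nn_learning_rate,
            batch_size=self._spec.nn_batch_size,
            epochs=self._spec.nn_epochs,
        ).fit(X, onehot, np.asarray(sample_weight, dtype=float))
        return self

    def predict_proba(self, X):
        return self._net.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------


def build_training_variants(
    seed_pool: SamplePool,
    pseudo_pool_a: Optional[SamplePool],
    pseudo_pool_b: Optional[SamplePool],
    tiers: pd.DataFrame,
) -> List[TrainingVariant]:
    """Materialize BASELINE / PLUS_HC / PLUS_LC / PLUS_ALL.

    ``tiers`` must hold one row per pseudo-labeled sample (columns
    sample_id, tier).  Pool A is the held-back reference half, pool B an
    external cohort; their ids must not overlap the seed pool or each
    other.  ``counts`` tables stratify each composition by frequency
    (low = class with < 10 seed-labeled samples).
    """
    pools = [p for p in (pseudo_pool_a, pseudo_pool_b) if p is not None and p.n]
    all_ids = [seed_pool.ids] + [p.ids for p in pools]
    joined = np.concatenate(all_ids)
    if np.unique(joined).size != joined.size:
        raise ValueError("sample ids overlap across pools")

    tier_map = dict(zip(tiers["sample_id"].astype(str), tiers["tier"]))
    if pools:
        pseudo_ids = np.concatenate([p.ids for p in pools])
        missing = [i for i in pseudo_ids if str(i) not in tier_map]
        if missing:
            raise ValueError(
                f"{len(missing)} pseudo-labeled samples lack a tier, e.g. {missing[:3]}"
            )

    seed_classes, seed_counts = np.unique(seed_pool.y.astype(str), return_counts=True)
    freq = {
        c: ("low" if n < LOW_FREQUENCY_CUTOFF else "high")
        for c, n in zip(seed_classes, seed_counts)
    }

    def stratum(label) -> str:
        return freq.get(str(label), "low")  # unseen-in-seed classes are rare

    def gather(wanted_tiers) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids, Xs, ys = [], [], []
        for p in pools:
            keep = np.asarray([tier_map[str(i)] in wanted_tiers for i in p.ids])
            ids.append(p.ids[keep])
            Xs.append(p.X[keep])
            ys.append(p.y[keep])
        if not ids:
            d = seed_pool.X.shape[1]
            return (np.empty(0, dtype=object), np.empty((0, d)), np.empty(0, dtype=seed_pool.y.dtype))
        return np.concatenate(ids), np.vstack(Xs), np.concatenate(ys)

    wanted = {
        VariantName.BASELINE: (),
        VariantName.PLUS_HC: ("HC",),
        VariantName.PLUS_LC: ("LC",),
        VariantName.PLUS_ALL: ("HC", "LC"),
    }
    variants: List[TrainingVariant] = []
    for name, tiers_wanted in wanted.items():
        ids, X, y = gather(tiers_wanted)
        rows = [
            {
                "source": "seed",
                "stratum": s,
                "count": int(sum(stratum(l) == s for l in seed_pool.y)),
            }
            for s in ("high", "low")
        ]
        for s in ("high", "low"):
            rows.append(
                {
                    "source": "pseudo",
                    "stratum": s,
                    "count": int(sum(stratum(l) == s for l in y)),
                }
            )
        variants.append(
            TrainingVariant(
                name=name,
                extra_ids=ids,
                extra_X=X,
                extra_y=y,
                counts=pd.DataFrame(rows),
            )
        )
        if name is not VariantName.BASELINE and ids.size == 0:
            logger.warning("variant %s adds no pseudo-labels (== BASELINE)", name.value)
    return variants


# ---------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------


def train_supervised(spec: SupervisedModelSpec, X, y, class_weighting: str = "balanced"):
    """Fit one supervised classifier with balanced sample weights.

    Returns an estimator exposing ``predict`` and ``predict_proba``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("supervised training needs >= 2 classes")
    if (counts == 1).any():
        logger.warning(
            "train_supervised: %d classes have a single sample", int((counts == 1).sum())
        )
    sw = balanced_sample_weights(y) if class_weighting == "balanced" else None
    if spec.kind == "rf":
        est = RandomForestClassifier(
            n_estimators=spec.rf_n_trees, random_state=spec.seed, n_jobs=1
        )
        return est.fit(X, y, sample_weight=sw)
    return _NNClassifier(spec, seed=spec.seed).fit(X, y, sample_weight=sw)


def _weighted_recall(truth, predicted) -> float:
    """Recall weighted by balanced sample weights (equals balanced accuracy
    when every class is predicted at least once against itself)."""
    truth = np.asarray(truth)
    w = balanced_sample_weights(truth)
    correct = (np.asarray(predicted) == truth).astype(float)
    return float((w * correct).sum() / w.sum())


@dataclass
class ComparisonReport:
    """CV and hold-out metrics per variant x classifier, plus Tukey HSD."""

    cv_table: pd.DataFrame
    holdout_table: pd.DataFrame
    tukey_table: pd.DataFrame
    variant_counts: Dict[str, pd.DataFrame] = field(default_factory=dict)


def evaluate_variants(
    variants: Sequence[TrainingVariant],
    seed_pool: SamplePool,
    specs: Sequence[SupervisedModelSpec],
    holdout_resamples: int = 7,
    cv_repeats: int = 5,
    cv_folds: int = 3,
    holdout_frac: float = 0.30,
    seed: int = 0,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Run the full variant comparison.

    Hold-out sets are stratified 30% resamples of the *seed-labeled* pool
    only — pseudo-labeled samples are never evaluated against, an
    assertable hygiene rule.  Every variant and classifier sees identical
    hold-out draws.  Cross-validation (``cv_repeats`` x stratified
    ``cv_folds``; ``cv_repeats=0`` skips it) runs on each variant's full
    training composition.  Hold-out balanced accuracies are compared
    across variants per classifier with Tukey HSD at ``alpha``.
    """
    if holdout_resamples < 2:
        logger.warning("fewer than 2 hold-out resamples: comparisons skipped")
    cv_rows, ho_rows = [], []
    seed_y = seed_pool.y

    sss = StratifiedShuffleSplit(
        n_splits=holdout_resamples, test_size=holdout_frac, random_state=seed
    )
    splits = list(sss.split(seed_pool.X, seed_y.astype(str)))

    for spec in specs:
        for var in variants:
            # --- cross-validation on the full composition -------------
            X_full = np.vstack([seed_pool.X, var.extra_X])
            y_full = np.concatenate([seed_pool.y, var.extra_y])
            _, fold_counts = np.unique(y_full.astype(str), return_counts=True)
            k = max(2, min(cv_folds, int(fold_counts.min())))
            cv_splits = (
                RepeatedStratifiedKFold(
                    n_splits=k, n_repeats=cv_repeats, random_state=seed
                ).split(X_full, y_full.astype(str))
                if cv_repeats > 0
                else ()
            )
            for fold, (tr, va) in enumerate(cv_splits):
                if np.unique(y_full[tr]).size < 2:
                    continue
                est = train_supervised(spec, X_full[tr], y_full[tr])
                pred = est.predict(X_full[va])
                m = multiclass_metrics(y_full[va], pred)
                cv_rows.append(
                    {
                        "classifier": spec.kind,
                        "variant": var.name.value,
                        "fold": fold,
                        "balanced_accuracy": m.balanced_accuracy,
                        "weighted_recall": _weighted_recall(y_full[va], pred),
                    }
                )
            # --- hold-out resamples -----------------------------------
            for r, (tr, ho) in enumerate(splits):
                assert np.intersect1d(
                    seed_pool.ids[ho], var.extra_ids
                ).size == 0, "pseudo-labeled sample leaked into a hold-out set"
                X_tr = np.vstack([seed_pool.X[tr], var.extra_X])
                y_tr = np.concatenate([seed_y[tr], var.extra_y])
                est = train_supervised(spec, X_tr, y_tr)
                pred = est.predict(seed_pool.X[ho])
                m = multiclass_metrics(seed_y[ho], pred)
                ho_rows.append(
                    {
                        "classifier": spec.kind,
                        "variant": var.name.value,
                        "resample": r,
                        "balanced_accuracy": m.balanced_accuracy,
                        "accuracy": m.accuracy,
                    }
                )

    ho = pd.DataFrame(ho_rows)
    tk_rows = []
    if holdout_resamples >= 2 and not ho.empty:
        for clf, sub in ho.groupby("classifier"):
            if sub["variant"].nunique() < 2:
                continue
            res = pairwise_tukeyhsd(
                sub["balanced_accuracy"].to_numpy(),
                sub["variant"].to_numpy(),
                alpha=alpha,
            )
            tbl = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
            tbl.insert(0, "classifier", clf)
            tk_rows.append(tbl)
    tukey = pd.concat(tk_rows, ignore_index=True) if tk_rows else pd.DataFrame()
    return ComparisonReport(
        cv_table=pd.DataFrame(cv_rows),
        holdout_table=ho,
        tukey_table=tukey,
        variant_counts={v.name.value: v.counts for v in variants},
    )


# ---------------------------------------------------------------------
# packaged end-to-end experiment
# ---------------------------------------------------------------------


def default_experiment_cohort(seed: int = 0) -> CohortSpec:
    """The packaged augmentation cohort: 15 subclasses in 5 families.

    Twelve common classes of 45 samples in four three-subclass families,
    plus three rare classes (8, 7 and 6 samples) that each form their own
    family, give 561 samples with the severe imbalance the tier analysis
    is about.  Rare tumor entities are typically molecularly distinct
    rather than subclasses of a common type, hence the singleton families;
    moderate beta noise (concentration 8) leaves some low-confidence
    pseudo-labels for the tiers to separate.
    """
    sizes = [45] * 12 + [8, 7, 6]
    return CohortSpec(
        n_families=7,
        subclasses_per_family=[3, 3, 3, 3, 1, 1, 1],
        samples_per_subclass=sizes,
        n_probes=1000,
        n_informative_per_subclass=16,
        family_share=0.7,
        concentration=8.0,
        seed=seed,
    )


def run_augmentation_experiment(
    cohort_spec: Optional[CohortSpec] = None,
    specs: Optional[Sequence[SupervisedModelSpec]] = None,
    sd_threshold: float = 0.0,
    tau: float = 0.8,
    holdout_resamples: int = 7,
    cv_repeats: int = 5,
    cv_folds: int = 3,
    n_lambda: int = 40,
    seed: int = 0,
) -> ComparisonReport:
    """Generate a cohort, pseudo-label it with SETRED-SVM, and compare variants.

    Pipeline: draw the reference cohort and a same-structure external
    cohort (new samples from the same archetypes, as a prospective cohort
    profiled on the same array would be); select features by SD on the
    reference cohort; split the reference 30% hold-out-population / 35%
    labeled / 35% unlabeled; fit SETRED-SVM, calibrate its transductive
    scores and tier them at ``tau``; pseudo-label the external cohort
    inductively (pool B) with the same calibration; then evaluate BASELINE
    vs the pseudo-label variants with the supervised classifiers.  The
    seed-labeled population used for hold-out resampling is the labeled
    pool plus the 30% hold-out population — pseudo-labeled samples never
    reach a hold-out set.
    """
    if cohort_spec is None:
        cohort_spec = default_experiment_cohort(seed)
    if specs is None:
        specs = [
            SupervisedModelSpec(kind="rf", seed=seed),
            SupervisedModelSpec(kind="nn", nn_hidden=(64, 32), seed=seed),
        ]
    # reference + external samples in one draw so both share archetypes
    # and informative-probe structure; per-subclass blocks are split in two
    sizes = list(cohort_spec.samples_per_subclass)
    big = generate_cohort(
        CohortSpec(
            **{**cohort_spec.__dict__, "samples_per_subclass": [2 * s for s in sizes]}
        )
    )
    ref_idx, ext_idx = [], []
    start = 0
    for s in sizes:
        ref_idx.extend(range(start, start + s))
        ext_idx.extend(range(start + s, start + 2 * s))
        start += 2 * s
    ref_idx = np.asarray(ref_idx)
    ext_idx = np.asarray(ext_idx)

    beta_all = BetaMatrix.from_frame(big.beta)
    ref_beta = BetaMatrix(
        sample_ids=beta_all.sample_ids[ref_idx],
        probe_ids=beta_all.probe_ids,
        values=beta_all.values[ref_idx],
    )
    sel = select_features_by_sd(ref_beta, FeatureSelectConfig(sd_threshold))
    keep = np.asarray([list(beta_all.probe_ids).index(p) for p in sel.probe_ids])
    ext_X = beta_all.values[ext_idx][:, keep]
    ext_truth = big.mc_labels[ext_idx]

    plan = make_bootstrap_partitions(
        big.mc_labels[ref_idx], n_boot=1, test_frac=0.30, labeled_frac=0.5, seed=seed
    )[0]
    X = sel.values
    y = big.mc_labels[ref_idx]
    lab, unlab, held = plan.labeled_idx, plan.unlabeled_idx, plan.inductive_test_idx

    ssl_spec = model_grid(seed=seed)["setred-svm"]
    fit = fit_ssl(ssl_spec, X[lab], y[lab], X[unlab])

    ids_a = np.asarray([f"pseudoA_{i}" for i in range(unlab.size)], dtype=object)
    raw_a = RawScoreMatrix(
        sample_ids=ids_a, class_ids=fit.classes_, scores=fit.raw_scores
    )
    cal_model = fit_calibration(raw_a, y[unlab], n_lambda=n_lambda, seed=seed)
    cal_a = calibrate(cal_model, raw_a)
    tiers_a = assign_confidence_tiers(cal_a, ConfidenceConfig(tau))

    # external cohort (pool B): labeled inductively by the SSL fit
    ext_lab, ext_scores = predict(fit, ext_X)
    ids_b = np.asarray([f"pseudoB_{i}" for i in range(ext_X.shape[0])], dtype=object)
    raw_b = RawScoreMatrix(sample_ids=ids_b, class_ids=fit.classes_, scores=ext_scores)
    cal_b = calibrate(cal_model, raw_b)
    tiers_b = assign_confidence_tiers(cal_b, ConfidenceConfig(tau))

    seed_ids = np.asarray(
        [f"seed_{i}" for i in range(lab.size + held.size)], dtype=object
    )
    seed_pool = SamplePool(
        ids=seed_ids,
        X=np.vstack([X[lab], X[held]]),
        y=np.concatenate([y[lab], y[held]]),
    )
    pool_a = SamplePool(ids=ids_a, X=X[unlab], y=fit.pseudo_labels)
    pool_b = SamplePool(ids=ids_b, X=ext_X, y=ext_lab)
    tiers = pd.concat([tiers_a, tiers_b], ignore_index=True)

    variants = build_training_variants(seed_pool, pool_a, pool_b, tiers)
    return evaluate_variants(
        variants,
        seed_pool,
        specs,
        holdout_resamples=holdout_resamples,
        cv_repeats=cv_repeats,
        cv_folds=cv_folds,
        seed=seed,
    )
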
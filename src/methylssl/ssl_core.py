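"""Self-labeled semi-supervised classifiers.

Five training schemes over three classical base learners, yielding the
eleven model combinations benchmarked for methylation-class assignment:

==========  =========================================  ================
scheme      idea                                       base learners
==========  =========================================  ================
SELFT       plain self-training                        1-NN, tree, SVM
SETRED      self-training with cut-edge data editing   1-NN, tree, SVM
SNNRCE      self-training NN rule with cut edges       fixed 1-NN
TRITRAIN    tri-training (three bootstrapped views)    1-NN, tree, SVM
DEMO        democratic co-learning                     all three jointly
==========  =========================================  ================

SETRED and SNNRCE edit candidate pseudo-labels with a statistic on the
relative neighborhood graph (RNG): for a vertex v with label y and incident
edge weights w_e = 1/(1+d), the observed cut-edge weight J = sum of w_e over
edges whose endpoints disagree.  Under the null that neighbor labels are
i.i.d. with prior p_y, J has mean (1-p_y)*sum(w_e) and variance
p_y*(1-p_y)*sum(w_e^2); a candidate whose standardized J lands in the upper
tail has too many disagreeing neighbors and is likely mislabeled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerKind",
    "Scheme",
    "BaseLearnerSpec",
    "SSLModelSpec",
    "SSLFit",
    "CutEdgeStat",
    "NeighborhoodGraph",
    "IsolatedVertexError",
    "fit_base_learner",
    "build_rng",
    "cut_edge_statistic",
    "self_train",
    "setred_train",
    "snnrce_train",
    "tri_train",
    "demo_train",
    "fit_ssl",
    "predict",
    "model_grid",
]


class LearnerKind(str, Enum):
    ONE_NN = "1nn"
    TREE = "tree"
    SVM_RBF = "svm"


class Scheme(str, Enum):
    SELFT = "selft"
    SETRED = "setred"
    SNNRCE = "snnrce"
    TRITRAIN = "tritrain"
    DEMO = "demo"


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A classical supervised base learner.

    1-NN uses Euclidean distance; the tree is an entropy-criterion decision
    tree standing in for C5.0 (exact C5.0 internals are proprietary); the
    SVM is soft-margin C-classification with an RBF kernel and
    pairwise-coupled probability estimates.  ``svm_gamma='auto'`` means
    1/n_features.
    """

    kind: LearnerKind = LearnerKind.ONE_NN
    svm_cost: float = 1.0
    svm_gamma: float | str = "auto"
    tree_max_depth: Optional[int] = None
    tree_min_leaf: int = 1


@dataclass(frozen=True)
class SSLModelSpec:
    """One scheme x learner combination with its hyperparameters.

    ``theta`` is SETRED's editing significance level, ``alpha`` SNNRCE's
    relabeling level; ``perc_full`` is the fraction of the unlabeled pool a
    self-training loop may consume; all randomness flows from ``seed``.
    """

    scheme: Scheme
    learners: Tuple[BaseLearnerSpec, ...] = (BaseLearnerSpec(),)
    max_iter: int = 50
    perc_full: float = 0.7
    theta: float = 0.1
    alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme is Scheme.DEMO:
            if len(self.learners) != 3:
                raise ValueError("DEMO needs exactly three base learners")
        elif self.scheme is Scheme.SNNRCE:
            if any(l.kind is not LearnerKind.ONE_NN for l in self.learners):
                raise ValueError("SNNRCE's built-in learner is fixed to 1-NN")
        elif len(self.learners) != 1:
            raise ValueError(f"{self.scheme.value} takes a single base learner")


def model_grid(seed: int = 0, **overrides) -> Dict[str, SSLModelSpec]:
    """The eleven valid scheme x learner combinations, by canonical name."""
    one_nn = BaseLearnerSpec(LearnerKind.ONE_NN)
    tree = BaseLearnerSpec(LearnerKind.TREE)
    svm = BaseLearnerSpec(LearnerKind.SVM_RBF)
    grid: Dict[str, SSLModelSpec] = {}
    for scheme in (Scheme.SELFT, Scheme.SETRED, Scheme.TRITRAIN):
        for learner in (one_nn, tree, svm):
            name = f"{scheme.value}-{learner.kind.value}"
            grid[name] = SSLModelSpec(
                scheme=scheme, learners=(learner,), seed=seed, **overrides
            )
    grid["snnrce"] = SSLModelSpec(
        scheme=Scheme.SNNRCE, learners=(one_nn,), seed=seed, **overrides
    )
    grid["demo"] = SSLModelSpec(
        scheme=Scheme.DEMO, learners=(one_nn, tree, svm), seed=seed, **overrides
    )
    return grid


# ---------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------


class Predictor:
    """Fitted base learner exposing labels and per-class scores.

    ``predict_scores`` returns one row per sample over ``classes_`` with
    non-negative entries summing to 1; ``predict`` is the row-wise argmax
    with ties broken toward the smallest class index.
    """

    classes_: np.ndarray

    def predict_scores(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


class _ConstantPredictor(Predictor):
    def __init__(self, label):
        self.classes_ = np.asarray([label])

    def predict_scores(self, X):
        return np.ones((np.asarray(X).shape[0], 1))


class _OneNN(Predictor):
    """1-NN with distance-softened per-class confidences.

    score_c proportional to 1/(1 + d_c) with d_c the Euclidean distance to
    the nearest training point of class c; the argmax equals the 1-NN
    label.
    """

    def __init__(self, X, y):
        self._X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._class_masks = [y == c for c in self.classes_]

    def predict_scores(self, X):
        X = np.asarray(X, dtype=float)
        d2 = (
            np.square(X).sum(axis=1)[:, None]
            + np.square(self._X).sum(axis=1)[None, :]
            - 2.0 * X @ self._X.T
        )
        np.maximum(d2, 0.0, out=d2)
        d = np.sqrt(d2)
        per_class = np.column_stack([d[:, m].min(axis=1) for m in self._class_masks])
        scores = 1.0 / (1.0 + per_class)
        return scores / scores.sum(axis=1, keepdims=True)


class _SkWrap(Predictor):
    def __init__(self, est):
        self._est = est
        self.classes_ = est.classes_

    def predict_scores(self, X):
        return self._est.predict_proba(np.asarray(X, dtype=float))


class _SVMPredictor(Predictor):
    """RBF-SVM with softmax-normalized decision values as confidences.

    Platt-style probability estimates need an internal cross-validation
    that is ill-defined for the rare classes (< 5 samples) this pipeline
    must handle, so confidences are a softmax over the one-vs-rest
    aggregated pairwise decision values instead; the argmax always agrees
    with the SVM's own label prediction.
    """

    def __init__(self, est):
        self._est = est
        self.classes_ = est.classes_

    def predict_scores(self, X):
        d = self._est.decision_function(np.asarray(X, dtype=float))
        if d.ndim == 1:  # binary: signed distance for classes_[1]
            d = np.column_stack([-d, d]) / 2.0
        d = d - d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)


def fit_base_learner(
    spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> Predictor:
    """Fit one base learner; returns a :class:`Predictor`.

    Single-class training sets yield a constant predictor with confidence 1
    for that class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a base learner on an empty training set")
    if np.unique(y).size == 1:
        return _ConstantPredictor(y[0])
    if spec.kind is LearnerKind.ONE_NN:
        return _OneNN(X, y)
    if spec.kind is LearnerKind.TREE:
        est = DecisionTreeClassifier(
            criterion="entropy",
            max_depth=spec.tree_max_depth,
            min_samples_leaf=spec.tree_min_leaf,
            random_state=seed,
        )
        return _SkWrap(est.fit(X, y))
    if spec.kind is LearnerKind.SVM_RBF:
        est = SVC(
            C=spec.svm_cost,
            kernel="rbf",
            gamma=spec.svm_gamma,
            decision_function_shape="ovr",
            random_state=seed,
        )
        return _SVMPredictor(est.fit(X, y))
    raise ValueError(f"unknown learner kind {spec.kind}")


def align_scores(
    scores: np.ndarray, pred_classes: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Expand a score matrix onto the full class list, absent classes at 0."""
    out = np.zeros((scores.shape[0], len(classes)))
    index = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(pred_classes):
        out[:, index[c]] = scores[:, j]
    return out


# ---------------------------------------------------------------------
# relative neighborhood graph and cut-edge statistic
# ---------------------------------------------------------------------


class IsolatedVertexError(ValueError):
    """The cut-edge statistic is undefined for a vertex without edges."""


@dataclass
class NeighborhoodGraph:
    """Undirected RNG with cached Euclidean distances.

    Edge weights are w = 1/(1+d), bounded in (0, 1].
    """

    adjacency: np.ndarray  # boolean n x n, symmetric, zero diagonal
    distances: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[v])

    def edge_weights(self, v: int) -> np.ndarray:
        nb = self.neighbors(v)
        return 1.0 / (1.0 + self.distances[v, nb])


@dataclass
class CutEdgeStat:
    """Observed cut-edge weight and its null moments for one vertex."""

    J: float
    mu0: float
    sigma0: float
    z: float


def build_rng(X: np.ndarray) -> NeighborhoodGraph:
    """Relative neighborhood graph under the Euclidean metric.

    Edge (a, b) exists iff no third point c satisfies
    max(d(a,c), d(c,b)) < d(a,b).  Duplicate points (d = 0) are always
    connected, as a zero distance cannot be blocked.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("an RNG needs at least 2 points")
    sq = np.square(X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2)
    # min over c of max(d(a,c), d(c,b)); c in {a, b} yields d(a,b) itself,
    # which never satisfies the strict inequality, so no exclusion needed
    blocked = np.min(np.maximum(D[:, None, :], D[None, :, :]), axis=2) < D
    adj = ~blocked
    np.fill_diagonal(adj, False)
    adj &= adj.T
    return NeighborhoodGraph(adjacency=adj, distances=D)


def cut_edge_statistic(
    graph: NeighborhoodGraph,
    labels: np.ndarray,
    priors: Dict,
    vertex: int,
) -> CutEdgeStat:
    """Standardized cut-edge weight for one vertex.

    ``priors`` maps each label to its null frequency p_y.  J sums the
    weights of incident edges whose far endpoint disagrees with the
    vertex's label; under the i.i.d.-neighbor null,
    mu0 = (1-p_y) * sum(w) and sigma0^2 = p_y (1-p_y) * sum(w^2).
    """
    labels = np.asarray(labels)
    nb = graph.neighbors(vertex)
    if nb.size == 0:
        raise IsolatedVertexError(f"vertex {vertex} has no incident edge")
    w = graph.edge_weights(vertex)
    y = labels[vertex]
    cut = labels[nb] != y
    J = float(w[cut].sum())
    p = float(priors[y])
    mu0 = (1.0 - p) * float(w.sum())
    var0 = p * (1.0 - p) * float(np.square(w).sum())
    sigma0 = math.sqrt(var0)
    if sigma0 > 0:
        z = (J - mu0) / sigma0
    else:  # degenerate prior p in {0, 1}
        z = math.inf if J > mu0 else (-math.inf if J < mu0 else 0.0)
    return CutEdgeStat(J=J, mu0=mu0, sigma0=sigma0, z=z)


# ---------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------


@dataclass
class SSLFit:
    """Result of one SSL training run.

    ``pseudo_labels`` holds one label per unlabeled sample (the assigned
    pseudo-label for consumed samples, the final prediction otherwise);
    ``raw_scores`` is the transductive per-class score matrix over
    ``classes_``; ``edit_log`` records per-iteration accept/reject counts.
    """

    spec: SSLModelSpec
    classes_: np.ndarray
    predictors: List[Predictor]
    pseudo_labels: np.ndarray
    consumed: np.ndarray
    raw_scores: np.ndarray
    edit_log: List[dict] = field(default_factory=list)
    vote_weights: Optional[np.ndarray] = None  # DEMO eligibility weights

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.vote_weights is not None:
            total = np.zeros((X.shape[0], len(self.classes_)))
            wsum = 0.0
            for w, p in zip(self.vote_weights, self.predictors):
                if w <= 0:
                    continue
                total += w * align_scores(p.predict_scores(X), p.classes_, self.classes_)
                wsum += w
            if wsum == 0:  # no eligible voter; fall back to unweighted mean
                for p in self.predictors:
                    total += align_scores(p.predict_scores(X), p.classes_, self.classes_)
                wsum = float(len(self.predictors))
            return total / wsum
        if len(self.predictors) == 1:
            p = self.predictors[0]
            return align_scores(p.predict_scores(X), p.classes_, self.classes_)
        total = np.zeros((X.shape[0], len(self.classes_)))
        for p in self.predictors:
            total += align_scores(p.predict_scores(X), p.classes_, self.classes_)
        return total / len(self.predictors)


def predict(fit: SSLFit, X: np.ndarray):
    """Inductive prediction: labels (argmax, smallest-index tie-break) + scores."""
    scores = fit.predict_scores(X)
    labels = fit.classes_[np.argmax(scores, axis=1)]
    n_ties = int((np.isclose(scores, scores.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("predict: %d rows had tied top scores (smallest index wins)", n_ties)
    return labels, scores


# ---------------------------------------------------------------------
# self-training loop (SELFT, and SETRED through an editing hook)
# ---------------------------------------------------------------------


def _class_quotas(p: np.ndarray, batch: int) -> np.ndarray:
    """Largest-remainder rounding of class-proportional shares, min 1 each."""
    raw = p * batch
    quotas = np.floor(raw).astype(int)
    rem = raw - quotas
    short = batch - quotas.sum()
    for i in np.argsort(-rem, kind="stable")[: max(short, 0)]:
        quotas[i] += 1
    return np.maximum(quotas, 1)


def _self_train_impl(spec: SSLModelSpec, X_l, y_l, X_u, editor=None) -> SSLFit:
    learner = spec.learners[0]
    X_l = np.asarray(X_l, dtype=float)
    y_l = np.asarray(y_l)
    X_u = np.asarray(X_u, dtype=float)
    classes = np.unique(y_l)
    n_u0 = X_u.shape[0]

    cur_X = X_l.copy()
    cur_y = y_l.copy()
    pseudo = np.empty(n_u0, dtype=y_l.dtype)
    consumed = np.zeros(n_u0, dtype=bool)
    edit_log: List[dict] = []

    if n_u0 and spec.max_iter > 0:
        p = np.array([(y_l == c).mean() for c in classes])
        n_target = int(math.floor(spec.perc_full * n_u0))
        batch = max(len(classes), math.ceil(n_target / max(spec.max_iter, 1)))
        quotas = _class_quotas(p, batch)
        remaining = np.arange(n_u0)
        for _ in range(spec.max_iter):
            if consumed.sum() >= n_target or remaining.size == 0:
                break
            pred = fit_base_learner(learner, cur_X, cur_y, seed=spec.seed)
            scores = align_scores(
                pred.predict_scores(X_u[remaining]), pred.classes_, classes
            )
            conf = scores.max(axis=1)
            pred_lab = classes[np.argmax(scores, axis=1)]
            cand: List[int] = []
            for ci, c in enumerate(classes):
                pool = np.flatnonzero(pred_lab == c)
                if pool.size == 0:
                    continue
                order = pool[np.argsort(-conf[pool], kind="stable")]
                cand.extend(remaining[order[: quotas[ci]]])
            cand_idx = np.asarray(sorted(cand), dtype=int)
            if cand_idx.size == 0:
                break
            local = {u: i for i, u in enumerate(remaining)}
            cand_lab = pred_lab[[local[u] for u in cand_idx]]
            if editor is not None:
                accept_mask = editor(cur_X, cur_y, X_u[cand_idx], cand_lab)
            else:
                accept_mask = np.ones(cand_idx.size, dtype=bool)
            edit_log.append(
                {
                    "candidates": int(cand_idx.size),
                    "accepted": int(accept_mask.sum()),
                    "rejected": int((~accept_mask).sum()),
                }
            )
            accepted = cand_idx[accept_mask]
            if accepted.size == 0:
                break  # editing stalls: nothing acceptable this round
            cur_X = np.vstack([cur_X, X_u[accepted]])
            cur_y = np.concatenate([cur_y, cand_lab[accept_mask]])
            pseudo[accepted] = cand_lab[accept_mask]
            consumed[accepted] = True
            remaining = np.setdiff1d(remaining, accepted, assume_unique=True)

    final = fit_base_learner(learner, cur_X, cur_y, seed=spec.seed)
    if n_u0:
        raw = align_scores(final.predict_scores(X_u), final.classes_, classes)
        pred_all = classes[np.argmax(raw, axis=1)]
        pseudo[~consumed] = pred_all[~consumed]
    else:
        raw = np.zeros((0, len(classes)))
    return SSLFit(
        spec=spec,
        classes_=classes,
        predictors=[final],
        pseudo_labels=pseudo,
        consumed=consumed,
        raw_scores=raw,
        edit_log=edit_log,
    )


def self_train(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Plain self-training (SELFT).

    Iteratively fits the base learner, moves its most confident unlabeled
    predictions into the labeled set (class-proportional quotas, minimum 1
    per class so rare classes are not frozen out) until ``perc_full`` of
    the unlabeled pool is consumed or ``max_iter`` is reached.
    """
    return _self_train_impl(spec, X_l, y_l, X_u, editor=None)


def setred_edit(X_l, y_l, X_cand, cand_lab, theta: float = 0.1) -> np.ndarray:
    """SETRED's candidate screen; returns the boolean accept mask.

    Builds the RNG over labeled points plus candidates and keeps only
    candidates whose cut-edge weight J lies significantly *below* its null
    mean: under the null that neighbor labels are i.i.d. with the
    labeled-set class frequencies, a correctly labeled point should show
    fewer disagreeing neighbors than chance, so a candidate is rejected
    when its standardized J exceeds the left-tail critical value
    Phi^{-1}(theta) — equivalently, when J exceeds the quantile q with
    P(J > q) = 1 - theta.  Isolated candidates are accepted unedited —
    the statistic is undefined and rejection would starve rare classes.
    ``theta = 1`` pushes the critical value to +inf and disables editing.
    """
    X_l = np.asarray(X_l, dtype=float)
    X_cand = np.asarray(X_cand, dtype=float)
    cand_lab = np.asarray(cand_lab)
    zcrit = norm.ppf(theta)
    labels_all = np.concatenate([np.asarray(y_l), cand_lab])
    graph = build_rng(np.vstack([X_l, X_cand]))
    classes, counts = np.unique(y_l, return_counts=True)
    priors = dict(zip(classes, counts / counts.sum()))
    n_l = X_l.shape[0]
    accept = np.ones(X_cand.shape[0], dtype=bool)
    for i in range(X_cand.shape[0]):
        try:
            stat = cut_edge_statistic(graph, labels_all, priors, n_l + i)
        except IsolatedVertexError:
            continue  # no neighborhood evidence; accept
        if stat.z > zcrit:
            accept[i] = False
    return accept


def setred_train(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Self-training with editing (SETRED).

    Each candidate batch is screened by :func:`setred_edit` before
    insertion; rejected candidates return to the unlabeled pool.
    ``theta >= 1`` disables editing, reducing SETRED to SELFT.
    """

    def editor(cur_X, cur_y, X_cand, cand_lab):
        return setred_edit(cur_X, cur_y, X_cand, cand_lab, theta=spec.theta)

    return _self_train_impl(spec, X_l, y_l, X_u, editor=editor)


# ---------------------------------------------------------------------
# SNNRCE
# ---------------------------------------------------------------------


def snnrce_train(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Self-training nearest-neighbor rule using cut edges (fixed 1-NN).

    Phase 1: on the RNG over all points, unlabeled vertices whose labeled
    neighbors unanimously agree take that label.  Phase 2: plain 1-NN
    self-training consumes the remainder.  Phase 3: initially-unlabeled
    vertices whose cut-edge z-score exceeds the normal critical value at
    level ``alpha`` are relabeled to the majority label of their RNG
    neighbors.  Scores come from the final 1-NN predictor.
    """
    one_nn = BaseLearnerSpec(LearnerKind.ONE_NN)
    spec = replace(spec, learners=(one_nn,))
    X_l = np.asarray(X_l, dtype=float)
    y_l = np.asarray(y_l)
    X_u = np.asarray(X_u, dtype=float)
    classes = np.unique(y_l)
    n_l, n_u = X_l.shape[0], X_u.shape[0]
    if n_u == 0:
        return _self_train_impl(spec, X_l, y_l, X_u)

    X_all = np.vstack([X_l, X_u])
    graph = build_rng(X_all)
    labels = np.empty(n_l + n_u, dtype=y_l.dtype)
    labels[:n_l] = y_l
    assigned = np.zeros(n_l + n_u, dtype=bool)
    assigned[:n_l] = True

    # phase 1: vertices whose RNG neighborhood is entirely labeled and
    # unanimous take that label (single simultaneous pass)
    phase1: List[int] = []
    for v in range(n_l, n_l + n_u):
        nb = graph.neighbors(v)
        if nb.size and (nb < n_l).all() and np.unique(y_l[nb]).size == 1:
            labels[v] = y_l[nb[0]]
            phase1.append(v)
    for v in phase1:
        assigned[v] = True

    # phase 2: 1-NN self-training on the rest
    rest = np.flatnonzero(~assigned)
    inner = _self_train_impl(
        spec,
        X_all[assigned],
        labels[assigned],
        X_all[rest],
    )
    labels[rest] = inner.pseudo_labels
    consumed = np.zeros(n_u, dtype=bool)
    consumed[[v - n_l for v in phase1]] = True
    rest_u = rest - n_l
    consumed[rest_u] = inner.consumed

    # phase 3: cut-edge relabeling of initially-unlabeled vertices
    zcrit = norm.ppf(1.0 - spec.alpha)
    cls, counts = np.unique(labels, return_counts=True)
    priors = dict(zip(cls, counts / counts.sum()))
    relabeled = 0
    new_labels = labels.copy()
    for v in range(n_l, n_l + n_u):
        nb = graph.neighbors(v)
        if nb.size == 0:
            continue
        stat = cut_edge_statistic(graph, labels, priors, v)
        if stat.z > zcrit:
            vals, cnt = np.unique(labels[nb], return_counts=True)
            new_labels[v] = vals[np.argmax(cnt)]  # ties: smallest label
            if new_labels[v] != labels[v]:
                relabeled += 1
    labels = new_labels

    final = fit_base_learner(one_nn, X_all, labels, seed=spec.seed)
    raw = align_scores(final.predict_scores(X_u), final.classes_, classes)
    return SSLFit(
        spec=spec,
        classes_=classes,
        predictors=[final],
        pseudo_labels=labels[n_l:],
        consumed=consumed,
        raw_scores=raw,
        edit_log=[
            {"phase1_labeled": len(phase1), "phase3_relabeled": relabeled}
        ],
    )


# ---------------------------------------------------------------------
# tri-training
# ---------------------------------------------------------------------


def tri_train(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Tri-training: three bootstrapped copies of one base learner.

    In each round a learner is retrained on L plus the unlabeled points its
    two peers agree on, but only while the peers' joint error keeps the
    e_i * |L_i| product shrinking (subsampling L_i when needed).  The final
    label is the majority vote; scores average the three aligned
    confidence rows.
    """
    learner = spec.learners[0]
    X_l = np.asarray(X_l, dtype=float)
    y_l = np.asarray(y_l)
    X_u = np.asarray(X_u, dtype=float)
    classes = np.unique(y_l)
    n_l, n_u = X_l.shape[0], X_u.shape[0]
    rng = np.random.default_rng(spec.seed)

    preds: List[Predictor] = []
    for i in range(3):
        idx = rng.integers(0, n_l, size=n_l)
        # guarantee every class survives the bootstrap
        missing = np.setdiff1d(classes, np.unique(y_l[idx]))
        for c in missing:
            idx = np.concatenate([idx, np.flatnonzero(y_l == c)[:1]])
        preds.append(fit_base_learner(learner, X_l[idx], y_l[idx], seed=spec.seed + i))

    e_prev = [0.5, 0.5, 0.5]
    l_prev = [0, 0, 0]
    extra: List[Tuple[np.ndarray, np.ndarray]] = [(np.empty((0, X_l.shape[1])), np.empty(0, dtype=y_l.dtype))] * 3

    if n_u:
        for _ in range(max(spec.max_iter, 1)):
            lab_l = [p.predict(X_l) for p in preds]
            lab_u = [p.predict(X_u) for p in preds]
            updates: List[Optional[Tuple[np.ndarray, np.ndarray, float, int]]] = [None] * 3
            for i in range(3):
                j, k = [t for t in range(3) if t != i]
                agree_l = lab_l[j] == lab_l[k]
                if agree_l.any():
                    e_i = float((lab_l[j][agree_l] != y_l[agree_l]).mean())
                else:
                    e_i = 0.5
                if e_i >= e_prev[i]:
                    continue
                agree_u = np.flatnonzero(lab_u[j] == lab_u[k])
                li = agree_u
                if l_prev[i] == 0:
                    l_prev[i] = int(math.floor(e_i / (e_prev[i] - e_i) + 1))
                if li.size <= l_prev[i]:
                    continue
                if e_i * li.size >= e_prev[i] * l_prev[i]:
                    if l_prev[i] > e_i / (e_prev[i] - e_i):
                        s = int(math.ceil(e_prev[i] * l_prev[i] / e_i - 1))
                        li = rng.choice(li, size=min(s, li.size), replace=False)
                        li.sort()
                    else:
                        continue
                if e_i * li.size >= e_prev[i] * l_prev[i]:
                    continue
                updates[i] = (li, lab_u[j][li], e_i, li.size)
            if all(u is None for u in updates):
                break
            for i, u in enumerate(updates):
                if u is None:
                    continue
                li, lab, e_i, sz = u
                extra[i] = (X_u[li], lab)
                e_prev[i], l_prev[i] = e_i, sz
                preds[i] = fit_base_learner(
                    learner,
                    np.vstack([X_l, extra[i][0]]),
                    np.concatenate([y_l, extra[i][1]]),
                    seed=spec.seed + i,
                )

    fit = SSLFit(
        spec=spec,
        classes_=classes,
        predictors=preds,
        pseudo_labels=np.empty(n_u, dtype=y_l.dtype),
        consumed=np.zeros(n_u, dtype=bool),
        raw_scores=np.zeros((n_u, len(classes))),
        edit_log=[{"final_errors": e_prev, "pool_sizes": l_prev}],
    )
    if n_u:
        fit.raw_scores = fit.predict_scores(X_u)
        votes = np.stack([p.predict(X_u) for p in preds])
        maj = np.empty(n_u, dtype=y_l.dtype)
        for s in range(n_u):
            vals, cnt = np.unique(votes[:, s], return_counts=True)
            maj[s] = vals[np.argmax(cnt)]
        fit.pseudo_labels = maj
        fit.consumed = np.ones(n_u, dtype=bool)
    return fit


# ---------------------------------------------------------------------
# democratic co-learning
# ---------------------------------------------------------------------


def _accuracy_bounds(pred: Predictor, X, y, level: float = 0.95):
    """Normal-approximation confidence bounds on labeled-set accuracy."""
    acc = float((pred.predict(X) == y).mean())
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(acc * (1.0 - acc), 0.0) / len(y))
    return max(acc - half, 0.0), min(acc + half, 1.0)


def demo_train(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Democratic co-learning over the three heterogeneous learners.

    Per round each unlabeled point gets a confidence-weighted majority
    label; a dissenting learner adopts the point only when the agreeing
    group's summed lower-bound accuracies beat the dissenters'.  The final
    vote weighs learners by mean CI accuracy and excludes any learner whose
    lower bound is <= 0.5.
    """
    X_l = np.asarray(X_l, dtype=float)
    y_l = np.asarray(y_l)
    X_u = np.asarray(X_u, dtype=float)
    classes = np.unique(y_l)
    n_u = X_u.shape[0]

    preds = [
        fit_base_learner(sp, X_l, y_l, seed=spec.seed + i)
        for i, sp in enumerate(spec.learners)
    ]
    transfers = 0
    if n_u:
        prev_rep: List[Tuple] = [() for _ in range(3)]
        for _ in range(max(spec.max_iter, 1)):
            bounds = [_accuracy_bounds(p, X_l, y_l) for p in preds]
            weights = [(lo + hi) / 2.0 for lo, hi in bounds]
            lab_u = [p.predict(X_u) for p in preds]
            proposals: List[List[int]] = [[], [], []]
            prop_labels: List[List] = [[], [], []]
            for s in range(n_u):
                vote: Dict = {}
                for i in range(3):
                    vote[lab_u[i][s]] = vote.get(lab_u[i][s], 0.0) + weights[i]
                c_star = min(
                    (c for c in vote), key=lambda c: (-vote[c], str(c))
                )
                agree = [i for i in range(3) if lab_u[i][s] == c_star]
                dissent = [i for i in range(3) if lab_u[i][s] != c_star]
                if not dissent:
                    continue
                if sum(bounds[i][0] for i in agree) > sum(bounds[i][0] for i in dissent):
                    for i in dissent:
                        proposals[i].append(s)
                        prop_labels[i].append(c_star)
            rep = [
                tuple(zip(proposals[i], map(str, prop_labels[i]))) for i in range(3)
            ]
            if rep == prev_rep:
                break  # training sets unchanged
            for i in range(3):
                if rep[i] == prev_rep[i]:
                    continue
                transfers += len(proposals[i])
                preds[i] = fit_base_learner(
                    spec.learners[i],
                    np.vstack([X_l, X_u[proposals[i]]]),
                    np.concatenate(
                        [y_l, np.asarray(prop_labels[i], dtype=y_l.dtype)]
                    ),
                    seed=spec.seed + i,
                )
            prev_rep = rep

    bounds = [_accuracy_bounds(p, X_l, y_l) for p in preds]
    vote_weights = np.array(
        [((lo + hi) / 2.0) if lo > 0.5 else 0.0 for lo, hi in bounds]
    )
    fit = SSLFit(
        spec=spec,
        classes_=classes,
        predictors=preds,
        pseudo_labels=np.empty(n_u, dtype=y_l.dtype),
        consumed=np.ones(n_u, dtype=bool),
        raw_scores=np.zeros((n_u, len(classes))),
        edit_log=[{"transfers": transfers, "vote_weights": vote_weights.tolist()}],
        vote_weights=vote_weights,
    )
    if n_u:
        fit.raw_scores = fit.predict_scores(X_u)
        fit.pseudo_labels = classes[np.argmax(fit.raw_scores, axis=1)]
    return fit


_DISPATCH = {
    Scheme.SELFT: self_train,
    Scheme.SETRED: setred_train,
    Scheme.SNNRCE: snnrce_train,
    Scheme.TRITRAIN: tri_train,
    Scheme.DEMO: demo_train,
}


def fit_ssl(spec: SSLModelSpec, X_l, y_l, X_u) -> SSLFit:
    """Train the scheme named in ``spec`` on labeled + unlabeled data."""
    return _DISPATCH[spec.scheme](spec, X_l, y_l, X_u)
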
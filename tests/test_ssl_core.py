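"""Base learners, RNG/cut-edge statistics and the five SSL schemes."""

from dataclasses import replace

import numpy as np
import pytest

from methylssl import (
    BaseLearnerSpec,
    LearnerKind,
    SSLModelSpec,
    Scheme,
    build_rng,
    cut_edge_statistic,
    fit_base_learner,
    fit_ssl,
    inject_label_noise,
    make_bootstrap_partitions,
    model_grid,
    predict,
)
from methylssl.ssl_core import IsolatedVertexError, setred_edit

LEARNERS = [
    BaseLearnerSpec(LearnerKind.ONE_NN),
    BaseLearnerSpec(LearnerKind.TREE),
    BaseLearnerSpec(LearnerKind.SVM_RBF),
]


def _split(cohort, features, labeled_frac=0.5, seed=0):
    plan = make_bootstrap_partitions(
        cohort.mc_labels, n_boot=1, test_frac=0.0, labeled_frac=labeled_frac, seed=seed
    )[0]
    X = features.values
    return (
        X[plan.labeled_idx],
        cohort.mc_labels[plan.labeled_idx],
        X[plan.unlabeled_idx],
        cohort.mc_labels[plan.unlabeled_idx],
    )


class TestBaseLearners:
    def test_one_nn_nearest_by_euclidean(self):
        pred = fit_base_learner(
            LEARNERS[0], np.array([[0.0], [10.0]]), np.array(["A", "B"])
        )
        assert pred.predict(np.array([[1.0]]))[0] == "A"

    @pytest.mark.parametrize("spec", LEARNERS, ids=lambda s: s.kind.value)
    def test_training_points_recovered_on_separable_toy(self, spec):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0], [0.0, 5.0], [0.1, 5.0]])
        y = np.array(["a", "a", "b", "b", "c", "c"])
        pred = fit_base_learner(spec, X, y, seed=0)
        assert (pred.predict(X) == y).all()

    @pytest.mark.parametrize("spec", LEARNERS, ids=lambda s: s.kind.value)
    def test_confidence_rows_normalized(self, spec, rng):
        X = rng.uniform(size=(30, 4))
        y = rng.choice(["a", "b", "c"], size=30)
        pred = fit_base_learner(spec, X, y, seed=0)
        scores = pred.predict_scores(rng.uniform(size=(8, 4)))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert (scores >= 0).all()

    def test_single_class_constant_predictor(self):
        pred = fit_base_learner(LEARNERS[2], np.zeros((3, 2)), np.array(["z"] * 3))
        labels = pred.predict(np.ones((4, 2)))
        assert (labels == "z").all()
        np.testing.assert_allclose(pred.predict_scores(np.ones((4, 2))), 1.0)

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            fit_base_learner(LEARNERS[0], np.empty((0, 2)), np.empty(0))


class TestRelativeNeighborhoodGraph:
    def test_colinear_points_middle_blocks(self):
        g = build_rng(np.array([[0.0], [1.0], [2.0]]))
        expected = np.array(
            [[False, True, False], [True, False, True], [False, True, False]]
        )
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_two_points_single_edge(self):
        g = build_rng(np.array([[0.0], [3.0]]))
        assert g.adjacency[0, 1] and g.adjacency[1, 0]

    def test_equilateral_triangle_fully_connected(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        g = build_rng(X)
        assert g.adjacency.sum() == 6  # 3 undirected edges

    def test_duplicate_points_connected(self):
        g = build_rng(np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]))
        assert g.adjacency[0, 1]

    def test_matches_brute_force_oracle(self, rng):
        def brute_force(X):
            n = len(X)
            d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            adj = np.zeros((n, n), dtype=bool)
            for a in range(n):
                for b in range(a + 1, n):
                    blocked = any(
                        max(d[a, c], d[c, b]) < d[a, b]
                        for c in range(n)
                        if c not in (a, b)
                    )
                    adj[a, b] = adj[b, a] = not blocked
            return adj

        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.uniform(size=(r.integers(5, 31), r.integers(1, 4)))
            np.testing.assert_array_equal(build_rng(X).adjacency, brute_force(X))


class TestCutEdgeStatistic:
    def test_hand_computed_colinear_example(self):
        # points 0,1,2 labeled A,B,A; vertex 1 has both edges cut with w=0.5
        g = build_rng(np.array([[0.0], [1.0], [2.0]]))
        labels = np.array(["A", "B", "A"])
        stat = cut_edge_statistic(g, labels, {"B": 1 / 3, "A": 2 / 3}, 1)
        assert stat.J == pytest.approx(1.0)
        assert stat.mu0 == pytest.approx(2 / 3, abs=1e-4)
        assert stat.sigma0**2 == pytest.approx(1 / 9, abs=1e-4)

    def test_uniform_labels_have_zero_cut_weight(self, rng):
        X = rng.uniform(size=(12, 2))
        g = build_rng(X)
        labels = np.array(["same"] * 12)
        for v in range(12):
            if g.neighbors(v).size:
                assert cut_edge_statistic(g, labels, {"same": 1.0}, v).J == 0.0

    def test_prior_near_one_makes_cut_edges_extreme(self):
        g = build_rng(np.array([[0.0], [1.0], [2.0]]))
        labels = np.array(["A", "B", "A"])
        stat = cut_edge_statistic(g, labels, {"B": 0.999, "A": 0.001}, 1)
        assert stat.mu0 < 0.01
        assert stat.z > 10

    def test_isolated_vertex_signalled(self):
        g = build_rng(np.array([[0.0], [1.0], [2.0]]))
        g.adjacency[:, 1] = g.adjacency[1, :] = False
        with pytest.raises(IsolatedVertexError):
            cut_edge_statistic(g, np.array(["A", "B", "A"]), {"B": 0.5}, 1)


class TestSchemeReductions:
    """Every scheme with an empty unlabeled pool reduces to its base fit."""

    @pytest.mark.parametrize("name", list(model_grid()))
    def test_empty_unlabeled_pool_reduces_to_base(self, name, separable_cohort,
                                                  separable_features):
        X = separable_features.values
        y = separable_cohort.mc_labels
        spec = model_grid(seed=0)[name]
        fit = fit_ssl(spec, X, y, np.empty((0, X.shape[1])))
        assert fit.pseudo_labels.size == 0
        labels, scores = predict(fit, X)
        assert (labels == y).all()
        assert scores.shape == (len(y), len(fit.classes_))

    def test_setred_theta_one_equals_selft(self, separable_cohort, separable_features):
        Xl, yl, Xu, _ = _split(separable_cohort, separable_features)
        setred = replace(model_grid(seed=0)["setred-svm"], theta=1.0)
        selft = model_grid(seed=0)["selft-svm"]
        f1 = fit_ssl(setred, Xl, yl, Xu)
        f2 = fit_ssl(selft, Xl, yl, Xu)
        np.testing.assert_array_equal(f1.pseudo_labels, f2.pseudo_labels)
        np.testing.assert_allclose(f1.raw_scores, f2.raw_scores)

    def test_max_iter_zero_scores_from_initial_fit(self, separable_cohort,
                                                   separable_features):
        Xl, yl, Xu, yu = _split(separable_cohort, separable_features)
        spec = replace(model_grid(seed=0)["selft-1nn"], max_iter=0)
        fit = fit_ssl(spec, Xl, yl, Xu)
        assert not fit.consumed.any()
        base = fit_base_learner(BaseLearnerSpec(LearnerKind.ONE_NN), Xl, yl)
        np.testing.assert_array_equal(fit.pseudo_labels, base.predict(Xu))


class TestNoiselessRecovery:
    @pytest.mark.parametrize("name", list(model_grid()))
    def test_all_models_perfect_on_separable_cohort(self, name, separable_cohort,
                                                    separable_features):
        Xl, yl, Xu, yu = _split(separable_cohort, separable_features)
        fit = fit_ssl(model_grid(seed=0)[name], Xl, yl, Xu)
        trans_acc = (fit.pseudo_labels == yu).mean()
        assert trans_acc >= (0.9 if name == "snnrce" else 1.0)

    def test_raw_scores_shape_and_finite(self, separable_cohort, separable_features):
        Xl, yl, Xu, _ = _split(separable_cohort, separable_features)
        fit = fit_ssl(model_grid(seed=0)["demo"], Xl, yl, Xu)
        assert fit.raw_scores.shape == (Xu.shape[0], len(fit.classes_))
        assert np.isfinite(fit.raw_scores).all()
        np.testing.assert_allclose(fit.raw_scores.sum(axis=1), 1.0, atol=1e-9)


class TestSetredEditing:
    def test_noisy_candidates_rejected_more_often(self, rng):
        from methylssl import (
            BetaMatrix,
            CohortSpec,
            FeatureSelectConfig,
            generate_cohort,
            select_features_by_sd,
        )

        wins = 0
        for seed in range(5):
            spec = CohortSpec(
                n_families=3,
                subclasses_per_family=[2, 2, 2],
                samples_per_subclass=[20] * 6,
                n_probes=1000,
                n_informative_per_subclass=30,
                concentration=15.0,
                seed=100 + seed,
            )
            c = generate_cohort(spec)
            sel = select_features_by_sd(
                BetaMatrix.from_frame(c.beta), FeatureSelectConfig(0.2)
            )
            plan = make_bootstrap_partitions(c.mc_labels, n_boot=1, seed=seed)[0]
            X_l = sel.values[plan.labeled_idx]
            y_l = c.mc_labels[plan.labeled_idx]
            X_c = sel.values[plan.unlabeled_idx]
            y_c, mask = inject_label_noise(
                c.mc_labels[plan.unlabeled_idx], 0.2, seed=seed
            )
            accept = setred_edit(X_l, y_l, X_c, y_c, theta=0.1)
            if (~accept[mask]).mean() > (~accept[~mask]).mean():
                wins += 1
        assert wins >= 4

    def test_edit_log_counts_accepts_and_rejects(self, midnoise_cohort):
        from methylssl import BetaMatrix, FeatureSelectConfig, select_features_by_sd

        sel = select_features_by_sd(
            BetaMatrix.from_frame(midnoise_cohort.beta), FeatureSelectConfig(0.2)
        )
        Xl, yl, Xu, _ = _split(midnoise_cohort, sel, labeled_frac=0.2)
        fit = fit_ssl(model_grid(seed=0)["setred-1nn"], Xl, yl, Xu)
        assert fit.edit_log
        for row in fit.edit_log:
            assert row["candidates"] == row["accepted"] + row["rejected"]


class TestSnnrce:
    def test_unanimous_labeled_neighborhood_labeled_in_phase1(self):
        # u at 1.0 sits between two labeled A points; its RNG neighbors are
        # exactly those labeled points, so phase 1 assigns A
        X_l = np.array([[0.0], [2.0], [10.0]])
        y_l = np.array(["A", "A", "B"])
        X_u = np.array([[1.0]])
        fit = fit_ssl(model_grid(seed=0)["snnrce"], X_l, y_l, X_u)
        assert fit.pseudo_labels[0] == "A"
        assert fit.edit_log[0]["phase1_labeled"] == 1

    def test_noiseless_cohort_no_phase3_relabeling(self, separable_cohort,
                                                   separable_features):
        Xl, yl, Xu, yu = _split(separable_cohort, separable_features)
        fit = fit_ssl(model_grid(seed=0)["snnrce"], Xl, yl, Xu)
        assert fit.edit_log[0]["phase3_relabeled"] == 0

    def test_alpha_one_relabels_to_neighborhood_majority(self):
        # degenerate level: every vertex with a cut edge adopts its
        # neighborhood majority; the isolated mislabel cannot survive
        spec = replace(model_grid(seed=0)["snnrce"], alpha=1.0)
        X_l = np.array([[0.0], [1.0], [2.0], [3.0], [20.0]])
        y_l = np.array(["A", "A", "A", "A", "B"])
        X_u = np.array([[1.5]])
        fit = fit_ssl(spec, X_l, y_l, X_u)
        assert fit.pseudo_labels[0] == "A"


class TestTriTrainAndDemo:
    def test_tritrain_agreement_covers_u_when_learners_identical(
        self, separable_cohort, separable_features
    ):
        Xl, yl, Xu, yu = _split(separable_cohort, separable_features)
        fit = fit_ssl(model_grid(seed=3)["tritrain-1nn"], Xl, yl, Xu)
        assert (fit.pseudo_labels == yu).all()

    def test_demo_excludes_weak_voter(self):
        from methylssl.ssl_core import SSLFit, _ConstantPredictor

        # a learner whose labeled-set accuracy lower bound is <= 0.5 gets
        # vote weight 0 in the final combination
        fit = SSLFit(
            spec=model_grid()["demo"],
            classes_=np.array(["a", "b"]),
            predictors=[_ConstantPredictor("a"), _ConstantPredictor("b"),
                        _ConstantPredictor("a")],
            pseudo_labels=np.empty(0),
            consumed=np.empty(0, dtype=bool),
            raw_scores=np.empty((0, 2)),
            vote_weights=np.array([0.9, 0.0, 0.8]),
        )
        scores = fit.predict_scores(np.zeros((1, 1)))
        np.testing.assert_allclose(scores, [[1.0, 0.0]])

    def test_demo_unanimity_no_transfers(self, separable_cohort, separable_features):
        Xl, yl, Xu, _ = _split(separable_cohort, separable_features)
        fit = fit_ssl(model_grid(seed=0)["demo"], Xl, yl, Xu)
        assert fit.edit_log[0]["transfers"] == 0


class TestPredict:
    def test_argmax_and_tie_break(self):
        from methylssl.ssl_core import SSLFit, _ConstantPredictor

        class FixedScores:
            classes_ = np.array(["c1", "c2", "c3"])

            def predict_scores(self, X):
                return np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0]])

        fit = SSLFit(
            spec=model_grid()["selft-1nn"],
            classes_=np.array(["c1", "c2", "c3"]),
            predictors=[FixedScores()],
            pseudo_labels=np.empty(0),
            consumed=np.empty(0, dtype=bool),
            raw_scores=np.empty((0, 3)),
        )
        labels, _ = predict(fit, np.zeros((2, 1)))
        assert list(labels) == ["c2", "c1"]  # tie row → smallest class index


class TestDeterminism:
    @pytest.mark.parametrize("name", ["setred-svm", "tritrain-tree", "demo", "snnrce"])
    def test_same_seed_identical_fit(self, name, midnoise_cohort):
        from methylssl import BetaMatrix, FeatureSelectConfig, select_features_by_sd

        sel = select_features_by_sd(
            BetaMatrix.from_frame(midnoise_cohort.beta), FeatureSelectConfig(0.2)
        )
        Xl, yl, Xu, _ = _split(midnoise_cohort, sel, labeled_frac=0.3)
        a = fit_ssl(model_grid(seed=7)[name], Xl, yl, Xu)
        b = fit_ssl(model_grid(seed=7)[name], Xl, yl, Xu)
        np.testing.assert_array_equal(a.pseudo_labels, b.pseudo_labels)
        np.testing.assert_array_equal(a.raw_scores, b.raw_scores)


class TestModelGrid:
    def test_exactly_eleven_valid_combinations(self):
        grid = model_grid()
        assert len(grid) == 11
        assert grid["snnrce"].learners[0].kind is LearnerKind.ONE_NN
        assert len(grid["demo"].learners) == 3

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            SSLModelSpec(scheme=Scheme.DEMO, learners=(BaseLearnerSpec(),))
        with pytest.raises(ValueError):
            SSLModelSpec(
                scheme=Scheme.SNNRCE,
                learners=(BaseLearnerSpec(LearnerKind.TREE),),
            )
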
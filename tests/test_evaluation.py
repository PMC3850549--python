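import numpy as np
import pandas as pd
import pytest

from nhmc import (
    ClassHierarchy,
    NetworkHMCClassifier,
    aupr_average,
    binarize,
    evaluate,
    holdout_protocol,
    pr_area,
    pr_curve,
    select_significance,
    tau_grid,
)
from nhmc.synthetic import SynthConfig, generate


class TestTauGrid:
    def test_default_grid_has_51_points_with_both_endpoints(self):
        g = tau_grid()
        assert len(g) == 51
        assert g[0] == 0.0 and g[-1] == 1.0


class TestBinarize:
    def test_tau_one_predicts_nothing(self):
        assert not binarize(np.array([[1.0, 0.9]]), 1.0).any()

    def test_tau_zero_predicts_all_positive_scores(self):
        np.testing.assert_array_equal(
            binarize(np.array([[0.4, 0.0, 1.0]]), 0.0), [[1, 0, 1]]
        )

    def test_scalar_tau_yields_ancestor_closed_predictions(self):
        cfg = SynthConfig(n=100, depth=2, m_cont=5, delta=1.5, seed=1)
        h, ds, net = generate(cfg)
        est = NetworkHMCClassifier(alpha=0.5, significance=0.05)
        est.fit(ds.X, ds.Y, hierarchy=h, network=net, ids=ds.ids)
        scores = est.predict_proba(ds.X)
        for tau in tau_grid():
            pred = binarize(scores, tau)
            closed = h.close_bits(pred)
            np.testing.assert_array_equal(pred, closed)

    def test_per_class_tau_must_be_ancestor_monotone(self):
        h = ClassHierarchy.from_paths(["A", "A/A1"])
        scores = np.array([[0.9, 0.4]])
        np.testing.assert_array_equal(
            binarize(scores, np.array([0.2, 0.5]), h), [[1, 0]]
        )
        with pytest.raises(ValueError, match="ancestor"):
            binarize(scores, np.array([0.5, 0.2]), h)


class TestPRCurve:
    def test_perfect_scores_have_unit_area(self):
        truth = np.array([[1], [1], [0], [0]])
        scores = truth.astype(float)
        points = pr_curve(scores, truth, 0)
        assert len(points) == 51
        assert pr_area(points) == pytest.approx(1.0)

    def test_random_scores_approach_positive_rate(self, rng):
        n, pi = 4000, 0.3
        truth = (rng.random((n, 1)) < pi).astype(int)
        scores = rng.random((n, 1))
        area = pr_area(pr_curve(scores, truth, 0))
        assert area == pytest.approx(pi, abs=0.05)

    def test_class_without_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.zeros((3, 1)), np.zeros((3, 1), dtype=int), 0)

    def test_grid_resolution_bounds_deviation_from_threshold_free_area(self, rng):
        """The 51-point grid area stays close to the exact threshold-free
        PR area; residual differences are a documented grid artifact."""
        from sklearn.metrics import average_precision_score

        n = 1500
        truth = (rng.random((n, 1)) < 0.4).astype(int)
        scores = np.clip(truth[:, 0] * 0.3 + rng.random(n) * 0.7, 0, 1)[:, None]
        grid_area = pr_area(pr_curve(scores, truth, 0))
        exact = average_precision_score(truth[:, 0], scores[:, 0])
        assert grid_area == pytest.approx(exact, abs=0.05)


class TestAuprAverage:
    def test_all_unit_areas_average_to_one(self):
        assert aupr_average([1.0, 1.0], [5, 5], "uniform") == 1.0
        assert aupr_average([1.0, 1.0], [5, 5], "frequency") == 1.0

    def test_equal_frequencies_agree_across_modes(self):
        assert aupr_average([0.0, 1.0], [7, 7], "uniform") == 0.5
        assert aupr_average([0.0, 1.0], [7, 7], "frequency") == 0.5

    def test_frequency_mode_upweights_the_common_class(self):
        areas, counts = [0.2, 1.0], [90, 10]
        assert aupr_average(areas, counts, "uniform") == pytest.approx(0.6)
        assert aupr_average(areas, counts, "frequency") == pytest.approx(0.28)


class TestEvaluate:
    def test_classes_without_positives_are_excluded(self):
        h = ClassHierarchy.from_paths(["A", "B"])
        truth = np.array([[1, 0], [1, 0]])
        scores = np.array([[0.9, 0.1], [0.8, 0.2]])
        report = evaluate(scores, truth, h)
        assert report.n_included == 1
        assert report.excluded_classes == ["B"]
        assert 0.0 <= report.average <= 1.0

    def test_average_lies_in_unit_interval_on_random_data(self, rng):
        scores = rng.random((50, 4))
        truth = (rng.random((50, 4)) < 0.4).astype(int)
        truth[0] = 1  # make sure every class has a positive
        assert 0.0 <= evaluate(scores, truth).average <= 1.0


class TestSelectSignificance:
    def _data(self, seed=0, n=60):
        cfg = SynthConfig(n=n, depth=1, branching=2, m_cont=4, delta=2.0, seed=seed)
        return generate(cfg)

    def test_single_candidate_returned_unconditionally(self):
        h, ds, net = self._data()
        level = select_significance(ds.X, ds.Y, h, [0.01], ids=ds.ids)
        assert level == 0.01

    def test_returned_level_is_a_candidate(self):
        h, ds, net = self._data()
        levels = [0.01, 0.05, 0.125]
        got = select_significance(
            ds.X, ds.Y, h, levels, network=net, ids=ds.ids,
            params={"alpha": 0.5}, seed=3,
        )
        assert got in levels

    def test_pure_dataset_ties_resolve_to_smallest_level(self):
        h = ClassHierarchy.from_paths(["A"])
        X = pd.DataFrame({"x1": np.linspace(0, 1, 12)})
        Y = np.ones((12, 1), dtype=np.uint8)
        got = select_significance(X, Y, h, [0.005, 0.05, 0.125],
                                  params={"alpha": 1.0}, seed=0)
        assert got == 0.005


class TestHoldoutProtocol:
    def test_split_proportions_and_determinism(self):
        cfg = SynthConfig(n=90, depth=2, m_cont=5, delta=1.5, seed=6)
        h, ds, net = generate(cfg)
        est1, rep1 = holdout_protocol(ds, net, {"alpha": 0.5, "significance": 0.05}, seed=4)
        est2, rep2 = holdout_protocol(ds, net, {"alpha": 0.5, "significance": 0.05}, seed=4)
        # 2/3 - 1/3 within one example
        n_leaf_examples = sum(
            leaf for leaf in _leaf_sizes(est1.model_.root)
        )
        assert abs(n_leaf_examples - 60) <= 1
        assert rep1.average == rep2.average
        assert est1.model_.structure() == est2.model_.structure()

    def test_test_set_edges_never_enter_training(self):
        """Adding edges incident to held-out examples must not change the
        trained model: the network is restricted to training ids."""
        cfg = SynthConfig(n=90, depth=2, m_cont=5, delta=1.2, p_in=0.3, seed=8)
        h, ds, net = generate(cfg)
        est1, _ = holdout_protocol(ds, net, {"alpha": 0.3, "significance": 0.05}, seed=1)
        # find the held-out ids for seed=1 and pollute the network around them
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.n_examples)
        test_ids = [ds.ids[i] for i in sorted(perm[: int(round(90 / 3))])]
        for t in test_ids:
            for u in ds.ids[:20]:
                if u != t:
                    net.add_edge(t, u, 5.0)
        est2, _ = holdout_protocol(ds, net, {"alpha": 0.3, "significance": 0.05}, seed=1)
        assert est1.model_.structure() == est2.model_.structure()

    def test_explicit_id_lists_respected(self):
        cfg = SynthConfig(n=45, depth=1, m_cont=4, delta=2.0, seed=2)
        h, ds, net = generate(cfg)
        train_ids, test_ids = ds.ids[:30], ds.ids[30:]
        est, rep = holdout_protocol(
            ds, net, {"alpha": 1.0, "significance": 0.05},
            train_ids=train_ids, test_ids=test_ids,
        )
        assert sum(_leaf_sizes(est.model_.root)) == 30


def _leaf_sizes(node):
    if hasattr(node, "prototype"):
        return [node.n_examples]
    return _leaf_sizes(node.left) + _leaf_sizes(node.right)
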
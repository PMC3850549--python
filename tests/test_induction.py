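import numpy as np
import pandas as pd
import pytest

from nhmc import (
    ClassHierarchy,
    HMCTreeClassifier,
    Network,
    NetworkHMCClassifier,
    PCTModel,
    build_tree,
    candidate_thresholds,
    f_test_accept,
)
from nhmc.induction import TreeBuilder, _prepare_columns, enumerate_discrete_subsets
from nhmc.synthetic import SynthConfig, generate

from ._oracles import brute_autocorrelation, brute_variance


class TestCandidateEnumeration:
    def test_midpoints_between_distinct_values(self):
        assert candidate_thresholds([1, 3, 3, 7]) == [2.0, 5.0]

    def test_constant_or_missing_column_yields_no_tests(self):
        assert candidate_thresholds([4, 4, 4]) == []
        assert candidate_thresholds([np.nan, np.nan]) == []

    def test_missing_values_excluded_from_thresholds(self):
        assert candidate_thresholds([1.0, np.nan, 3.0]) == [2.0]

    def test_discrete_greedy_chain_is_nested_and_proper(self):
        # score favours {'a'}, then {'a','c'}; {'a','b','c'} is the full
        # domain and must never be proposed
        target = {frozenset("a"): 3.0, frozenset("ac"): 5.0, frozenset("ab"): 1.0,
                  frozenset("b"): 1.0, frozenset("c"): 2.0, frozenset("bc"): 0.5}
        chain = enumerate_discrete_subsets(
            ["a", "b", "c", "a"], lambda s: target.get(s, 0.0)
        )
        assert chain == [frozenset("a"), frozenset("ac")]
        for earlier, later in zip(chain, chain[1:]):
            assert earlier < later

    def test_discrete_growth_stops_when_score_drops(self):
        chain = enumerate_discrete_subsets(
            ["a", "b", "c"], lambda s: {frozenset("a"): 2.0}.get(s, 1.0)
        )
        assert chain == [frozenset("a")]


class TestFTest:
    def test_no_reduction_rejected_at_every_level(self):
        for level in (0.001, 0.05, 0.125):
            assert not f_test_accept(0.4, 0.4, 50, level)

    def test_perfect_split_always_accepted(self):
        assert f_test_accept(0.4, 0.0, 50, 0.001)

    def test_acceptance_monotone_in_level(self):
        # a moderate reduction: acceptance at a stricter level implies
        # acceptance at every looser level
        levels = [0.001, 0.005, 0.01, 0.05, 0.1, 0.125]
        decisions = [f_test_accept(0.40, 0.37, 40, lv) for lv in levels]
        for stricter, looser in zip(decisions, decisions[1:]):
            assert looser or not stricter

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            f_test_accept(1.0, 0.5, 1, 0.05)
        with pytest.raises(ValueError):
            f_test_accept(1.0, 0.5, 10, 1.5)


def _fit(ds, h, net=None, **kw):
    kw.setdefault("significance", 0.05)
    est = NetworkHMCClassifier(**kw)
    return est.fit(ds.X, ds.Y, hierarchy=h, network=net, ids=ds.ids)


class TestBuildTree:
    def test_pure_labels_give_single_leaf_with_common_vector(self):
        h = ClassHierarchy.from_paths(["A", "B"])
        X = pd.DataFrame({"x1": np.arange(12, dtype=float)})
        Y = np.tile(h.close(["A"]), (12, 1))
        est = NetworkHMCClassifier(alpha=1.0, significance=0.05).fit(X, Y, hierarchy=h)
        assert est.model_.n_leaves == 1
        np.testing.assert_array_equal(est.predict_proba(X)[0], h.close(["A"]))

    def test_perfectly_separating_attribute_chosen_at_root(self, rng):
        h = ClassHierarchy.from_paths(["A", "B"])
        n = 40
        group = np.arange(n) < n // 2
        X = pd.DataFrame({
            "noise": rng.standard_normal(n),
            "signal": np.where(group, 0.0, 10.0) + rng.standard_normal(n) * 0.01,
        })
        Y = np.where(group[:, None], h.close(["A"]), h.close(["B"])).astype(np.uint8)
        est = NetworkHMCClassifier(alpha=1.0, significance=0.05).fit(X, Y, hierarchy=h)
        root = est.model_.root
        assert root.test.name == "signal"

    def test_alpha1_identical_to_variance_only_learner(self):
        """Mixing coefficient 1 must reproduce the variance-only baseline
        node for node and score for score, despite the different scoring
        code path (normalised vs raw variance reduction)."""
        for seed in range(3):
            cfg = SynthConfig(n=100, depth=2, m_cont=5, m_disc=2, delta=1.5, seed=seed)
            h, ds, net = generate(cfg)
            a = _fit(ds, h, alpha=1.0)
            b = HMCTreeClassifier(significance=0.05).fit(ds.X, ds.Y, hierarchy=h, ids=ds.ids)
            assert a.model_.structure() == b.model_.structure()
            np.testing.assert_array_equal(a.predict_proba(ds.X), b.predict_proba(ds.X))

    def test_alpha_below_one_requires_network(self):
        cfg = SynthConfig(n=30, depth=1, m_cont=3, m_disc=0, seed=0)
        h, ds, _ = generate(cfg)
        with pytest.raises(ValueError, match="network"):
            _fit(ds, h, alpha=0.5, net=None)
        _fit(ds, h, alpha=1.0, net=None)  # variance-only mode needs none

    def test_min_leaf_respected(self):
        cfg = SynthConfig(n=80, depth=2, m_cont=5, delta=2.0, seed=3)
        h, ds, net = generate(cfg)
        est = _fit(ds, h, net, alpha=0.5, min_leaf=7)

        def leaves(node):
            if hasattr(node, "prototype"):
                return [node.n_examples]
            return leaves(node.left) + leaves(node.right)

        assert min(leaves(est.model_.root)) >= 7

    def test_leaf_prototypes_monotone_along_hierarchy(self):
        cfg = SynthConfig(n=120, depth=3, m_cont=6, delta=1.5, seed=5)
        h, ds, net = generate(cfg)
        est = _fit(ds, h, net, alpha=0.5)
        scores = est.predict_proba(ds.X)
        for c in h.classes:
            k = h.index[c]
            for p in h.parents[c]:
                assert np.all(scores[:, h.index[p]] >= scores[:, k] - 1e-12)

    def test_network_never_influences_prediction(self):
        """Predictions are a function of the serialized tree alone: a model
        trained with the network predicts identically after the network
        object is discarded (round trip through JSON)."""
        cfg = SynthConfig(n=90, depth=2, m_cont=5, delta=1.2, seed=7)
        h, ds, net = generate(cfg)
        est = _fit(ds, h, net, alpha=0.3)
        before = est.predict_proba(ds.X)
        del net
        reloaded = PCTModel.from_dict(est.model_.to_dict())
        np.testing.assert_array_equal(reloaded.predict(ds.X), before)

    def test_linearity_in_alpha_for_candidate_scores(self):
        cfg = SynthConfig(n=60, depth=2, m_cont=4, delta=1.0, seed=11)
        h, ds, net = generate(cfg)
        cols = _prepare_columns(ds.X)
        restricted = net.restrict(ds.ids)
        Yf = ds.Y.astype(float)
        adjacency = [[] for _ in ds.ids]
        for i, j, w in restricted.edges():
            d2 = float(np.dot(h.weights, (Yf[i] - Yf[j]) ** 2))
            adjacency[i].append((j, w, d2))
            adjacency[j].append((i, w, d2))
        scores = {}
        for alpha in (0.0, 0.5, 1.0):
            # alpha=1 builders skip A_Y; force its computation for comparison
            b = TreeBuilder(cols, ds.Y, h.weights, adjacency, alpha=alpha,
                            min_leaf=5, significance=0.05)
            b._need_autocorr = True
            idx = np.arange(len(ds.ids))
            recs = b.enumerate_candidates(idx)
            node_var = brute_variance(h.weights, ds.Y)
            s, _, _ = b.score_candidates(recs, node_var, len(idx))
            # key by the test itself: the greedy discrete chain depends on
            # alpha, so only tests present under every alpha are comparable
            scores[alpha] = {
                (r.attribute, r.threshold, r.subset): v for r, v in zip(recs, s)
            }
        common = set(scores[0.0]) & set(scores[0.5]) & set(scores[1.0])
        assert len(common) >= 50
        for key in common:
            assert scores[0.5][key] == pytest.approx(
                (scores[0.0][key] + scores[1.0][key]) / 2.0, rel=1e-9, abs=1e-12
            )

    def test_incremental_candidate_stats_match_brute_force(self):
        """Every candidate's child variance and A_Y produced by the sweep
        equals a from-scratch double-loop recomputation of that partition."""
        cfg = SynthConfig(n=30, depth=2, m_cont=3, m_disc=1, delta=1.0,
                          p_in=0.4, p_out=0.05, seed=13)
        h, ds, net = generate(cfg)
        cols = _prepare_columns(ds.X)
        restricted = net.restrict(ds.ids)
        n = len(ds.ids)
        W = np.zeros((n, n))
        for i, j, w in restricted.edges():
            W[i, j] = W[j, i] = w
        Yf = ds.Y.astype(float)
        adjacency = [[] for _ in range(n)]
        for i, j, w in restricted.edges():
            d2 = float(np.dot(h.weights, (Yf[i] - Yf[j]) ** 2))
            adjacency[i].append((j, w, d2))
            adjacency[j].append((i, w, d2))
        builder = TreeBuilder(cols, ds.Y, h.weights, adjacency, alpha=0.5,
                              min_leaf=1, significance=0.05)
        idx = np.arange(n)
        records = builder.enumerate_candidates(idx)
        assert records, "expected at least one candidate"
        for rec in records:
            vals = cols[rec.attribute].data
            if rec.kind == "continuous":
                fv = vals.astype(float)
                left = ~np.isnan(fv) & (fv <= rec.threshold)
            else:
                left = np.array(
                    [v is not None and str(v) in rec.subset for v in vals]
                )
            right = ~left
            if rec.kind == "continuous":
                right &= ~np.isnan(vals.astype(float))
                right |= np.isnan(vals.astype(float))  # missing sit right
            for mask, n_rec, var_rec, a_rec in (
                (left, rec.n1, rec.var1, rec.a1),
                (right, rec.n2, rec.var2, rec.a2),
            ):
                sub = np.flatnonzero(mask)
                assert n_rec == len(sub)
                assert var_rec == pytest.approx(
                    brute_variance(h.weights, Yf[sub]), rel=1e-9, abs=1e-12
                )
                assert a_rec == pytest.approx(
                    brute_autocorrelation(h.weights, Yf[sub], W[np.ix_(sub, sub)]),
                    rel=1e-9,
                )


class TestMissingValues:
    def test_missing_routes_to_majority_child(self):
        h = ClassHierarchy.from_paths(["A", "B"])
        n = 30
        vals = np.concatenate([np.zeros(8), np.ones(20), [np.nan, np.nan]])
        X = pd.DataFrame({"x1": vals})
        Y = np.vstack([np.tile(h.close(["A"]), (8, 1)),
                       np.tile(h.close(["B"]), (22, 1))]).astype(np.uint8)
        est = NetworkHMCClassifier(alpha=1.0, significance=0.05, min_leaf=2).fit(
            X, Y, hierarchy=h
        )
        root = est.model_.root
        assert root.test.kind == "continuous"
        # the larger (right, x1 > threshold) child got the missing rows
        assert root.test.missing_left is False
        missing_scores = est.predict_proba(pd.DataFrame({"x1": [np.nan]}))
        np.testing.assert_array_equal(missing_scores[0], root.right.prototype)


class TestSerialization:
    def test_save_load_round_trip_is_bit_identical(self, tmp_path):
        cfg = SynthConfig(n=80, depth=2, m_cont=4, m_disc=1, delta=1.5, seed=2)
        h, ds, net = generate(cfg)
        est = _fit(ds, h, net, alpha=0.5)
        path = tmp_path / "model.json"
        est.model_.save(path)
        reloaded = PCTModel.load(path)
        np.testing.assert_array_equal(reloaded.predict(ds.X), est.predict_proba(ds.X))
        # and the serialized document itself is stable
        reloaded.save(tmp_path / "model2.json")
        assert (tmp_path / "model.json").read_bytes() == (tmp_path / "model2.json").read_bytes()

    def test_schema_mismatch_rejected(self):
        cfg = SynthConfig(n=40, depth=1, m_cont=3, seed=0)
        h, ds, net = generate(cfg)
        est = _fit(ds, h, net)
        with pytest.raises(ValueError, match="schema"):
            est.predict_proba(ds.X.rename(columns={"x1": "zz"}))


class TestEstimatorContract:
    def test_sklearn_params_round_trip(self):
        est = NetworkHMCClassifier(alpha=0.25, min_leaf=3)
        params = est.get_params()
        assert params["alpha"] == 0.25
        clone = NetworkHMCClassifier(**params)
        assert clone.get_params() == params
        est.set_params(alpha=0.75)
        assert est.alpha == 0.75

    def test_labels_must_be_ancestor_closed(self):
        h = ClassHierarchy.from_paths(["A", "A/A1"])
        X = pd.DataFrame({"x1": [0.0, 1.0] * 5})
        bad = np.tile([0, 1], (10, 1))  # A1 without A
        with pytest.raises(ValueError, match="ancestor-closed"):
            NetworkHMCClassifier(alpha=1.0).fit(X, bad, hierarchy=h)

    def test_build_tree_wrapper_matches_estimator(self):
        cfg = SynthConfig(n=60, depth=2, m_cont=4, delta=1.5, seed=4)
        h, ds, net = generate(cfg)
        model = build_tree(ds, net, {"alpha": 0.5, "significance": 0.05})
        est = _fit(ds, h, net, alpha=0.5)
        assert model.structure() == est.model_.structure()
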
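import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sespocket.ranking import (
    EvaluatedRow,
    RankItem,
    anomaly_score,
    average_path_length,
    build_training_set,
    eq5_score,
    expand_single_pocket_list,
    fit_iforest,
    load_models,
    save_models,
    score_and_rank,
    subpocket_penalty,
)

EULER = 0.5772156649015329


class TestScoreLaw:
    def test_score_half_when_path_equals_cn(self):
        for n in (16, 256, 1000):
            assert eq5_score(average_path_length(n), n) == pytest.approx(0.5)

    def test_score_tends_to_one_for_short_paths(self):
        assert eq5_score(0.0, 256) == pytest.approx(1.0)

    def test_score_decays_for_long_paths(self):
        assert eq5_score(10 * average_path_length(256), 256) < 0.01

    def test_hand_built_three_leaf_tree(self):
        # a stump over {x1, x2, x3}: x1 isolated at depth 1, x2/x3 at depth 2
        n = 3
        c3 = 2 * (np.log(2) + EULER) - 2 * 2 / 3
        s_deep = 2 ** (-2.0 / c3)      # observation in a depth-2 leaf
        assert eq5_score(2.0, n) == pytest.approx(s_deep)
        assert eq5_score(1.0, n) > eq5_score(2.0, n)

    def test_average_path_length_edge_cases(self):
        assert average_path_length(1) == 0.0
        assert average_path_length(2) == 1.0
        assert average_path_length(100) > average_path_length(10)


def _manual_forest_scores(est, X):
    """Independent re-evaluation of the anomaly score by walking each tree."""
    depths = np.zeros((len(X), len(est.estimators_)))
    for k, dt in enumerate(est.estimators_):
        tree = dt.tree_
        feats = est.estimators_features_[k]
        for i, x in enumerate(np.asarray(X, dtype=np.float32)):
            node, depth = 0, 0
            while tree.children_left[node] != -1:
                f = feats[tree.feature[node]]
                node = (tree.children_left[node]
                        if x[f] <= tree.threshold[node]
                        else tree.children_right[node])
                depth += 1
            depths[i, k] = depth + average_path_length(
                int(tree.n_node_samples[node]))
    n = est.max_samples_
    return 2.0 ** (-depths.mean(axis=1) / average_path_length(n))


class TestForest:
    def test_identical_rows_score_as_inliers(self):
        # exactly identical rows admit no split: paths bottom out at the
        # root and s = 0.5 precisely; any spread pushes an inlier below 0.5
        rows = np.ones((300, 5))
        model = fit_iforest(rows, n_trees=50, seed=1)
        assert anomaly_score(model, np.ones(5)) == pytest.approx(0.5)
        rng = np.random.default_rng(1)
        jittered = rows + rng.normal(scale=1e-6, size=rows.shape)
        model = fit_iforest(jittered, n_trees=50, seed=1)
        assert anomaly_score(model, np.ones(5)) < 0.5

    def test_far_outlier_scores_above_every_inlier(self):
        rng = np.random.default_rng(0)
        inliers = rng.normal(size=(200, 2))
        model = fit_iforest(inliers, n_trees=100, subsample=128, seed=2)
        s_in = anomaly_score(model, inliers)
        s_out = anomaly_score(model, np.array([30.0, -40.0]))
        assert s_out > s_in.max()

    def test_sklearn_engine_agrees_with_manual_path_walk(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(120, 4))
        model = fit_iforest(rows, n_trees=25, subsample=64, seed=4)
        X = np.vstack([rows[:10], [[8, 8, -8, 8]]])
        want = _manual_forest_scores(model.estimator, X)
        got = anomaly_score(model, X)
        assert np.allclose(got, want, atol=1e-8)

    def test_planted_outliers_land_in_worst_decile(self):
        rng = np.random.default_rng(11)
        inliers = rng.normal(size=(950, 8))
        outliers = rng.normal(loc=12.0, size=(50, 8))
        model = fit_iforest(inliers, n_trees=200, subsample=256, seed=5)
        s = anomaly_score(model, np.vstack([inliers, outliers]))
        worst = np.argsort(s)[-100:]            # worst decile of 1000
        recovered = np.intersect1d(worst, np.arange(950, 1000)).size / 50
        assert recovered >= 0.9

    def test_dimension_mismatch_rejected(self):
        model = fit_iforest(np.zeros((10, 3)), n_trees=5, seed=0)
        with pytest.raises(ValueError):
            anomaly_score(model, np.zeros(4))

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_iforest(np.empty((0, 5)))

    def test_scores_stay_in_unit_interval_and_deterministic(self, tmp_path):
        rng = np.random.default_rng(6)
        rows = rng.normal(size=(80, 6))
        model = fit_iforest(rows, n_trees=20, seed=7)
        s = anomaly_score(model, rows)
        assert np.all((s > 0) & (s < 1))
        save_models(tmp_path / "m.joblib", {("geometric", "large"): model})
        back, _ = load_models(tmp_path / "m.joblib")
        s2 = anomaly_score(back[("geometric", "large")], rows)
        assert np.array_equal(s, s2)


def _row(pc, hit=True, is_large=False):
    return EvaluatedRow(geometric=np.full(17, pc), chemical=np.full(22, pc),
                        pc=pc, hit=hit, is_large=is_large)


class TestTrainingSet:
    def test_replication_proportional_to_pc(self):
        ts = build_training_set([_row(1.0)], replication_scale=10)
        assert ts["small"].weights.tolist() == [10]
        assert len(ts["small"].replicated("geometric")) == 10

    def test_floor_guard_at_one_replica(self):
        ts = build_training_set([_row(0.05)], replication_scale=10)
        assert ts["small"].weights.tolist() == [1]

    def test_population_split(self):
        ts = build_training_set([_row(0.5, is_large=True), _row(0.5),
                                 _row(0.9, hit=False)])
        assert len(ts["large"].weights) == 1
        assert len(ts["small"].weights) == 1

    def test_no_hits_is_an_error(self):
        with pytest.raises(ValueError):
            build_training_set([_row(0.5, hit=False)])


def _models(seed=0):
    rng = np.random.default_rng(seed)
    geo = rng.normal(size=(100, 17))
    chem = rng.normal(size=(100, 22))
    out = {}
    for pop in ("large", "small"):
        out[("geometric", pop)] = fit_iforest(geo, "geometric", pop,
                                              n_trees=20, seed=seed)
        out[("chemical", pop)] = fit_iforest(chem, "chemical", pop,
                                             n_trees=20, seed=seed)
    return out


def _item(pid, shift=0.0, volume=1.0, subs=()):
    return RankItem(pocket_id=pid, geometric=np.full(17, shift),
                    chemical=np.full(22, shift), volume=volume,
                    subitems=list(subs))


class TestRanking:
    def test_orders_ascending_in_score(self):
        models = _models()
        scored = score_and_rank([_item(0, shift=0.0), _item(1, shift=25.0)],
                                models)
        assert [p.pocket_id for p in scored] == [0, 1]
        assert scored[0].s < scored[1].s
        assert [p.rank for p in scored] == [1, 2]
        assert all(p.s == pytest.approx((p.s_geo + p.s_chem) / 2) for p in scored)

    def test_subranks_are_internal_to_each_master(self):
        subs = [_item(10 + k, shift=float(k)) for k in range(3)]
        (scored,) = score_and_rank([_item(0, subs=subs)], _models())
        assert [q.subrank for q in scored.subranks] == [1, 2, 3]

    def test_score_ties_break_by_larger_volume(self):
        models = _models()
        scored = score_and_rank([_item(0, volume=5.0), _item(1, volume=50.0)],
                                models)
        assert scored[0].pocket_id == 1   # identical rows, bigger volume first

    def test_missing_model_is_an_error(self):
        models = _models()
        del models[("chemical", "large")]
        with pytest.raises(ValueError):
            score_and_rank([_item(0)], models)


class TestSubpocketPenalty:
    def test_identity_at_rank_one(self):
        assert subpocket_penalty(0.4, 1) == pytest.approx(0.4)

    @given(st.floats(0.01, 0.99))
    @settings(deadline=None, derandomize=True)
    def test_penalty_bounded_and_nonimproving_everywhere(self, s):
        vals = [subpocket_penalty(s, R) for R in range(1, 12)]
        assert vals[0] == pytest.approx(s)
        assert vals == sorted(vals)
        assert all(s - 1e-12 <= v < 1 for v in vals)

    @pytest.mark.parametrize("s", [0.1, 0.4, 0.9])
    def test_nonimproving_in_subrank(self, s):
        vals = [subpocket_penalty(s, R) for R in range(1, 6)]
        assert vals == sorted(vals)
        assert all(0 < v < 1 for v in vals)

    def test_penalty_gap_closes_like_one_over_R(self):
        # independent evaluation of the same law: 1 - s_R = (1 - s)/R
        for s in (0.2, 0.55):
            for R in (1, 2, 5, 9):
                assert 1 - subpocket_penalty(s, R) == pytest.approx((1 - s) / R)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            subpocket_penalty(0.4, 0)
        with pytest.raises(ValueError):
            subpocket_penalty(1.2, 2)


class TestSinglePocketExpansion:
    def test_single_subpocket_inherits_master_score(self):
        subs = [_item(10)]
        ranked = score_and_rank([_item(0, subs=subs), _item(1, shift=9.0)],
                                _models())
        expanded = expand_single_pocket_list(ranked)
        assert len(expanded) == len(ranked)
        master = [p for p in ranked if p.pocket_id == 0][0]
        sub = [p for p in expanded if p.pocket_id == 10][0]
        assert sub.s == pytest.approx(master.s)

    def test_at_most_three_subpockets_inserted(self):
        subs = [_item(10 + k, shift=float(k)) for k in range(4)]
        ranked = score_and_rank([_item(0, subs=subs)], _models())
        expanded = expand_single_pocket_list(ranked)
        assert len(expanded) == 3
        assert {p.pocket_id for p in expanded} <= {10, 11, 12, 13}

    def test_non_masters_pass_through(self):
        ranked = score_and_rank([_item(0), _item(1, shift=4.0)], _models())
        assert expand_single_pocket_list(ranked) == ranked

    def test_minimum_score_never_decreases(self):
        subs = [_item(10 + k, shift=float(k)) for k in range(3)]
        ranked = score_and_rank([_item(0, subs=subs), _item(1, shift=2.0)],
                                _models())
        expanded = expand_single_pocket_list(ranked)
        assert min(p.s for p in expanded) >= min(p.s for p in ranked) - 1e-12
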
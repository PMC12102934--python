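import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actipheno.cffs import (
    CffsParams,
    ScreenParams,
    aggregate_shap,
    build_graph,
    enumerate_cliques,
    filter_models,
    run_cffs,
    screen,
    train_clique,
)
from actipheno.table import FeatureTable

from _oracles import maximal_cliques_bruteforce

import networkx as nx


def toy_table(n=60, seed=0, informative=2, noise=6):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    cols = {}
    for i in range(informative):
        cols[f"inf_{i}"] = y + rng.normal(0, 0.7, n)
    for i in range(noise):
        cols[f"noise_{i}"] = rng.normal(size=n)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return FeatureTable(X, pd.Series(y, index=X.index))


class TestScreen:
    def test_perfectly_separating_feature_kept(self):
        t = toy_table(seed=1)
        t.X["perfect"] = t.y.astype(float)
        kept = screen(t)
        assert "perfect" in kept

    def test_independent_features_rarely_kept(self):
        # pure-noise features should survive at roughly the nominal rate
        rng = np.random.default_rng(2)
        n, k = 50, 300
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"f{i:03d}" for i in range(k)],
                         index=[f"s{i}" for i in range(n)])
        kept = screen(FeatureTable(X, pd.Series(y, index=X.index)))
        assert len(kept) / k <= 0.10

    def test_welch_arm_closed_form(self):
        # x=[1,2,3] vs y=[4,5,6]: |t| = 3.674..., p < 0.05
        t, p = stats.ttest_ind([4.0, 5.0, 6.0], [1.0, 2.0, 3.0], equal_var=False)
        assert abs(t) == pytest.approx(4.5 / np.sqrt(1.5), abs=1e-12)  # 3.6742
        assert p < 0.05

    def test_constant_feature_dropped(self):
        t = toy_table(seed=3)
        t.X["flat"] = 1.0
        assert "flat" not in screen(t)

    def test_cap_keeps_strongest(self):
        t = toy_table(n=80, seed=4, informative=6, noise=0)
        kept = screen(t, ScreenParams(max_features=3))
        assert len(kept) == 3


class TestGraph:
    def test_perfectly_correlated_no_edge(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=100)})
        t = FeatureTable(X, pd.Series([0, 1] * 50, index=X.index))
        g = build_graph(t, ["a", "b", "c"], corr_max=0.4)
        assert not g.has_edge("a", "b")
        assert g.has_edge("a", "c") and g.has_edge("b", "c")

    def test_independent_features_get_edge(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        t = FeatureTable(X, pd.Series([0, 1] * 100, index=X.index))
        assert build_graph(t, ["a", "b"], 0.3).has_edge("a", "b")

    def test_edges_match_hand_computed_matrix(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        X["b"] += 0.8 * X["a"]
        t = FeatureTable(X, pd.Series([0, 1] * 75, index=X.index))
        g = build_graph(t, list("abcd"), 0.3)
        r = np.corrcoef(X.to_numpy(), rowvar=False)
        for i, u in enumerate("abcd"):
            for j, v in enumerate("abcd"):
                if i < j:
                    assert g.has_edge(u, v) == (abs(r[i, j]) <= 0.3)


class TestCliques:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        assert enumerate_cliques(g, 3, 6) == [(0, 1, 2, 3)]

    def test_k4_minus_edge_two_triangles(self):
        g = nx.complete_graph(4)
        g.remove_edge(2, 3)
        assert enumerate_cliques(g, 3, 6) == [(0, 1, 2), (0, 1, 3)]

    def test_edgeless_graph_empty(self):
        g = nx.empty_graph(5)
        assert enumerate_cliques(g, 3, 6) == []

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=int(rng.integers(1e6)))
            ours = enumerate_cliques(g, 3, 6)
            ref = maximal_cliques_bruteforce(g.nodes, g.edges, 3, 6)
            assert ours == ref

    def test_subclique_expansion(self):
        g = nx.complete_graph(4)
        got = enumerate_cliques(g, 3, 6, expand_subcliques=True)
        assert (0, 1, 2, 3) in got and (0, 1, 2) in got and len(got) == 5


class TestTrainAndFilter:
    def test_separable_blobs_perfect_lr(self):
        rng = np.random.default_rng(9)
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "f1": y * 10 + rng.normal(0, 0.5, n),
            "f2": -y * 8 + rng.normal(0, 0.5, n),
        }, index=[f"s{i}" for i in range(n)])
        t = FeatureTable(X, pd.Series(y, index=X.index))
        res = train_clique(t, ("f1", "f2"), "LR", seed=1)
        assert res.cv_accuracy == 1.0

    def test_label_shuffle_null_accuracy(self):
        # accuracy on permuted labels hovers at chance
        rng = np.random.default_rng(10)
        accs = []
        for s in range(40):
            t = toy_table(n=60, seed=100 + s, informative=0, noise=3)
            res = train_clique(t, ("noise_0", "noise_1", "noise_2"), "LR", seed=s)
            accs.append(res.cv_accuracy)
        mean = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < 3 * se + 0.02

    def test_shap_additivity(self):
        t = toy_table(seed=11)
        res = train_clique(t, ("inf_0", "inf_1", "noise_0"), "ANN", seed=2)
        fx = res.model.predict_proba(res.feature_values.to_numpy())[:, 1]
        f0 = res.model.predict_proba(res.background[None, :])[0, 1]
        total = res.shap.sum(axis=1).to_numpy()
        assert total == pytest.approx(list(fx - f0), abs=1e-6)

    @pytest.mark.parametrize("algorithm", ["LR", "RF", "ANN"])
    def test_all_algorithms_train(self, algorithm):
        t = toy_table(seed=12)
        res = train_clique(t, ("inf_0", "inf_1"), algorithm, seed=3, rf_trees=50)
        assert 0.0 <= res.cv_accuracy <= 1.0
        assert res.shap.shape == (60, 2)

    def test_filter_boundary_inclusive(self):
        class R:
            def __init__(self, a):
                self.cv_accuracy = a

        rs = [R(0.55), R(0.60), R(0.71)]
        assert [r.cv_accuracy for r in filter_models(rs)] == [0.60, 0.71]
        assert filter_models([R(0.2), R(0.5)]) == []


class TestAggregate:
    def _result(self, t, clique, seed):
        return train_clique(t, clique, "LR", seed=seed)

    def test_single_model_identity(self):
        t = toy_table(seed=13)
        r = self._result(t, ("inf_0", "noise_0"), 1)
        agg = aggregate_shap([r])
        sub = agg.pooled[agg.pooled["feature"] == "inf_0"]
        assert np.array_equal(sub["shap_value"].to_numpy(), r.shap["inf_0"].to_numpy())

    def test_shared_feature_pools_pairs(self):
        t = toy_table(seed=14)
        r1 = self._result(t, ("inf_0", "noise_0"), 1)
        r2 = self._result(t, ("inf_0", "noise_1"), 2)
        agg = aggregate_shap([r1, r2])
        assert (agg.pooled["feature"] == "inf_0").sum() == 2 * t.n_subjects
        row = agg.ranking[agg.ranking["feature"] == "inf_0"].iloc[0]
        assert row["n_pairs"] == 2 * t.n_subjects

    def test_ranking_sorted_by_mean_abs_shap(self):
        t = toy_table(seed=15)
        agg = aggregate_shap([self._result(t, ("inf_0", "inf_1", "noise_0"), 1)])
        vals = agg.ranking["mean_abs_shap"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-15)


def test_run_cffs_deterministic(tmp_path):
    from actipheno.cffs import write_outputs

    t = toy_table(n=60, seed=16, informative=4, noise=4)
    params = CffsParams(corr_max=0.5, algorithms=("LR", "ANN"), seed=7,
                        screen=ScreenParams(welch_alpha=0.3))
    out = []
    for sub in ("a", "b"):
        res = run_cffs(t, params)
        d = tmp_path / sub
        write_outputs(res, d)
        out.append((d / "ranking.csv").read_bytes())
    assert out[0] == out[1]
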
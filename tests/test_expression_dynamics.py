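import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import pca_loadings_eig
from tscdyn import expression as ex
from tscdyn.core import SampleMeta
from tscdyn.simulate import SimulationConfig, driver_panel, simulate_expression


def toy_counts():
    return pd.DataFrame(
        {"s1": [0, 1, 100], "s2": [0, 50, 200]},
        index=pd.Index(["g0", "g1", "g2"], name="gene_id"),
    )


class TestNormalizeRpm:
    def test_known_values(self):
        counts = pd.DataFrame({"s": [1, 100, 10**6 - 101]}, index=["a", "b", "c"])
        counts.loc["c"] += 0  # library size exactly 1e6
        norm = ex.normalize_rpm(counts)
        assert norm.loc["a", "s"] == pytest.approx(1.0)           # log2(2)
        counts2 = pd.DataFrame({"s": [100, 2 * 10**6 - 100]}, index=["a", "b"])
        norm2 = ex.normalize_rpm(counts2)
        assert norm2.loc["a", "s"] == pytest.approx(np.log2(51), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        norm = ex.normalize_rpm(toy_counts())
        assert norm.loc["g0"].eq(0).all()

    def test_rpm_columns_sum_to_one_million(self):
        norm = ex.normalize_rpm(toy_counts())
        rpm = 2.0 ** norm - 1.0
        np.testing.assert_allclose(rpm.sum(axis=0), 1e6)

    def test_monotone_within_sample(self):
        norm = ex.normalize_rpm(toy_counts())
        assert norm["s1"].is_monotonic_increasing  # counts 0 < 1 < 100

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            ex.normalize_rpm(pd.DataFrame({"s": [0, 0]}))


class TestFilterExpressed:
    def test_strict_threshold(self):
        norm = pd.DataFrame({"s1": [0.0, 1.0, 1.01], "s2": [0.0, 1.0, 0.0]},
                            index=["zero", "boundary", "keep"])
        assert ex.filter_expressed(norm) == ["keep"]

    def test_toy_counting(self):
        norm = pd.DataFrame(
            {"s1": [0.5, 2.0, 0.2, 3.0, 0.9], "s2": [0.7, 0.1, 0.3, 0.2, 1.0]},
            index=list("abcde"),
        )
        assert ex.filter_expressed(norm) == ["b", "d"]


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(rng.normal(size=(12, 4)),
                            index=[f"g{i}" for i in range(12)],
                            columns=[f"s{i}" for i in range(4)])
        res = ex.pca_scores_loadings(norm, n_components=3)
        w, V = pca_loadings_eig(norm.to_numpy().T)
        for j in range(3):
            v = V[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings.iloc[:, j], v, atol=1e-8)
        np.testing.assert_allclose(
            res.explained_variance_ratio, w[:3] / w.sum(), atol=1e-10
        )

    def test_identical_samples_degenerate(self):
        norm = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["a", "b"])
        res = ex.pca_scores_loadings(norm)
        assert (res.scores.to_numpy() == 0).all()
        assert res.explained_variance_ratio.sum() == 0

    def test_rank_one_data_explained_fully_by_pc1(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        norm = pd.DataFrame(np.outer([1.0, -2.0, 0.5], t) + 5.0,
                            index=["a", "b", "c"], columns=list("wxyz"))
        res = ex.pca_scores_loadings(norm)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_too_many_components_rejected(self):
        norm = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["a"])
        with pytest.raises(ValueError, match="components"):
            ex.pca_scores_loadings(norm, n_components=3)


class TestTopLoadingSelection:
    def test_counts_without_ties(self):
        loadings = pd.DataFrame({"PC1": np.linspace(0.01, 1.0, 100)},
                                index=[f"g{i}" for i in range(100)])
        sel = ex.select_top_loading_genes(loadings, 0.05, components=("PC1",))
        assert len(sel) == 5
        assert set(sel) == {f"g{i}" for i in range(95, 100)}

    def test_total_tie_returns_all(self):
        loadings = pd.DataFrame({"PC1": [0.5] * 20}, index=[f"g{i}" for i in range(20)])
        assert len(ex.select_top_loading_genes(loadings, 0.05, ("PC1",))) == 20

    def test_invalid_fraction_rejected(self):
        loadings = pd.DataFrame({"PC1": [0.5]}, index=["g"])
        with pytest.raises(ValueError, match="fraction"):
            ex.select_top_loading_genes(loadings, 0.0)

    def test_driver_tfs_dominate_selection(self, default_sim):
        cfg, m, _ = default_sim
        nf = m.subset_samples(s.sample_id for s in m.samples_where(condition="NF"))
        norm = nf.norm
        pca = ex.pca_scores_loadings(norm.loc[ex.filter_expressed(norm)])
        sel = set(ex.select_top_loading_genes(pca.loadings))
        drivers = set(driver_panel(cfg))
        assert len(drivers & sel) / len(drivers) >= 0.9


def nf_meta(n_reps=2):
    from tscdyn.core import STAGE_ORDER

    return [
        SampleMeta(f"NF_{st}_{r}", "NF", st, r)
        for st in STAGE_ORDER
        for r in range(1, n_reps + 1)
    ]


class TestClusterTrends:
    def test_two_profiles_separate_and_trends_label(self):
        samples = nf_meta()
        up = [0.0, 1.0, 2.0, 3.0, 4.0]
        down = [4.0, 3.0, 2.0, 1.0, 0.0]
        data = {}
        for s in samples:
            i = ["TE3.5", "TE4.5", "outgrowth", "TSC_P1", "TSC_Pn"].index(s.stage)
            data[s.sample_id] = [up[i]] * 3 + [down[i]] * 3
        norm = pd.DataFrame(data, index=[f"u{i}" for i in range(3)] + [f"d{i}" for i in range(3)])
        assign = ex.cluster_trend_genes(norm, samples, list(norm.index), k=2)
        labels = assign.labels
        assert labels["u0"] == labels["u1"] == labels["u2"]
        assert labels["d0"] == labels["d1"] == labels["d2"]
        assert assign.trends[labels["u0"]] == "Pro"
        assert assign.trends[labels["d0"]] == "Down"

    def test_k_larger_than_genes_rejected(self):
        samples = nf_meta()
        norm = pd.DataFrame({s.sample_id: [1.0] for s in samples}, index=["g"])
        with pytest.raises(ValueError, match="k="):
            ex.cluster_trend_genes(norm, samples, ["g"], k=2)

    def test_planted_six_clusters_recovered(self, default_sim):
        cfg, m, truth = default_sim
        nf = m.subset_samples(s.sample_id for s in m.samples_where(condition="NF"))
        planted = truth.expression.loc[truth.expression["cluster"] > 0]
        assign = ex.cluster_trend_genes(nf.norm, nf.samples, list(planted.index), k=6)
        ari = adjusted_rand_score(planted["cluster"], assign.labels.loc[planted.index])
        assert ari >= 0.9
        # Pro/Down/Transient composition matches the planted design
        trends = pd.Series(
            [assign.trends[c] for c in assign.labels], index=assign.labels.index
        )
        planted_trend = planted["trend"]
        assert (trends == planted_trend).mean() >= 0.9


class TestCallDegs:
    def test_identical_groups_give_no_degs(self):
        counts = pd.DataFrame(
            {"a1": [10, 20], "a2": [12, 18], "b1": [10, 20], "b2": [12, 18]},
            index=["g1", "g2"],
        )
        tab = ex.call_degs(counts, ["a1", "a2"], ["b1", "b2"])
        assert not tab["significant"].any()

    def test_supplied_stat_table_threshold_semantics(self):
        stat = pd.DataFrame(
            {
                "p": [1e-6, 1e-6, 0.5, 1e-6, 0.02, 1e-6],
                "lfc": [3.0, -4.0, 3.0, 1.0, 2.5, 2.01],
            },
            index=[f"g{i}" for i in range(6)],
        )
        counts = pd.DataFrame(index=stat.index)
        tab = ex.call_degs(counts, [], [], stat_table=stat)
        assert set(tab.index[tab["significant"]]) == {"g0", "g1", "g5"}
        assert tab.loc["g1", "direction"] == "down"

    def test_direction_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        t1 = ex.call_degs(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        t2 = ex.call_degs(counts, ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        np.testing.assert_allclose(t1["lfc"], -t2["lfc"], atol=1e-12)
        both = (t1["direction"] != "none") & (t2["direction"] != "none")
        assert (t1.loc[both, "direction"] != t2.loc[both, "direction"]).all()

    def test_planted_upshift_called_up(self):
        # 8-fold shift, 5 replicates, low dispersion
        rng = np.random.default_rng(9)
        base = rng.poisson(200, size=(50, 10)).astype(float)
        counts = pd.DataFrame(
            base, index=[f"g{i}" for i in range(50)],
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        ).astype(int)
        counts.loc["g0", [f"a{i}" for i in range(5)]] *= 8
        tab = ex.call_degs(counts, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)])
        assert tab.loc["g0", "significant"]
        assert tab.loc["g0", "direction"] == "up"

    def test_unreplicated_group_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]}, index=["g"])
        with pytest.raises(ValueError, match="external stat_table"):
            ex.call_degs(counts, ["a1"], ["b1", "b2"])
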
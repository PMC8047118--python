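import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from oracles import fisher_two_sided
from tscdyn import methylation as me
from tscdyn.core import STAGE_ORDER, GenomicInterval, MethylationCallSet, TSSRecord


def calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])


def callset(sample_id, rows):
    return MethylationCallSet(sample_id, calls(rows))


class TestRetainCpgs:
    def test_low_coverage_in_one_replicate_drops_cpg(self):
        r1 = callset("r1", [("chr1", 10, 2, 4)])     # coverage 4: below >4 rule
        r2 = callset("r2", [("chr1", 10, 3, 9)])
        pooled = me.retain_cpgs([r1, r2], "s")
        assert len(pooled) == 0

    def test_qualifying_replicates_pooled(self):
        r1 = callset("r1", [("chr1", 10, 1, 5)])
        r2 = callset("r2", [("chr1", 10, 3, 7)])
        pooled = me.retain_cpgs([r1, r2], "s")
        assert pooled.calls.iloc[0].tolist() == ["chr1", 10, 4, 12]

    def test_empty_input(self):
        assert len(me.retain_cpgs([callset("r1", [])], "s")) == 0

    def test_any_mode_keeps_single_qualifier(self):
        r1 = callset("r1", [("chr1", 10, 2, 4)])
        r2 = callset("r2", [("chr1", 10, 3, 9)])
        pooled = me.retain_cpgs([r1, r2], "s", mode="any")
        assert pooled.calls.iloc[0].tolist() == ["chr1", 10, 3, 9]

    @given(st.integers(min_value=1, max_value=12))
    @settings(max_examples=10, deadline=None)
    def test_raising_min_cov_is_monotone(self, min_cov):
        rng = np.random.default_rng(0)
        reps = []
        for r in range(3):
            cov = rng.integers(1, 15, size=30)
            m = rng.integers(0, cov + 1)
            reps.append(callset(f"r{r}", list(zip(["chr1"] * 30, range(30), m, cov))))
        low = me.retain_cpgs(reps, "s", min_cov=min_cov)
        high = me.retain_cpgs(reps, "s", min_cov=min_cov + 1)
        assert set(map(tuple, high.calls[["chrom", "pos"]].values)) <= set(
            map(tuple, low.calls[["chrom", "pos"]].values)
        )


class TestCgiMethylation:
    CGIS = [GenomicInterval("chr1", 0, 100, "cgiA")]

    def test_ratio_is_mean_of_cpg_ratios_not_pooled(self):
        # ratios 0.2, 0.4, 0.6 with unequal coverage: mean 0.4, pooled differs
        cs = callset("s", [("chr1", 1, 2, 10), ("chr1", 2, 20, 50), ("chr1", 3, 3, 5)])
        mat = me.cgi_methylation({"s": cs}, self.CGIS, min_detected=3)
        assert mat.ratio.at["cgiA", "s"] == pytest.approx(0.4)
        assert mat.pooled_meth.at["cgiA", "s"] / mat.pooled_total.at["cgiA", "s"] != pytest.approx(0.4)

    def test_all_zero_cpgs_give_zero_ratio(self):
        cs = callset("s", [("chr1", i, 0, 10) for i in range(5)])
        mat = me.cgi_methylation({"s": cs}, self.CGIS)
        assert mat.ratio.at["cgiA", "s"] == 0.0

    def test_under_detected_cgi_dropped(self):
        cs = callset("s", [("chr1", i, 1, 10) for i in range(4)])
        mat = me.cgi_methylation({"s": cs}, self.CGIS, min_detected=5)
        assert mat.cgi_names == []

    def test_strict_mode_requires_every_sample(self):
        full = callset("s1", [("chr1", i, 1, 10) for i in range(5)])
        sparse = callset("s2", [("chr1", i, 1, 10) for i in range(3)])
        strict = me.cgi_methylation({"s1": full, "s2": sparse}, self.CGIS)
        any_mode = me.cgi_methylation({"s1": full, "s2": sparse}, self.CGIS, mode="any")
        assert strict.cgi_names == []
        assert any_mode.cgi_names == ["cgiA"]


class TestDifferentialCgis:
    def test_identical_counts_not_called(self):
        mat = make_matrix({"c1": [0.3, 0.3]}, ["a", "b"])
        tab = me.differential_cgis(mat, "a", "b")
        assert not tab["called"].any()
        assert tab.loc["c1", "p"] == pytest.approx(1.0)

    def test_strong_difference_called_and_p_matches_enumeration(self):
        from tscdyn.core import GenomicInterval
        from tscdyn.methylation import CGIMethylationMatrix

        cgis = [GenomicInterval("chr1", 0, 10, "c1")]
        ratio = pd.DataFrame({"a": [0.75], "b": [0.05]}, index=["c1"])
        meth = pd.DataFrame({"a": [30], "b": [2]}, index=["c1"])
        total = pd.DataFrame({"a": [40], "b": [40]}, index=["c1"])
        det = pd.DataFrame({"a": [5], "b": [5]}, index=["c1"])
        mat = CGIMethylationMatrix(cgis, ratio, meth, total, det)
        tab = me.differential_cgis(mat, "a", "b")
        assert tab.loc["c1", "called"]
        assert tab.loc["c1", "p"] == pytest.approx(fisher_two_sided(30, 10, 2, 38), abs=1e-10)

    def test_underpowered_small_counts_not_called(self):
        # delta 0.33 on 3 reads per side: Fisher cannot reach 0.05
        p = me.fisher_exact_pooled(1, 3, 0, 3)
        assert p == pytest.approx(fisher_two_sided(1, 2, 0, 3), abs=1e-12)
        assert p > 0.05


class TestDetectPhim:
    def stage_cols(self):
        return [f"NF_{s}" for s in STAGE_ORDER]

    def test_flat_cgi_not_phim(self):
        mat = make_matrix({"flat": [0.05] * 5}, self.stage_cols())
        rep = me.detect_phim(mat, self.stage_cols(), k=1)
        assert rep.phim_cgis == []

    def test_hand_adjacent_jump(self):
        mat = make_matrix({"jump": [0.05, 0.05, 0.6, 0.6, 0.6]}, self.stage_cols())
        rep = me.detect_phim(mat, self.stage_cols(), k=1)
        assert rep.phim_cgis == ["jump"]
        assert rep.table.loc["jump", "d2"] == pytest.approx(0.55)

    def test_noise_free_sensitivity_and_specificity(self):
        # jump 0.30 must be called at delta 0.25; jump 0.20 must not
        ratios = {f"hit{i}": [0.05, 0.05, 0.35, 0.35, 0.35] for i in range(10)}
        ratios |= {f"null{i}": [0.05, 0.05, 0.25, 0.25, 0.25] for i in range(10)}
        mat = make_matrix(ratios, self.stage_cols())
        rep = me.detect_phim(mat, self.stage_cols(), k=1)
        assert set(rep.phim_cgis) == {f"hit{i}" for i in range(10)}

    def test_global_mode_catches_gradual_rise(self):
        mat = make_matrix({"grad": [0.05, 0.15, 0.25, 0.35, 0.45]}, self.stage_cols())
        adj = me.detect_phim(mat, self.stage_cols(), k=1, mode="adjacent")
        glob = me.detect_phim(mat, self.stage_cols(), k=1, mode="global")
        assert adj.phim_cgis == [] and glob.phim_cgis == ["grad"]

    def test_k_exceeding_phim_count_rejected(self):
        mat = make_matrix({"jump": [0.05, 0.05, 0.6, 0.6, 0.6]}, self.stage_cols())
        with pytest.raises(ValueError, match="k="):
            me.detect_phim(mat, self.stage_cols(), k=5)

    def test_planted_groups_recovered(self, meth_pipeline):
        from sklearn.metrics import adjusted_rand_score

        cfg, sim, matrix = meth_pipeline
        rep = me.detect_phim(matrix, self.stage_cols(), seed=0)
        truth = sim.truth.loc[matrix.cgi_names]
        both = truth.index[(truth["category"] == "phim") & rep.table["is_phim"]]
        ari = adjusted_rand_score(truth.loc[both, "phim_group"], rep.table.loc[both, "group"])
        assert ari >= 0.9


class TestClassifyHighAndAberrant:
    def test_high_threshold_is_strict(self):
        mat = make_matrix({"a": [0.25], "b": [0.26]}, ["s"])
        high = me.classify_high(mat)
        assert high["s"] == {"b"}

    def test_hand_ahm_alm_statuses(self):
        mat = make_matrix(
            {"x": [0.70, 0.10], "y": [0.10, 0.70], "z": [0.30, 0.30]},
            ["NT_TE3.5", "NF_TE3.5"],
        )
        rep = me.detect_aberrant(mat, {"TE3.5": "NT_TE3.5"}, {"TE3.5": "NF_TE3.5"})
        assert rep.loc["x", "TE3.5"] == "AHM"
        assert rep.loc["y", "TE3.5"] == "ALM"
        assert rep.loc["z", "TE3.5"] == "normal"

    def test_swap_is_antisymmetric(self):
        rng = np.random.default_rng(1)
        ratios = {f"c{i}": [rng.uniform(), rng.uniform()] for i in range(50)}
        mat = make_matrix(ratios, ["t", "r"])
        fwd = me.detect_aberrant(mat, {"TE3.5": "t"}, {"TE3.5": "r"})
        rev = me.detect_aberrant(mat, {"TE3.5": "r"}, {"TE3.5": "t"})
        swap = {"AHM": "ALM", "ALM": "AHM", "normal": "normal"}
        assert (fwd["TE3.5"].map(swap) == rev["TE3.5"]).all()


class TestRescueAndOrigin:
    def report(self, statuses):
        return pd.DataFrame({"TE3.5": statuses}, index=[f"c{i}" for i in range(len(statuses))])

    def test_empty_snt_all_corrected(self):
        nt = self.report(["AHM", "AHM", "normal"])
        snt = self.report(["normal", "normal", "normal"])
        acc = me.rescue_accounting(nt, snt, "TE3.5")
        assert acc == {"n_NT": 2, "n_corrected": 2, "n_uncorrected": 0, "n_SNT": 0, "n_shared": 0}

    def test_identical_reports_nothing_corrected(self):
        nt = self.report(["AHM", "AHM", "normal"])
        acc = me.rescue_accounting(nt, nt.copy(), "TE3.5")
        assert acc["n_corrected"] == 0 and acc["n_uncorrected"] == 2

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_partition_identity_always_holds(self, flags):
        nt = self.report(["AHM" if a else "normal" for a, _ in flags])
        snt = self.report(["AHM" if b else "normal" for _, b in flags])
        acc = me.rescue_accounting(nt, snt, "TE3.5")
        assert acc["n_corrected"] + acc["n_uncorrected"] == acc["n_NT"]

    def test_origin_empty_donor_all_de_novo(self):
        rep = self.report(["AHM", "AHM"])
        res = me.donor_origin(rep, "TE3.5", set(), list(rep.index))
        assert (res["labels"] == "de_novo").all()
        assert res["inherited_fraction"] == 0.0

    def test_origin_full_subset_fraction_one(self):
        rep = self.report(["AHM", "AHM", "normal"])
        res = me.donor_origin(rep, "TE3.5", {"c0", "c1", "c2"}, list(rep.index))
        assert res["inherited_fraction"] == 1.0


class TestDensityAndPromoters:
    def test_empty_window_zero(self):
        assert me.cpg_density([], 500) == 0.0

    def test_center_cpg_weight_one(self):
        assert me.cpg_density([500], 500) == 1.0

    def test_hand_linear_weights(self):
        # distances 0, 75, 150 with window 300: weights 1, 0.5, 0
        assert me.cpg_density([500, 575, 650], 500) == pytest.approx(1.5)

    def test_membership_matches_uniform_count_oracle(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 1000, size=200)
        center = 500
        inside = np.abs(pos - center) <= 150
        assert me.cpg_density(pos, center, weighting="uniform") == inside.sum()
        # linear weight never exceeds membership count
        assert me.cpg_density(pos, center) <= inside.sum()

    def test_promoter_classes(self):
        tss = [TSSRecord(g, "chr1", p) for g, p in [("lcp", 10_000), ("icp", 20_000), ("hcp", 30_000)]]
        cpgs = {"chr1": [20_000, 20_010, 30_000, 30_005, 30_010, 30_015, 30_020]}
        tab = me.classify_promoters(tss, cpgs, lo=1.0, hi=4.0)
        assert tab.loc["lcp", "class"] == "LCP"
        assert tab.loc["icp", "class"] == "ICP"
        assert tab.loc["hcp", "class"] == "HCP"
        assert tab.loc["lcp", "density"] == 0.0


class TestAssociateCgiGene:
    CGI = [GenomicInterval("chr1", 10_000, 10_500, "cgi")]

    def test_tss_inside_distance_zero(self):
        recs = [TSSRecord("g", "chr1", 10_200)]
        tab = me.associate_cgi_gene(self.CGI, recs)
        assert tab.loc["cgi", "gene_id"] == "g" and tab.loc["cgi", "distance"] == 0

    def test_boundary_5001_excluded(self):
        recs = [TSSRecord("far", "chr1", 10_500 - 1 + 5001)]
        assert me.associate_cgi_gene(self.CGI, recs).empty
        recs2 = [TSSRecord("edge", "chr1", 10_500 - 1 + 5000)]
        tab = me.associate_cgi_gene(self.CGI, recs2)
        assert tab.loc["cgi", "distance"] == 5000

    def test_closest_gene_wins(self):
        recs = [TSSRecord("near", "chr1", 10_000 - 100), TSSRecord("far", "chr1", 10_000 - 4000)]
        tab = me.associate_cgi_gene(self.CGI, recs)
        assert tab.loc["cgi", "gene_id"] == "near"
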
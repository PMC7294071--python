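import io

import numpy as np
import pandas as pd
import pytest

from afdsim.cohort import CohortSpec, generate_cohort, table1_matrix
from afdsim.devstats import (BCaInterval, bonferroni_alpha, cluster_matrix,
                             column_median, export_dendrogram_newick,
                             r2_difference_bca, r2_matrix, r2_table, tract_r2)


def small_cohort(seed=0, schemes=("ss_6000", "ss_1200"), r2=(0.4, 0.1),
                 tracts=("T0",)):
    target = pd.DataFrame([list(r2)] * len(tracts), columns=list(schemes),
                          index=list(tracts))
    return generate_cohort(CohortSpec(schemes=schemes, target_r2=target,
                                      seed=seed))


class TestTractR2:
    def test_exact_linear_relation_gives_r2_one(self):
        coh = small_cohort(seed=1)
        coh = coh[(coh.tract == "T0") & (coh.scheme == "ss_6000")].copy()
        coh["afd"] = 0.3 + 0.01 * coh["age"]
        res = tract_r2(coh, "T0", "ss_6000")
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.p_age < 1e-100

    def test_affine_rescaling_leaves_r2_unchanged(self):
        coh = small_cohort(seed=2)
        a = tract_r2(coh, "T0", "ss_6000")
        coh2 = coh.copy()
        coh2["afd"] = coh2["afd"] * 3.7 + 1.2
        b = tract_r2(coh2, "T0", "ss_6000")
        assert abs(a.r2 - b.r2) < 1e-12

    def test_fast_matrix_matches_statsmodels(self, default_cohort):
        fast = r2_matrix(default_cohort, fast=True)
        slow = r2_matrix(default_cohort.query(
            "tract in ['AF_L', 'CG_L'] and scheme in ['ss_6000', 'ss_1200']"),
            fast=False)
        for tract in slow.index:
            for scheme in slow.columns:
                assert fast.loc[tract, scheme] == pytest.approx(
                    slow.loc[tract, scheme], abs=1e-12)

    def test_collinear_design_raises(self):
        coh = small_cohort(seed=3)
        coh = coh[(coh.tract == "T0") & (coh.scheme == "ss_6000")].copy()
        coh["motion"] = 2.0 * coh["age"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            tract_r2(coh, "T0", "ss_6000")

    def test_too_few_subjects_rejected(self):
        coh = small_cohort(seed=4)
        sub = coh[coh.subject_id.isin(coh.subject_id.unique()[:5])]
        with pytest.raises(ValueError, match="10"):
            tract_r2(sub, "T0", "ss_6000")


class TestBCa:
    def test_identical_schemes_give_degenerate_zero_interval(self):
        coh = small_cohort(seed=5)
        b = r2_difference_bca(coh, "T0", "ss_6000", "ss_6000", B=1000,
                              seed=0)
        assert b.estimate == 0.0 and b.lo == 0.0 and b.hi == 0.0

    def test_interval_brackets_estimate_for_separated_schemes(self):
        coh = small_cohort(seed=6, r2=(0.6, 0.05))
        b = r2_difference_bca(coh, "T0", "ss_6000", "ss_1200", B=2000,
                              seed=1)
        assert b.lo <= b.estimate <= b.hi
        assert b.lo > 0  # strongly separated planted effects

    def test_matches_scipy_bca_oracle(self):
        """Independent cross-check against scipy.stats.bootstrap (BCa)
        on the same paired statistic."""
        from scipy.stats import bootstrap

        coh = small_cohort(seed=7, r2=(0.5, 0.2))
        ours = r2_difference_bca(coh, "T0", "ss_6000", "ss_1200", B=4000,
                                 seed=2)
        a = coh[coh.scheme == "ss_6000"].sort_values("subject_id")
        b = coh[coh.scheme == "ss_1200"].sort_values("subject_id")
        x = np.column_stack([np.ones(len(a)), a.age, a.sex, a.motion])
        ya, yb = a.afd.to_numpy(), b.afd.to_numpy()

        def r2(x_, y_):
            beta, *_ = np.linalg.lstsq(x_, y_, rcond=None)
            res = y_ - x_ @ beta
            return 1 - res @ res / np.sum((y_ - y_.mean()) ** 2)

        def stat(idx):
            idx = np.asarray(idx, dtype=int)
            return r2(x[idx], ya[idx]) - r2(x[idx], yb[idx])

        res = bootstrap((np.arange(len(a)),), stat, method="BCa",
                        n_resamples=4000, vectorized=False,
                        rng=np.random.default_rng(3))
        assert ours.lo == pytest.approx(res.confidence_interval.low,
                                        abs=0.03)
        assert ours.hi == pytest.approx(res.confidence_interval.high,
                                        abs=0.03)

    def test_mismatched_subject_sets_rejected(self):
        coh = small_cohort(seed=8)
        drop = coh[~((coh.scheme == "ss_1200")
                     & (coh.subject_id == "sub-001"))]
        with pytest.raises(ValueError):
            r2_difference_bca(drop, "T0", "ss_6000", "ss_1200", B=100,
                              seed=0)


class TestBonferroni:
    @pytest.mark.parametrize("tracts,schemes,alpha,expected", [
        (38, 4, 0.05, 0.05 / 152),
        (1, 1, 0.05, 0.05),
        (10, 1, 0.05, 0.005),
    ])
    def test_threshold(self, tracts, schemes, alpha, expected):
        assert bonferroni_alpha(tracts, schemes, alpha) == pytest.approx(
            expected, rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0, 4)


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        mat = pd.DataFrame([[0.1, 0.2], [0.1, 0.2], [0.8, 0.9]],
                           index=["a", "b", "c"], columns=["s1", "s2"])
        cl = cluster_matrix(mat)
        assert cl.row_linkage[0, 2] == pytest.approx(0.0)
        cut = cl.cut_rows(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_planted_two_block_rows_recovered(self, rng):
        noise_sd = 0.01
        block = np.r_[np.zeros(10) + 0.2, np.zeros(10) + 0.2 + 10 * noise_sd]
        data = block[:, None] + rng.normal(0, noise_sd, size=(20, 4))
        mat = pd.DataFrame(data, index=[f"t{i}" for i in range(20)],
                           columns=list("wxyz"))
        cut = cluster_matrix(mat).cut_rows(2)
        labels = np.array([cut[f"t{i}"] for i in range(20)])
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_complete_linkage_heights_monotone(self, rng):
        from scipy.cluster.hierarchy import linkage
        for seed in range(100):
            r = np.random.default_rng(seed)
            link = linkage(r.normal(size=(12, 5)), method="complete")
            assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_missing_entries_rejected(self):
        mat = pd.DataFrame([[0.1, np.nan]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError):
            cluster_matrix(mat)

    def test_single_row_trivial(self):
        mat = pd.DataFrame([[0.1, 0.2]], index=["a"], columns=["x", "y"])
        cl = cluster_matrix(mat)
        assert cl.row_order == ("a",)


class TestColumnMedian:
    def test_even_count_convention(self):
        mat = pd.DataFrame({"s": [0.1, 0.2, 0.3, 0.4]})
        assert column_median(mat, "s") == pytest.approx(0.25)

    def test_constant_column(self):
        mat = pd.DataFrame({"s": [0.7] * 5})
        assert column_median(mat, "s") == pytest.approx(0.7)

    def test_missing_column(self):
        with pytest.raises(KeyError):
            column_median(pd.DataFrame({"s": [0.1]}), "t")


class TestNewick:
    def test_two_leaf_convention(self):
        mat = pd.DataFrame([[0.0], [1.0]], index=["A", "B"], columns=["x"])
        cl = cluster_matrix(mat)
        nwk = export_dendrogram_newick(cl.row_linkage, ["A", "B"])
        assert nwk in ("(A:0.5,B:0.5);", "(B:0.5,A:0.5);")

    def test_round_trip_topology_and_heights(self, rng):
        import skbio

        mat = pd.DataFrame(rng.normal(size=(10, 4)),
                           index=[f"L{i}" for i in range(10)])
        cl = cluster_matrix(mat)
        nwk = export_dendrogram_newick(cl.row_linkage, list(mat.index))
        tree = skbio.TreeNode.read(io.StringIO(nwk), convert_underscores=False)
        assert {t.name for t in tree.tips()} == set(mat.index)
        # path lengths between leaves reproduce cophenetic distances
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform
        coph = squareform(cophenet(cl.row_linkage))
        names = list(mat.index)
        for i in range(0, 10, 3):
            for j in range(1, 10, 4):
                if i == j:
                    continue
                d = tree.find(names[i]).distance(tree.find(names[j]))
                assert d == pytest.approx(coph[i, j], abs=1e-9)

    def test_reference_matrix_consistency(self):
        """The 4-leaf scheme dendrogram's first split agrees with the
        k=2 cut of the clustering."""
        mat = table1_matrix()
        cl = cluster_matrix(mat)
        nwk = export_dendrogram_newick(cl.col_linkage, list(mat.columns))
        cut = cl.cut_cols(2)
        import skbio
        tree = skbio.TreeNode.read(io.StringIO(nwk), convert_underscores=False)
        kids = tree.children
        groups = [{t.name for t in k.tips()} or {k.name} for k in kids]
        expected = [{s for s, g in cut.items() if g == v}
                    for v in sorted(set(cut.values()))]
        assert groups[0] in expected and groups[1] in expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            export_dendrogram_newick(np.zeros((2, 4)), ["a", "b"])
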
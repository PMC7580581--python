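import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import furscent as fs
from furscent.io import FingerprintError
from furscent.permanova import Term

from conftest import euclidean_dm


def _random_instance(seed, n=12, n_groups=3):
    rng = np.random.default_rng(seed)
    vals = rng.random((n, 10)) + 0.05
    mat = fs.AbundanceMatrix([f"s{i}" for i in range(n)],
                             [f"c{j}" for j in range(10)], vals, "log_relative")
    groups = rng.integers(0, n_groups, n).astype(str)
    while len(np.unique(groups)) < 2:
        groups = rng.integers(0, n_groups, n).astype(str)
    return fs.bray_curtis(mat), groups


class TestPermanova:
    def test_four_point_hand_instance(self, four_point_line):
        dm, groups, meta = four_point_line
        F, r2 = fs.permanova_oneway_oracle(dm, groups)
        assert F == pytest.approx(200.0, abs=1e-10)
        assert r2 == pytest.approx(100 / 101, abs=1e-12)
        model = fs.ModelSpec((Term("colony", "colony"),), permutations=0)
        tab = fs.permanova(dm, meta, model)
        assert tab["Total"]["SS"] == pytest.approx(101.0, abs=1e-9)
        assert tab["colony"]["SS"] == pytest.approx(100.0, abs=1e-9)
        assert tab["colony"]["F"] == pytest.approx(200.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed):
        dm, groups = _random_instance(seed)
        F_oracle, r2_oracle = fs.permanova_oneway_oracle(dm, groups)
        meta = fs.SampleMetadata(pd.DataFrame({"sample_id": dm.sample_ids,
                                               "colony": groups}))
        tab = fs.permanova(dm, meta, fs.ModelSpec((Term("colony", "colony"),),
                                                  permutations=0))
        assert tab["colony"]["F"] == pytest.approx(F_oracle, rel=1e-8)
        assert tab["colony"]["R2"] == pytest.approx(r2_oracle, rel=1e-8)

    def test_exhaustive_p_on_four_points(self, four_point_line):
        """4! permutations: 8 of 24 preserve the two-group split or swap it."""
        dm, groups, meta = four_point_line
        model = fs.ModelSpec((Term("colony", "colony"),), permutations=10 ** 6)
        tab = fs.permanova(dm, meta, model)
        assert tab["colony"]["p"] == pytest.approx(8 / 24)

    def test_nested_model_ss_conservation(self, bc_distance, preprocessed):
        model = fs.ModelSpec.from_formula(
            "age_class + colony + family_id %in% colony", permutations=0)
        tab = fs.permanova(bc_distance, preprocessed.metadata, model)
        t = tab.table
        terms = t[~t["term"].isin(["Residual", "Total"])]
        total = float(t[t["term"] == "Total"]["SS"].iloc[0])
        resid = float(t[t["term"] == "Residual"]["SS"].iloc[0])
        assert terms["SS"].sum() + resid == pytest.approx(total, rel=1e-8)
        assert terms["R2"].sum() + resid / total == pytest.approx(1.0, rel=1e-8)
        assert terms["df"].sum() + t[t["term"] == "Residual"]["df"].iloc[0] \
            == bc_distance.n - 1

    def test_nested_df_families_minus_colonies(self, bc_distance, preprocessed):
        model = fs.ModelSpec.from_formula("colony + family_id %in% colony",
                                          permutations=0)
        tab = fs.permanova(bc_distance, preprocessed.metadata, model)
        n_fam = preprocessed.metadata.table["family_id"].nunique()
        assert tab["family_id (in colony)"]["df"] == n_fam - 2

    def test_equivariance_under_joint_permutation(self, bc_distance, preprocessed):
        model = fs.ModelSpec.from_formula("colony", permutations=0)
        tab = fs.permanova(bc_distance, preprocessed.metadata, model)
        rng = np.random.default_rng(6)
        perm = rng.permutation(bc_distance.n)
        dm2 = bc_distance.subset(perm)
        meta2 = fs.SampleMetadata(preprocessed.metadata.table.iloc[perm])
        tab2 = fs.permanova(dm2, meta2, model)
        assert tab2["colony"]["F"] == pytest.approx(tab["colony"]["F"], rel=1e-10)
        assert tab2["colony"]["R2"] == pytest.approx(tab["colony"]["R2"], rel=1e-10)

    def test_nested_before_parent_rejected(self):
        with pytest.raises(FingerprintError, match="before its parent"):
            fs.ModelSpec((Term("family", "family_id", nested_in="colony"),
                          Term("colony", "colony")))

    def test_misaligned_metadata_rejected(self, four_point_line):
        dm, _, meta = four_point_line
        bad = fs.SampleMetadata(meta.table.iloc[::-1])
        with pytest.raises(FingerprintError, match="row-aligned"):
            fs.permanova(dm, bad, fs.ModelSpec((Term("colony", "colony"),),
                                               permutations=0))


class TestPermutationPvalue:
    def test_forced_values(self):
        assert fs.permutation_pvalue(100.0, np.arange(99)) == pytest.approx(1 / 100)
        assert fs.permutation_pvalue(-1.0, np.arange(99)) == 1.0
        # ties count toward the numerator
        assert fs.permutation_pvalue(5.0, np.array([5.0, 1.0, 2.0])) \
            == pytest.approx(2 / 4)


class TestBetadisper:
    def test_euclidean_matches_direct(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(10, 3)), 3 * rng.normal(size=(10, 3))])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = fs.betadisper(euclidean_dm(X), groups)
        direct = np.concatenate([
            np.linalg.norm(X[:10] - X[:10].mean(axis=0), axis=1),
            np.linalg.norm(X[10:] - X[10:].mean(axis=0), axis=1)])
        np.testing.assert_allclose(res.distances, direct, atol=1e-8)
        assert res.n_clamped == 0
        F_direct, p_direct = stats.f_oneway(direct[:10], direct[10:])
        assert res.F == pytest.approx(F_direct, rel=1e-8)
        assert res.p == pytest.approx(p_direct, rel=1e-6)

    def test_mirror_groups_null(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 2))
        X = np.vstack([A, A + 100.0])  # identical internal geometry
        groups = np.array(["a"] * 8 + ["b"] * 8)
        res = fs.betadisper(euclidean_dm(X), groups)
        assert res.F == pytest.approx(0.0, abs=1e-8)
        assert res.p > 0.99

    def test_clamping_counted_on_bray_curtis(self, bc_distance, preprocessed):
        res = fs.betadisper(bc_distance, preprocessed.metadata.column("colony"))
        assert np.all(res.distances >= 0)
        assert res.n_clamped >= 0
        assert res.df == (1, bc_distance.n - 2)

    def test_singleton_group_rejected(self):
        X = np.random.default_rng(2).normal(size=(5, 2))
        with pytest.raises(FingerprintError, match="fewer than 2 samples"):
            fs.betadisper(euclidean_dm(X), np.array(["a", "a", "a", "a", "b"]))

    def test_permutation_mode(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(10, 2)), 3 * rng.normal(size=(10, 2))])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = fs.betadisper(euclidean_dm(X), groups, p_mode="permutation",
                            permutations=199, seed=0)
        assert res.p <= 0.05


class TestPairwise:
    def test_six_levels_fifteen_pairs(self):
        ds = fs.generate_dataset(fs.study_design_config("six_colony", seed=4))
        pre = fs.preprocess_pipeline(ds)
        dm = fs.bray_curtis(pre.matrix)
        res = fs.pairwise_permanova(dm, pre.metadata, "colony",
                                    permutations=49, seed=0)
        assert res.n_pairs == math.comb(6, 2) == 15
        np.testing.assert_allclose(
            res.table["p_bonferroni"],
            np.minimum(1.0, res.table["p"] * 15), atol=1e-12)

    def test_two_levels_no_correction(self, bc_distance, preprocessed):
        res = fs.pairwise_permanova(bc_distance, preprocessed.metadata, "colony",
                                    permutations=49, seed=0)
        assert res.n_pairs == 1
        assert res.table["p_bonferroni"].iloc[0] == res.table["p"].iloc[0]

    def test_composite_grouping_four_levels(self, bc_distance, preprocessed):
        res = fs.pairwise_permanova(bc_distance, preprocessed.metadata,
                                    ["colony", "age_class"], permutations=19, seed=0)
        assert res.n_pairs == math.comb(4, 2) == 6


class TestCompareCounts:
    def test_hand_worked_t(self):
        t, p = fs.compare_counts(np.array([1, 2, 3, 4, 5, 6]),
                                 np.array(["a"] * 3 + ["b"] * 3), "t_test")
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_identical_groups(self):
        t, p = fs.compare_counts(np.array([1.0, 2, 3, 1, 2, 3]),
                                 np.array(["a"] * 3 + ["b"] * 3), "t_test")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_anova_equals_t_squared(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(20, 70, 30).astype(float)
        groups = np.array(["m"] * 15 + ["p"] * 15)
        t, _ = fs.compare_counts(counts, groups, "t_test")
        F, _ = fs.compare_counts(counts, groups, "anova")
        assert F == pytest.approx(t ** 2, rel=1e-9)

    def test_t_needs_two_groups(self):
        with pytest.raises(FingerprintError):
            fs.compare_counts(np.arange(9.0), np.array(["a", "b", "c"] * 3), "t_test")
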
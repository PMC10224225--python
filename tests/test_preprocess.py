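"""Transforms, filters, diversity and distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutlink import preprocess as pp
from gutlink.containers import CountTable, OmicsMatrix, ValidationError


def table(values, prefix="f"):
    arr = np.asarray(values, dtype=float)
    return CountTable(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])]))


class TestFeatureFilter:
    def test_prevalence_boundary_is_strict(self):
        # present in 19/100 samples -> dropped; exactly 20/100 -> retained
        m = np.zeros((100, 2))
        m[:19, 0] = 5
        m[:20, 1] = 5
        m[:, 1] += 0  # keep abundances comfortably above the floor
        t = table(m + np.tile([[0, 0]], (100, 1)))
        # add a common feature so relative abundances are defined everywhere
        data = t.data.copy()
        data["base"] = 100.0
        filtered = pp.filter_features(CountTable(data), 0.20, 0.0)
        assert "f0" not in filtered.feature_ids
        assert "f1" in filtered.feature_ids

    def test_toy_table_matches_exhaustive_rule(self):
        # 10 samples, hand-set prevalences/abundances; survivors enumerated
        # by applying both rules feature by feature
        data = pd.DataFrame(0.0, index=[f"s{i}" for i in range(10)],
                            columns=["a", "b", "c", "base"])
        data["base"] = 1.0
        data.loc["s0", "a"] = 0.01          # prevalence 0.1 -> fails
        data.loc[["s0", "s1"], "b"] = 1e-5  # prevalence 0.2, tiny abundance
        data.loc[["s0", "s1", "s2", "s3", "s4"], "c"] = 0.01  # passes both
        t = CountTable(data)
        rel = t.relative_abundance()
        expected = [f for f in data.columns
                    if (data[f] > 0).mean() >= 0.2 and rel[f].mean() >= 1e-5]
        got = pp.filter_features(t, 0.20, 1e-5).feature_ids
        assert got == expected
        assert "a" not in got and "c" in got

    def test_idempotent(self, small_cohort):
        once = pp.filter_features(small_cohort["species"])
        twice = pp.filter_features(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_empty_survivors_warns_not_raises(self):
        t = table([[1, 1], [1, 1]])
        with pytest.warns(UserWarning):
            out = pp.filter_features(t, min_prevalence=1.0,
                                     min_mean_relative_abundance=1.0)
        assert out.n_features == 0


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        out = pp.clr_transform(table([[1, 1, 1, 1]]))
        assert np.allclose(out.data.to_numpy(), 0.0)

    def test_hand_computed_values(self):
        out = pp.clr_transform(table([[1, 2, 4]]))
        expected = np.log([1, 2, 4]) - np.mean(np.log([1, 2, 4]))
        assert np.allclose(out.data.to_numpy()[0], expected, atol=1e-12)
        assert np.allclose(out.data.to_numpy()[0],
                           [-0.69314718, 0.0, 0.69314718], atol=1e-6)

    def test_scale_invariance_and_zero_row_sum(self, small_cohort):
        t = pp.filter_features(small_cohort["species"])
        a = pp.clr_transform(t).data.to_numpy()
        scaled = CountTable(t.data * 7.5)
        b = pp.clr_transform(scaled).data.to_numpy()
        assert np.allclose(a, b, atol=1e-9)
        assert np.abs(a.sum(axis=1)).max() < 1e-9

    def test_all_zero_row_names_sample(self):
        data = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "bad"],
                            columns=["a", "b"])
        with pytest.raises(ValidationError, match="bad"):
            pp.clr_transform(CountTable(data))


class TestInverseNormal:
    def test_middle_of_three_is_zero(self):
        out = pp.int_transform(pd.DataFrame({"x": [5.0, 1.0, 9.0]}))
        assert abs(out.data["x"].iloc[0]) < 1e-12

    def test_antisymmetry(self, rng):
        x = rng.normal(size=31)
        a = pp.int_transform(pd.DataFrame({"x": x})).data["x"].to_numpy()
        b = pp.int_transform(pd.DataFrame({"x": -x})).data["x"].to_numpy()
        assert np.allclose(a, -b, atol=1e-12)

    def test_largest_of_five_matches_normal_quantile_oracle(self):
        out = pp.int_transform(pd.DataFrame({"x": [3.0, 1.0, 4.0, 1.5, 9.0]}))
        expected = stats.norm.ppf((5 - 0.375) / (5 - 0.75 + 1))
        assert abs(out.data["x"].iloc[-1] - expected) < 1e-12
        assert abs(out.data["x"].iloc[-1] - stats.norm.ppf(0.880952380952)) < 1e-9

    def test_large_sample_mean_and_variance(self, rng):
        x = rng.normal(size=1000)
        out = pp.int_transform(pd.DataFrame({"x": x})).data["x"]
        assert abs(out.mean()) < 1e-9
        assert 0.9 < out.var() < 1.1

    def test_constant_column_names_feature(self):
        with pytest.raises(ValidationError, match="flat"):
            pp.int_transform(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestQCAndImputation:
    def test_protein_detection_boundary(self):
        # detected in exactly 75% -> dropped (rule keeps strictly > 75%)
        m = pd.DataFrame({"p75": [1.0] * 75 + [np.nan] * 25,
                          "p76": [1.0] * 76 + [np.nan] * 24})
        out = pp.qc_filter(OmicsMatrix(m, scale_tag="NPX_log2"), "protein")
        assert list(out.data.columns) == ["p76"]

    def test_metabolite_grid_matches_rule(self, rng):
        cols = {}
        expected = []
        for i, (cv, miss) in enumerate([(0.1, 0.0), (0.1, 0.25), (0.5, 0.0),
                                        (0.29, 0.1), (0.31, 0.1)]):
            base = 10.0
            x = rng.normal(base, cv * base, 200)
            n_miss = int(miss * 200)
            if n_miss:
                x[:n_miss] = np.nan
            cols[f"m{i}"] = x
            obs = x[~np.isnan(x)]
            if (np.std(obs, ddof=1) / np.mean(obs) < 0.30) and (n_miss / 200 < 0.20):
                expected.append(f"m{i}")
        out = pp.qc_filter(OmicsMatrix(pd.DataFrame(cols)), "metabolite")
        assert list(out.data.columns) == expected

    def test_half_min_imputation(self):
        m = pd.DataFrame({"a": [2.0, np.nan, 6.0], "b": [0.4, np.nan, np.nan]})
        out = pp.impute_half_min(OmicsMatrix(m))
        assert out.data["a"].tolist() == [2.0, 1.0, 6.0]
        assert out.data["b"].tolist() == [0.4, 0.2, 0.2]
        full = pd.DataFrame({"a": [1.0, 2.0]})
        assert pp.impute_half_min(OmicsMatrix(full)).data.equals(full)

    def test_all_missing_feature_is_an_error(self):
        with pytest.raises(ValidationError, match="gone"):
            pp.impute_half_min(OmicsMatrix(pd.DataFrame({"gone": [np.nan, np.nan]})))


class TestAlphaDiversity:
    def test_closed_forms(self):
        t = table([[10, 10, 10, 10]])
        assert abs(pp.alpha_diversity(t, "shannon").iloc[0] - np.log(4)) < 1e-12
        assert abs(pp.alpha_diversity(t, "simpson").iloc[0] - 0.75) < 1e-12
        single = table([[7, 0, 0]])
        assert pp.alpha_diversity(single, "shannon").iloc[0] == 0.0
        assert pp.alpha_diversity(single, "simpson").iloc[0] == 0.0

    def test_chao1_hand_formula(self):
        # counts (5,1,1,2): S_obs=4, F1=2, F2=1 -> 4 + 4/2 = 6
        assert pp.alpha_diversity(table([[5, 1, 1, 2]]), "chao1").iloc[0] == 6.0
        # F2 = 0 falls back to the bias-corrected form
        t = table([[3, 1, 1, 0]])
        assert pp.alpha_diversity(t, "chao1").iloc[0] == 3 + 2 * 1 / 2.0

    def test_chao1_rejects_non_integer(self):
        with pytest.raises(ValidationError):
            pp.alpha_diversity(table([[1.5, 2.0]]), "chao1")

    def test_matches_skbio_oracle(self, rng):
        from skbio.diversity.alpha import chao1, shannon, simpson
        counts = rng.integers(0, 50, size=(5, 12))
        t = table(counts)
        for i in range(5):
            assert np.isclose(pp.alpha_diversity(t, "shannon").iloc[i],
                              shannon(counts[i], base=np.e))
            assert np.isclose(pp.alpha_diversity(t, "simpson").iloc[i],
                              simpson(counts[i]))
            assert np.isclose(pp.alpha_diversity(t, "chao1").iloc[i],
                              chao1(counts[i], bias_corrected=False))


TREE3 = "((A:1.0,B:2.0):0.5,C:1.0);"


class TestDistances:
    def test_identical_and_disjoint_samples(self):
        data = pd.DataFrame([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
                            index=["u", "u2", "v"], columns=["A", "B", "C"])
        t = CountTable(data)
        d = pp.distance_matrix(t, "weighted_unifrac", tree=TREE3)
        assert d.loc["u", "u2"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["u", "v"] == pytest.approx(1.0, abs=1e-12)

    def test_three_leaf_hand_computation(self):
        # u=(.5,.5,0), v=(.25,.25,.5); branch-by-branch:
        #   A(1.0): |.5-.25| = .25 ; B(2.0): .25*2 = .5
        #   AB(0.5): |1-.5|*.5 = .25 ; C(1.0): .5
        #   num = 1.5 ; den = .75 + 1.5 + .75 + .5 = 3.5 -> 3/7
        data = pd.DataFrame([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]],
                            index=["u", "v"], columns=["A", "B", "C"])
        d = pp.distance_matrix(CountTable(data), "weighted_unifrac", tree=TREE3)
        assert d.loc["u", "v"] == pytest.approx(3 / 7, abs=1e-12)

    def test_matches_skbio_weighted_unifrac(self, rng):
        import skbio
        from skbio.diversity.beta import weighted_unifrac
        counts = rng.integers(0, 30, size=(4, 3)) + 1
        data = pd.DataFrame(counts, index=list("wxyz"), columns=["A", "B", "C"])
        t = CountTable(data)
        d = pp.distance_matrix(t, "weighted_unifrac", tree=TREE3)
        tree = skbio.TreeNode.read([TREE3])
        for i, j in [(0, 1), (0, 3), (2, 3)]:
            ref = weighted_unifrac(counts[i], counts[j], ["A", "B", "C"],
                                   tree, normalized=True)
            assert d.iloc[i, j] == pytest.approx(float(ref), abs=1e-10)

    def test_metric_properties_small_random(self, rng):
        counts = rng.integers(1, 40, size=(6, 5))
        t = table(counts, prefix="L")
        from gutlink.synthetic import generate_tree
        tree = generate_tree(t.feature_ids, seed=5)
        for method, kw in [("bray_curtis", {}), ("weighted_unifrac", {"tree": tree})]:
            D = pp.distance_matrix(t, method, **kw).to_numpy()
            assert np.allclose(D, D.T, atol=1e-12)
            assert np.allclose(np.diag(D), 0.0, atol=1e-12)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_missing_leaf_error(self):
        data = pd.DataFrame([[1.0, 1.0]], index=["s"], columns=["A", "Z"])
        with pytest.raises(ValidationError, match="Z"):
            pp.distance_matrix(CountTable(data), "weighted_unifrac", tree=TREE3)
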
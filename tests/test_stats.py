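"""Permutation statistics: PERMANOVA, Holm, pairwise tests, PCA, LDA, Tukey."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporescope import stats as S
from sporescope.errors import ValidationError


def permanova_oracle_one_way(dist, labels):
    """Classic one-way PERMANOVA from pairwise distances (group-sum form).

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = per-group analogue;
    F = (SS_among/(a-1)) / (SS_within/(n-a)).  Independent of the
    projection-matrix route used by the implementation.
    """
    labels = np.asarray(labels)
    n = len(labels)
    d2 = dist ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(np.unique(labels))
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return ss_among, ss_within, ss_total, f


class TestEuclideanDistances:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [2.0, 2.0, 5.0]})
        d = S.euclidean_distances(df, ["x", "y"], standardize=False)
        assert d[0, 1] == 0.0

    def test_three_four_five(self):
        df = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]})
        d = S.euclidean_distances(df, ["x", "y"], standardize=False)
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        d = S.euclidean_distances(df, ["a", "b", "c"], standardize=False)
        X = df.to_numpy()
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12)

    def test_constant_trait_with_standardize_raises(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="x"):
            S.euclidean_distances(df, ["x", "y"], standardize=True)


class TestPermanova:
    def _random_table(self, seed, n=12, groups=3):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["t1", "t2", "t3"])
        df["g"] = [f"g{i % groups}" for i in range(n)]
        return df

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_group_sum_oracle(self, seed):
        df = self._random_table(seed)
        d = S.euclidean_distances(df, ["t1", "t2", "t3"], standardize=False)
        res = S.permanova(d, df, ["g"], n_perm=9, seed=0)
        ss_a, ss_w, ss_t, f = permanova_oracle_one_way(d, df["g"])
        assert res.table.loc["g", "SS"] == pytest.approx(ss_a, abs=1e-8)
        assert res.table.loc["Residual", "SS"] == pytest.approx(ss_w, abs=1e-8)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f, abs=1e-8)
        assert res.table.loc["g", "R2"] == pytest.approx(ss_a / ss_t, abs=1e-8)

    def test_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        df = self._random_table(7)
        d = S.euclidean_distances(df, ["t1", "t2", "t3"], standardize=False)
        ours = S.permanova(d, df, ["g"], n_perm=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d), df["g"].tolist(), permutations=99)
        assert ours.table.loc["g", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], abs=1e-10)

    def test_exact_enumeration_agreement(self):
        # n = 6, two groups of 3: 720 row permutations enumerable exactly
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"t": rng.normal(size=6),
                           "g": ["a"] * 3 + ["b"] * 3})
        d = S.euclidean_distances(df, ["t"], standardize=False)
        f_obs = S.permanova(d, df, ["g"], n_perm=1, seed=0).table.loc[
            "g", "pseudo_F"]
        exceed = total = 0
        for perm in itertools.permutations(range(6)):
            dp = d[np.ix_(perm, perm)]
            *_, f = permanova_oracle_one_way(dp, df["g"])
            total += 1
            exceed += f >= f_obs - 1e-12
        p_exact = exceed / total
        res = S.permanova(d, df, ["g"], n_perm=9999, seed=3)
        p_mc = res.table.loc["g", "p_perm"]
        se = np.sqrt(p_exact * (1 - p_exact) / 9999)
        assert abs(p_mc - p_exact) < max(4 * se, 0.01)

    def test_strong_effect_floors_p(self):
        df = pd.DataFrame({
            "t": [0.0, 0.1, -0.1, 100.0, 100.1, 99.9],
            "g": ["a"] * 3 + ["b"] * 3,
        })
        d = S.euclidean_distances(df, ["t"], standardize=False)
        res = S.permanova(d, df, ["g"], n_perm=999, seed=1)
        assert res.table.loc["g", "R2"] > 0.9
        # permutation floor with the (1+b)/(1+B) estimator
        assert res.table.loc["g", "p_perm"] <= 0.1  # exchange symmetry: 3!3!/6! * C
        assert res.table.loc["g", "p_perm"] >= 1 / 1000

    def test_sequential_terms_partition_variance(self, nested_table):
        table, _ = nested_table
        traits = list(table.columns[4:])
        d = S.euclidean_distances(table, traits)
        res = S.permanova(d, table, ["site", "host_ploidy", "individual"],
                          n_perm=49, seed=0)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0)
        assert res.table.loc["Total", "SS"] == pytest.approx(
            res.table["SS"].drop("Total").sum())

    def test_strata_restricted_permutation_runs(self, nested_table):
        table, _ = nested_table
        traits = list(table.columns[4:])
        d = S.euclidean_distances(table, traits)
        res = S.permanova(d, table, ["individual"], n_perm=49, seed=0,
                          strata="site")
        assert 0 < res.table.loc["individual", "p_perm"] <= 1

    def test_single_level_term_raises(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        d = S.euclidean_distances(df, ["t"], standardize=False)
        with pytest.raises(ValidationError):
            S.permanova(d, df, ["g"], n_perm=9, seed=0)

    def test_zero_permutations_raises(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0], "g": list("abab")})
        d = S.euclidean_distances(df, ["t"], standardize=False)
        with pytest.raises(ValidationError):
            S.permanova(d, df, ["g"], n_perm=0, seed=0)

    def test_seed_determinism(self):
        df = self._random_table(5)
        d = S.euclidean_distances(df, ["t1", "t2", "t3"], standardize=False)
        a = S.permanova(d, df, ["g"], n_perm=199, seed=42)
        b = S.permanova(d, df, ["g"], n_perm=199, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestHolm:
    def test_hand_worked_triple(self):
        adj = S.holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_and_capped(self):
        assert S.holm_adjust([0.2]) == pytest.approx([0.2])
        assert S.holm_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            S.holm_adjust([0.5, 1.2])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    def test_dominance_and_monotonicity(self, pvals):
        adj = S.holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_adjusted_significance_subset_of_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=8)
            adj = S.holm_adjust(p)
            assert set(np.flatnonzero(adj < 0.05)) <= set(
                np.flatnonzero(p < 0.05))


class TestPairwisePermutation:
    def test_identical_groups_large_p(self):
        # both levels hold the same values: centroid distance is zero and
        # no permutation can fall below it
        rng = np.random.default_rng(2)
        vals = rng.normal(size=20)
        df = pd.DataFrame({"t": np.concatenate([vals, vals]),
                           "g": ["a"] * 20 + ["b"] * 20})
        res = S.pairwise_permutation_tests(df, ["t"], "g", n_perm=1000, seed=0)
        assert len(res) == 1
        assert res[0].p_raw >= 0.5
        assert res[0].p_holm == res[0].p_raw  # single pair: m = 1

    def test_separated_groups_small_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "t": np.concatenate([rng.normal(0, 1, 15),
                                 rng.normal(20, 1, 15)]),
            "g": ["a"] * 15 + ["b"] * 15,
        })
        res = S.pairwise_permutation_tests(df, ["t"], "g", n_perm=999, seed=0)
        assert res[0].p_raw == pytest.approx(1 / 1000)

    def test_all_pairs_reported_and_holm_applied(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"t": rng.normal(size=30),
                           "u": rng.normal(size=30),
                           "g": (["a"] * 10 + ["b"] * 10 + ["c"] * 10)})
        res = S.pairwise_permutation_tests(df, ["t", "u"], "g",
                                           n_perm=199, seed=0)
        assert len(res) == 3
        raw = [r.p_raw for r in res]
        assert [r.p_holm for r in res] == pytest.approx(
            list(S.holm_adjust(raw)))

    def test_small_level_skipped_with_warning(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "g": ["a", "a", "b", "b", "c"]})
        with pytest.warns(UserWarning, match="skipped"):
            res = S.pairwise_permutation_tests(df, ["t"], "g",
                                               n_perm=99, seed=0,
                                               standardize=False)
        assert {(r.group_a, r.group_b) for r in res} == {("a", "b")}


class TestPca:
    def test_collinear_data_rank_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({"x": x, "y": 2 * x})
        res = S.pca(df, ["x", "y"])
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_even_split(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["x", "y"])
        res = S.pca(df, ["x", "y"])
        assert res.variance_fraction[0] == pytest.approx(0.5, abs=0.05)
        assert res.variance_fraction[1] == pytest.approx(0.5, abs=0.05)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = S.pca(df, list("abcd"), scale_unit_variance=False)
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        assert np.allclose(res.scores @ res.loadings.T, X, atol=1e-10)

    def test_loadings_orthonormal_and_fractions_sorted(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = S.pca(df, list("abcde"))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5),
                           atol=1e-10)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)
        assert res.cumulative_fraction[-1] == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        r1, r2 = S.pca(df, list("abc")), S.pca(df, list("abc"))
        assert np.array_equal(r1.loadings, r2.loadings)
        for j in range(3):
            col = r1.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_column_raises(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            S.pca(df, ["x", "y"])


class TestLdaLoocv:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame({
            "x": np.concatenate([rng.normal(0, 0.3, 10),
                                 rng.normal(10, 0.3, 10)]),
            "y": rng.normal(size=20),
            "g": ["a"] * 10 + ["b"] * 10,
        })
        res = S.lda_loocv(df, ["x", "y"], "g")
        assert res.accuracy == 1.0
        assert res.kappa == pytest.approx(1.0)

    def test_kappa_hand_computed(self):
        # confusion [[3,1],[1,3]]: po = 0.75, pe = 0.5 -> kappa = 0.5
        conf = np.array([[3, 1], [1, 3]])
        assert S.cohen_kappa(conf) == pytest.approx(0.5)
        assert np.trace(conf) / conf.sum() == 0.75

    def test_structureless_labels_kappa_near_zero(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({
            "x": rng.normal(size=200), "y": rng.normal(size=200),
            "g": rng.permutation(["a", "b"] * 100),
        })
        res = S.lda_loocv(df, ["x", "y"], "g")
        assert abs(res.kappa) < 0.15

    def test_matches_sklearn_predictions(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(32)
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(1.5, 1, (15, 3))])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["g"] = ["p"] * 15 + ["q"] * 15
        ours = S._FisherLda().fit(X, df["g"].to_numpy())
        theirs = sklearn_da.LinearDiscriminantAnalysis(
            priors=[0.5, 0.5]).fit(X, df["g"])
        assert np.array_equal(ours.predict(X), theirs.predict(X))

    def test_singleton_group_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]})
        with pytest.raises(ValidationError):
            S.lda_loocv(df, ["x"], "g")

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.lists(st.integers(min_value=0, max_value=50),
                             min_size=3, max_size=3),
                    min_size=3, max_size=3))
    def test_kappa_bounds_fuzz(self, rows):
        conf = np.array(rows)
        if conf.sum() == 0:
            return
        k = S.cohen_kappa(conf)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12


class TestAnovaTukey:
    def test_identical_groups_share_letter(self):
        res = S.anova_tukey([5.0] * 9, ["a", "b", "c"] * 3)
        assert res.f_statistic == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_strongly_offset_groups_distinct_letters(self):
        rng = np.random.default_rng(40)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        res = S.anova_tukey(values, ["a"] * 10 + ["b"] * 10)
        assert set(res.letters["a"]) != set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["b"])

    def test_matches_statsmodels_tukey_p(self):
        sm_multi = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(41)
        values = np.concatenate([rng.normal(m, 1, 8) for m in (0, 0.8, 2.5)])
        groups = np.repeat(["a", "b", "c"], 8)
        ours = S.anova_tukey(values, groups)
        theirs = sm_multi.pairwise_tukeyhsd(values, groups)
        for (g1, g2, p_sm) in zip(theirs._results_table.data[1:],
                                  [None] * 3, [None] * 3):
            pass  # table parsing below
        sm_p = theirs.pvalues
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        for (g1, g2), p_sm in zip(pairs, sm_p):
            assert ours.pairwise_p.loc[g1, g2] == pytest.approx(p_sm, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_letters_consistent_with_significance_graph(self, seed):
        # oracle: groups share a letter iff NOT significantly different
        rng = np.random.default_rng(seed)
        k = 4
        values = np.concatenate(
            [rng.normal(m, 1, 8) for m in rng.uniform(0, 4, k)])
        groups = np.repeat([f"g{i}" for i in range(k)], 8)
        res = S.anova_tukey(values, groups)
        for i in range(k):
            for j in range(i + 1, k):
                gi, gj = f"g{i}", f"g{j}"
                share = bool(set(res.letters[gi]) & set(res.letters[gj]))
                significant = res.pairwise_p.loc[gi, gj] < res.alpha
                assert share != significant

    def test_zero_variance_unequal_means(self):
        res = S.anova_tukey([1.0, 1.0, 5.0, 5.0], ["a", "a", "b", "b"])
        assert res.p_value == 0.0  # documented p floor
        assert not set(res.letters["a"]) & set(res.letters["b"])


class TestGrowthRate:
    @pytest.mark.parametrize("series, expected", [
        ([(0, 5), (24, 29)], 1.0),
        ([(0, 7), (8, 7), (16, 7)], 0.0),
        ([(0, 3.0), (24, 43.56)], 1.69),
    ])
    def test_known_rates(self, series, expected):
        assert S.growth_rate(series).gr_mm_per_day == pytest.approx(expected)

    def test_intermediate_points_ignored(self):
        assert S.growth_rate([(0, 5), (8, 20), (16, 22), (24, 29)]
                             ).gr_mm_per_day == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValidationError):
            S.growth_rate([(0, 5)])
        with pytest.raises(ValidationError):
            S.growth_rate([(0, 5), (0, 6)])
        with pytest.raises(ValidationError):
            S.growth_rate([(8, 5), (0, 6)])
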
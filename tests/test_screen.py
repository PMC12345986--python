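"""Weight-group screening: binning, ANOVA/Tukey, trends, correlations,
clustering, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swinegrowth import (
    InsufficientDataError,
    assign_weight_groups,
    classify_trend,
    correlation_matrix,
    dressing_percentage,
    group_test,
    hierarchical_cluster,
    pca,
)


class TestAssignWeightGroups:
    def test_group_one_contains_published_group_mean(self):
        # lean-breed bins start at 80 kg; 84.93 kg (group-1 mean) -> group 1
        assert assign_weight_groups([84.93], start_kg=80.0)[0] == 1

    def test_boundaries_are_half_open(self):
        groups = assign_weight_groups([80.0, 90.0, 89.999], start_kg=80.0)
        assert list(groups) == [1, 2, 1]

    def test_uniform_draw_fills_every_group(self):
        rng = np.random.default_rng(0)
        bw = rng.uniform(80.0, 160.0, size=257)
        groups = assign_weight_groups(bw, start_kg=80.0)
        assert set(groups) == set(range(1, 9))

    def test_out_of_range_flagged_unassigned(self):
        with pytest.warns(UserWarning, match="unassigned"):
            groups = assign_weight_groups([70.0, 85.0, 200.0], start_kg=80.0)
        assert list(groups) == [-1, 1, -1]


class TestDressingPercentage:
    @pytest.mark.parametrize("cw, bw, expected", [(75, 100, 75.0), (50, 100, 50.0)])
    def test_direct_formula(self, cw, bw, expected):
        assert dressing_percentage(cw, bw) == pytest.approx(expected)

    def test_carcass_heavier_than_body_rejected(self):
        with pytest.raises(ValueError):
            dressing_percentage(101, 100)

    def test_generated_dp_recovers_programmed_mean(self):
        rng = np.random.default_rng(1)
        bw = rng.uniform(90, 150, 400)
        cw = bw * 0.72 * (1 + 0.01 * rng.standard_normal(400))
        dp = dressing_percentage(cw, bw)
        assert np.mean(dp) == pytest.approx(72.0, abs=3 * 100 * 0.72 * 0.01 / 20)


class TestGroupTest:
    def test_hand_worked_three_group_anova(self):
        # groups (2,3,4), (4,5,6), (8,9,10): means 3, 5, 9; grand mean 17/3.
        # SSB = 3*[(3-17/3)^2 + (5-17/3)^2 + (9-17/3)^2] = 3*168/9 = 56,
        # SSW = 2 + 2 + 2 = 6; F = (56/2)/(6/6) = 28, p = sf(28; 2, 6).
        res = group_test([(2, 3, 4), (4, 5, 6), (8, 9, 10)])
        assert res.statistic == pytest.approx(28.0, rel=1e-12)
        assert res.p_value == pytest.approx(9.0631e-4, rel=1e-4)
        assert res.method == "anova"

    def test_tukey_separates_distant_group(self):
        res = group_test({"a": (2, 3, 4), "b": (4, 5, 6), "c": (8, 9, 10)})
        tk = res.tukey.set_index(["group1", "group2"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.05

    def test_degenerate_constant_groups_flagged(self):
        res = group_test([(5, 5, 5), (5, 5), (5, 5, 5)])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_two_groups_fall_back_to_t_test(self):
        res = group_test([(1.0, 2.0, 3.0), (4.0, 5.0, 6.0)])
        t, p = stats.ttest_ind([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.method == "t-test"
        assert res.p_value == pytest.approx(p)

    def test_small_groups_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = group_test({"a": (1, 2, 3), "b": (9,), "c": (2, 3, 4), "d": (5, 6)})
        assert res.n_groups_used == 3
        assert res.excluded_groups == ("b",)

    def test_null_p_values_uniform(self):
        # 8 groups of n=10 under the null; KS check on 1000 replicate p-values
        rng = np.random.default_rng(42)
        x = rng.standard_normal((8, 10, 1000))
        _, p = stats.f_oneway(*x, axis=0)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestClassifyTrend:
    def _groups(self, bw):
        return assign_weight_groups(bw, start_kg=80.0)

    def test_identity_trait_is_up_with_unit_correlation(self):
        bw = np.linspace(81, 159, 80)
        res = classify_trend(bw, bw, self._groups(bw))
        assert res.direction == "up"
        assert res.bw_correlation == pytest.approx(1.0)

    def test_negated_trait_with_small_noise_is_down(self):
        rng = np.random.default_rng(2)
        bw = np.linspace(81, 159, 80)
        y = -bw + 0.1 * rng.standard_normal(80)
        assert classify_trend(y, bw, self._groups(bw)).direction == "down"

    def test_constant_trait_flagged_unchanged(self):
        bw = np.linspace(81, 159, 80)
        res = classify_trend(np.ones(80), bw, self._groups(bw))
        assert res.direction == "unchanged"
        assert res.zero_variance

    def test_direction_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(3)
        bw = np.linspace(81, 159, 80)
        y = 0.2 * bw + rng.standard_normal(80)
        g = self._groups(bw)
        d1 = classify_trend(y, bw, g).direction
        d2 = classify_trend(1000 + 3.7 * y, bw, g).direction
        assert d1 == d2 == "up"

    def test_recovers_programmed_directions(self, slaughter_tables):
        # every programmed up/down trait must come back with the right sign;
        # flat traits are allowed the nominal alpha false-positive rate
        traits, truth = slaughter_tables
        for breed, start in (("YP", 80.0), ("QYP", 60.0)):
            sub = traits[traits.breed == breed]
            groups = assign_weight_groups(sub.bw.to_numpy(), start)
            expected = truth[truth.breed == breed].set_index("trait")["direction"]
            for trait, want in expected.items():
                if want == "unchanged":
                    continue
                got = classify_trend(
                    sub[trait].to_numpy(), sub.bw.to_numpy(), groups
                ).direction
                assert got == want, f"{breed}/{trait}: {got} != {want}"


class TestCorrelationMatrix:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        m = correlation_matrix(df)
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        m = correlation_matrix(df)
        for i in df.columns:
            for j in df.columns:
                x, y = df[i].to_numpy(), df[j].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
                assert m.loc[i, j] == pytest.approx(r, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, slaughter_tables):
        traits, _ = slaughter_tables
        m = correlation_matrix(traits[traits.breed == "YP"].drop(columns=["animal_id", "breed"]))
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.nanmax(np.abs(m.values)) <= 1.0 + 1e-12

    def test_constant_column_flagged_not_zeroed(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            m = correlation_matrix(df)
        assert np.isnan(m.loc["a", "b"])

    def test_programmed_block_structure_recovered(self, slaughter_tables):
        # body weight, carcass weight and backfat/IMF all rise with weight in
        # the fat breed -> strong positive within-block correlations, while
        # flat meat-colour traits stay uncorrelated with the weight block
        traits, _ = slaughter_tables
        sub = traits[traits.breed == "QYP"]
        block = ["bw", "CW", "backfat1", "IMF", "marbling"]
        flat = ["L1", "a1", "b1"]
        m = correlation_matrix(sub[block + flat])
        within = [m.loc[i, j] for i in block for j in block if i != j]
        cross = [abs(m.loc[i, j]) for i in block for j in flat]
        assert np.mean(within) > 0.5
        assert np.mean(cross) < 0.3


class TestHierarchicalCluster:
    def test_identical_items_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        res = hierarchical_cluster(df)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2]) == {0.0, 1.0}

    def test_first_merge_is_closest_pair_on_a_line(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 10.0]})
        res = hierarchical_cluster(df)
        assert set(res.linkage[0, :2]) == {0.0, 1.0}

    def test_non_finite_entries_rejected(self):
        df = pd.DataFrame({"x": [0.0, np.nan], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            hierarchical_cluster(df)

    def test_group_means_cluster_by_weight_adjacency(self, slaughter_tables):
        # smooth programmed trends make adjacent weight groups the nearest
        # neighbours: the first merge joins two adjacent group indices
        traits, _ = slaughter_tables
        sub = traits[traits.breed == "YP"]
        groups = assign_weight_groups(sub.bw.to_numpy(), 80.0)
        means = (
            sub.select_dtypes(include=[np.number])
            .assign(weight_group=groups)
            .groupby("weight_group")
            .mean()
        )
        res = hierarchical_cluster(means, zscore=True)
        i, j = int(res.linkage[0, 0]), int(res.linkage[0, 1])
        assert abs(i - j) == 1


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_component(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        res = pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(7)
        res = pca(pd.DataFrame(rng.standard_normal((2000, 4))))
        assert res.explained_variance_ratio.max() < 0.35

    def test_sign_convention_largest_loading_positive(self, slaughter_tables):
        traits, _ = slaughter_tables
        res = pca(traits.drop(columns=["animal_id", "breed"]))
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((25, 4)))
        res = pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-10)

    def test_group_mean_shift_separates_pc1_scores(self):
        # two groups with a programmed >= 3 SD mean shift on 5 of 10 traits:
        # PC1 score clouds must not overlap
        rng = np.random.default_rng(11)
        n = 60
        base = rng.standard_normal((2 * n, 10))
        base[n:, :5] += 3.5
        df = pd.DataFrame(base)
        res = pca(df)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = np.sort(pc1[:n]), np.sort(pc1[n:])
        assert a.max() < b.min() or b.max() < a.min()

    def test_more_traits_than_animals_caps_rank(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((4, 10)))
        with pytest.warns(UserWarning, match="rank"):
            res = pca(df)
        assert res.scores.shape[1] == 3

    def test_too_small_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            pca(pd.DataFrame({"a": [1.0]}))
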
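"""Diversity, group contrasts, indicator values, rarity and biotope filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lotictraits import (
    bray_curtis,
    beta_dispersion_by_group,
    classify_rare,
    contrast_anova_tukey,
    filter_dominant_biotopes,
    indval,
    inverse_simpson,
)


class TestInverseSimpson:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ([1.0, 1.0, 1.0, 1.0], 4.0),   # uniform over 4 -> D = 4
            ([7.0, 0.0, 0.0], 1.0),        # single category -> minimum
            ([0.5, 0.5, 0.0], 2.0),        # 1 / (0.25 + 0.25)
        ],
    )
    def test_closed_forms(self, vector, expected):
        assert inverse_simpson(np.array([vector]))[0] == pytest.approx(expected)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            inverse_simpson(np.array([[0.0, 0.0]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_scale_invariant_and_uniform_maximal(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        v = rng.gamma(1.0, 1.0, size=k) + 1e-6
        d = inverse_simpson(np.array([v]))[0]
        d_scaled = inverse_simpson(np.array([10.0 * v]))[0]
        assert d == pytest.approx(d_scaled, rel=1e-12)
        assert d <= k + 1e-9  # uniform distribution attains the max


class TestContrastAnovaTukey:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(loc=1.0, size=7)
        values = pd.Series(np.concatenate([x, y]))
        groups = ["a"] * 6 + ["b"] * 7
        result = contrast_anova_tukey(values, groups)
        t = stats.ttest_ind(x, y).statistic
        assert result.anova_f == pytest.approx(t**2, abs=1e-10)

    def test_balanced_three_group_hand_oracle(self):
        # classic balanced layout, F computed by hand from the SS formulas:
        # groups (1,2,3), (2,3,4), (6,7,8); means 2, 3, 7; grand mean 4
        # SS_between = 3*((2-4)^2 + (3-4)^2 + (7-4)^2) = 42; SS_within = 6
        # F = (42/2) / (6/6) = 21
        values = pd.Series([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0])
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        result = contrast_anova_tukey(values, groups)
        assert result.anova_f == pytest.approx(21.0, abs=1e-10)
        assert result.r_squared == pytest.approx(42.0 / 48.0, abs=1e-12)
        # Tukey: q = diff / sqrt(MSE/n) with MSE = 1, n = 3
        row = result.tukey.set_index(["group_1", "group_2"]).loc[("g1", "g3")]
        expected_p = stats.studentized_range.sf(
            5.0 / np.sqrt(1.0 / 3.0), 3, 6
        )
        assert row["p_adjusted"] == pytest.approx(expected_p, rel=1e-6)

    def test_tukey_p_at_least_unadjusted_pairwise(self, rng):
        values = pd.Series(rng.normal(size=15))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        result = contrast_anova_tukey(values, groups)
        for row in result.tukey.itertuples():
            x = values[[g == row.group_1 for g in groups]]
            y = values[[g == row.group_2 for g in groups]]
            unadjusted = stats.ttest_ind(x, y).pvalue
            assert row.p_adjusted >= unadjusted - 1e-9

    def test_zero_residual_variance_rejected(self):
        values = pd.Series([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate|residual"):
            contrast_anova_tukey(values, ["a", "a", "b", "b"])

    def test_pairwise_set_covers_all_pairs_once(self, rng):
        values = pd.Series(rng.normal(size=12))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        result = contrast_anova_tukey(values, groups)
        pairs = set(zip(result.tukey["group_1"], result.tukey["group_2"]))
        assert len(pairs) == 6


class TestIndval:
    def test_perfect_single_group_indicator(self):
        data = pd.DataFrame({"item": [1.0, 1.0, 0.0, 0.0, 0.0, 0.0]})
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        result = indval(data, groups, n_perm=99, seed=0)
        row = result.table.loc["item"]
        assert row["A"] == 1.0
        assert row["B"] == 1.0
        assert row["stat"] == 1.0
        assert row["combination"] == "g1"

    def test_uniform_item_hits_square_root_half(self):
        # equal group means, full presence, 2 groups: best single-group
        # combination has A = 1/2, B = 1 -> stat = sqrt(1/2)
        data = pd.DataFrame({"item": [2.0, 2.0, 2.0, 2.0]})
        result = indval(data, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert result.table.loc["item", "stat"] == pytest.approx(
            np.sqrt(0.5), abs=1e-12
        )

    def test_full_group_set_never_reported(self, rng):
        data = pd.DataFrame(
            rng.gamma(2.0, 2.0, size=(12, 6)),
            columns=[f"t{i}" for i in range(6)],
        )
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        result = indval(data, groups, n_perm=9, seed=1)
        assert (result.table["n_groups_in_combination"] < 3).all()

    def test_statistic_squared_is_a_times_b(self, rng):
        data = pd.DataFrame(rng.gamma(1.0, 2.0, size=(10, 5)))
        groups = ["a"] * 5 + ["b"] * 5
        result = indval(data, groups, n_perm=9, seed=2)
        assert np.allclose(
            result.table["stat"] ** 2,
            result.table["A"] * result.table["B"],
            atol=1e-12,
        )

    def test_scale_invariance_per_item(self, rng):
        data = pd.DataFrame(
            rng.gamma(1.0, 2.0, size=(10, 3)), columns=["x", "y", "z"]
        )
        groups = ["a"] * 5 + ["b"] * 5
        base = indval(data, groups, n_perm=9, seed=3)
        scaled = data.copy()
        scaled["y"] *= 37.0
        after = indval(scaled, groups, n_perm=9, seed=3)
        assert after.table.loc["y", "stat"] == pytest.approx(
            base.table.loc["y", "stat"], rel=1e-12
        )

    def test_group_equalized_reduces_to_plain_on_balanced_data(self, rng):
        """On balanced groups, within-group means are sums / n with a common
        n, so the group-equalized A equals the sum-based A (brute-force)."""
        data = rng.gamma(1.0, 2.0, size=(12, 4))
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        result = indval(pd.DataFrame(data), list(groups), n_perm=9, seed=4)
        for k, item in enumerate(result.table.index):
            sums = {g: data[groups == g, item].sum() for g in "abc"}
            combo = set(result.table.loc[item, "combination"].split(" + "))
            a_sum_based = sum(sums[g] for g in combo) / sum(sums.values())
            assert result.table.loc[item, "A"] == pytest.approx(
                a_sum_based, abs=1e-12
            )

    def test_zero_total_items_excluded_with_report(self, rng):
        data = pd.DataFrame(
            {"live": rng.gamma(1.0, 2.0, size=6), "ghost": np.zeros(6)}
        )
        result = indval(data, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=5)
        assert result.excluded == ["ghost"]
        assert "ghost" not in result.table.index


class TestBetaDispersion:
    def test_single_group_rejected(self, rng):
        data = rng.gamma(2.0, 2.0, size=(6, 4)) + 0.05
        with pytest.raises(ValueError, match="two groups"):
            beta_dispersion_by_group(bray_curtis(data), ["only"] * 6)

    def test_wider_group_more_dispersed(self, rng):
        tight = np.array([10.0, 10.0, 10.0]) + rng.normal(0, 0.1, size=(5, 3))
        loose = np.array([10.0, 10.0, 10.0]) + rng.normal(0, 4.0, size=(5, 3))
        data = np.abs(np.vstack([tight, loose])) + 0.1
        result = beta_dispersion_by_group(
            bray_curtis(data), ["tight"] * 5 + ["loose"] * 5
        )
        assert result.group_means["loose"] > result.group_means["tight"]

    def test_duplicated_samples_zero_dispersion(self):
        data = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [3.0, 1.0],
                         [1.0, 5.0], [6.0, 2.0]])
        result = beta_dispersion_by_group(bray_curtis(data), ["a"] * 3 + ["b"] * 3)
        assert result.group_means["a"] == pytest.approx(0.0, abs=1e-10)


class TestRarity:
    def _metadata(self, n_control, n_restored):
        rows = []
        for i in range(n_control):
            rows.append({"sample_id": f"c{i}", "reach_type": "control"})
        for i in range(n_restored):
            rows.append({"sample_id": f"r{i}", "reach_type": "restored"})
        return pd.DataFrame(rows).set_index("sample_id")

    def test_share_arithmetic_and_strict_boundary(self):
        metadata = self._metadata(1, 1)
        abundances = pd.DataFrame(
            {"common": [985, 0], "rare": [5, 0], "boundary": [0, 10]},
            index=metadata.index,
        )
        report = classify_rare(abundances, metadata)
        assert report.loc["rare", "share"] == pytest.approx(0.005)
        assert bool(report.loc["rare", "rare"])
        assert report.loc["boundary", "share"] == pytest.approx(0.01)
        assert not bool(report.loc["boundary", "rare"])  # strict <

    def test_exclusivity_flags(self):
        metadata = self._metadata(2, 2)
        abundances = pd.DataFrame(
            {
                "everywhere": [5, 5, 5, 5],
                "control_only": [3, 1, 0, 0],
                "restored_only": [0, 0, 2, 0],
            },
            index=metadata.index,
        )
        report = classify_rare(abundances, metadata)
        assert report.loc["everywhere", "exclusive_to"] is None
        assert report.loc["control_only", "exclusive_to"] == "control"
        assert report.loc["restored_only", "exclusive_to"] == "restored"
        assert report.loc["restored_only", "n_samples"] == 1

    def test_shares_sum_to_one(self, rng):
        metadata = self._metadata(3, 3)
        abundances = pd.DataFrame(
            rng.poisson(10.0, size=(6, 8)), index=metadata.index,
            columns=[f"t{i}" for i in range(8)],
        )
        report = classify_rare(abundances, metadata)
        assert report["share"].sum() == pytest.approx(1.0, abs=1e-12)


class TestDominantBiotopeFilter:
    def _metadata(self, cells):
        rows = []
        for (pair, reach, biotope, n) in cells:
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{pair}:{reach}:{biotope}:{i}",
                        "site_pair": pair,
                        "reach_type": reach,
                        "biotope": biotope,
                        "replicate": i + 1,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def test_threshold_drops_sparse_cells(self):
        metadata = self._metadata(
            [("P1", "control", "algae", 3), ("P1", "restored", "sand", 2)]
        )
        filtered, excluded = filter_dominant_biotopes(metadata, min_patches=3)
        assert set(filtered["biotope"]) == {"algae"}
        assert len(excluded) == 1
        assert excluded.loc[0, "biotope"] == "sand"

    def test_min_one_is_identity(self):
        metadata = self._metadata(
            [("P1", "control", "algae", 3), ("P1", "restored", "sand", 1)]
        )
        filtered, excluded = filter_dominant_biotopes(metadata, min_patches=1)
        assert len(filtered) == len(metadata)
        assert excluded.empty

    def test_everything_dropped_is_an_error(self):
        metadata = self._metadata([("P1", "control", "algae", 2)])
        with pytest.raises(ValueError, match="all biotopes excluded"):
            filter_dominant_biotopes(metadata, min_patches=3)
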
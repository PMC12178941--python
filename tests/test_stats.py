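"""Nonparametric group inference: normality screen, Kruskal-Wallis,
Mann-Whitney Z-maps, clinical correlations, map agreement, meta-analysis
and partition summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pmvnet.stats import (
    clinical_correlation_map,
    compare_zmaps,
    kruskal_wallis_map,
    mannwhitney_u_z,
    mannwhitney_zmap,
    normality_screen,
    stouffer_meta,
    summarize_by_partition,
)
from pmvnet.synthetic import generate_atlas
from pmvnet.types import ZMap


def table_from(arr, groups_per_row):
    arr = np.asarray(arr, dtype=float)
    idx = [f"s{i}" for i in range(arr.shape[0])]
    pmv = pd.DataFrame(arr, index=pd.Index(idx, name="subject_id"),
                       columns=np.arange(1, arr.shape[1] + 1))
    groups = pd.Series(groups_per_row, index=idx)
    return pmv, groups


class TestNormalityScreen:
    def test_skewed_data_rejected_often(self, rng):
        vals = np.exp(rng.normal(size=(50, 20)))
        pmv, groups = table_from(vals, ["g"] * 50)
        _, frac = normality_screen(pmv, groups)
        assert frac > 0.5

    def test_gaussian_data_calibrated(self, rng):
        vals = rng.normal(size=(50, 200))
        pmv, groups = table_from(vals, ["g"] * 50)
        _, frac = normality_screen(pmv, groups)
        assert 0.01 < frac < 0.12

    def test_constant_group_reported_not_crashed(self):
        vals = np.ones((5, 3))
        pmv, groups = table_from(vals, ["g"] * 5)
        table, frac = normality_screen(pmv, groups)
        assert (table.loc["g"] == 0).all()
        assert frac == 1.0

    def test_small_group_excluded_with_warning(self, rng):
        vals = rng.normal(size=(5, 3))
        pmv, groups = table_from(vals, ["a", "a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="excluded"):
            table, _ = normality_screen(pmv, groups)
        assert list(table.index) == ["a"]


class TestKruskalWallis:
    def test_hand_computed_rank_statistic(self):
        pmv, groups = table_from([[1], [2], [3], [4], [5], [6]],
                                 ["a", "a", "b", "b", "c", "c"])
        out = kruskal_wallis_map(pmv, groups)
        # ranks 1..6; rank sums 3, 7, 11 -> H = 12/42 * 179/2 - 21
        assert out["statistic"].iloc[0] == pytest.approx(4.571428571428571)

    def test_null_rejections_rare(self, rng):
        rejected = 0
        for _ in range(50):
            vals = rng.normal(size=(45, 30))
            pmv, groups = table_from(vals, ["a"] * 15 + ["b"] * 15 + ["c"] * 15)
            out = kruskal_wallis_map(pmv, groups, alpha=0.05)
            rejected += int(out["significant"].any())
        assert rejected / 50 <= 0.1

    def test_planted_shift_detected_with_power(self, rng):
        hits = 0
        for _ in range(10):
            vals = rng.normal(size=(180, 20))
            vals[120:, :5] += 1.0  # third group shifted in regions 1..5
            pmv, groups = table_from(vals, ["a"] * 60 + ["b"] * 60 + ["c"] * 60)
            out = kruskal_wallis_map(pmv, groups, alpha=0.05)
            hits += int(out["significant"].iloc[:5].all())
        assert hits >= 9

    def test_single_group_rejected(self, rng):
        pmv, groups = table_from(rng.normal(size=(6, 3)), ["a"] * 6)
        with pytest.raises(ValueError):
            kruskal_wallis_map(pmv, groups)


class TestMannWhitneyZ:
    def test_null_center_gives_zero(self, rng):
        x = np.array([1.0, 4.0])
        y = np.array([2.0, 3.0])  # U = 2 = n1*n2/2
        u, z = mannwhitney_u_z(x, y)
        assert u == 2.0 and z == 0.0

    def test_complete_separation_closed_form(self):
        u, z = mannwhitney_u_z(np.array([4.0, 5.0, 6.0]),
                               np.array([1.0, 2.0, 3.0]))
        assert u == 9.0
        assert z == pytest.approx(1.9639610121239315)

    def test_antisymmetry_under_group_swap(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=5)
        _, z1 = mannwhitney_u_z(x, y)
        _, z2 = mannwhitney_u_z(y, x)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_moments_match_enumeration_oracle(self):
        """For n1+n2 <= 8 the U distribution over all orderings has mean
        n1*n2/2 and variance n1*n2*(n1+n2+1)/12 (no ties)."""
        for n1 in range(1, 5):
            for n2 in range(1, 9 - n1):
                n = n1 + n2
                us = []
                for pos in combinations(range(n), n1):
                    # U = number of (x, y) pairs with x ranked above y
                    pos = set(pos)
                    u = sum(1 for i in pos for j in range(n)
                            if j not in pos and i > j)
                    us.append(u)
                us = np.array(us, dtype=float)
                assert us.mean() == pytest.approx(n1 * n2 / 2)
                assert us.var(ddof=0) == pytest.approx(n1 * n2 * (n + 1) / 12)

    def test_zmap_orientation_and_restriction(self, rng):
        vals = rng.normal(size=(20, 6))
        vals[10:, 0] += 3.0
        pmv, groups = table_from(vals, ["a"] * 10 + ["b"] * 10)
        zmap, stat = mannwhitney_zmap(pmv, groups, "b", "a", restrict_to=[1, 2])
        assert zmap.values[0] > 0          # group b higher at region 1
        assert np.isnan(zmap.values[2:]).all()
        assert stat["n_tests"].iloc[0] == 2

    def test_empty_restriction_warns(self, rng):
        pmv, groups = table_from(rng.normal(size=(8, 3)), ["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="empty restriction"):
            zmap, stat = mannwhitney_zmap(pmv, groups, "a", "b", restrict_to=[])
        assert len(stat) == 0


class TestClinicalCorrelation:
    def test_score_equal_to_regional_pmv(self, rng):
        vals = rng.normal(size=(12, 4))
        pmv, groups = table_from(vals, ["MCI"] * 12)
        scores = pd.DataFrame({"m": vals[:, 2]}, index=pmv.index)
        out = clinical_correlation_map(pmv, groups, scores, subset=["MCI"])
        assert out["m"]["r"].loc[3] == pytest.approx(1.0)

    def test_null_score_rarely_significant(self, rng):
        rejections = 0
        for _ in range(30):
            vals = rng.normal(size=(40, 15))
            pmv, groups = table_from(vals, ["MCI"] * 40)
            scores = pd.DataFrame({"m": rng.normal(size=40)}, index=pmv.index)
            out = clinical_correlation_map(pmv, groups, scores, subset=["MCI"])
            rejections += int(out["m"]["significant"].any())
        assert rejections / 30 <= 0.1

    def test_missing_scores_dropped_pairwise(self, rng):
        vals = rng.normal(size=(10, 3))
        pmv, groups = table_from(vals, ["AD"] * 10)
        s = vals[:, 0].copy()
        s[:3] = np.nan
        scores = pd.DataFrame({"m": s}, index=pmv.index)
        out = clinical_correlation_map(pmv, groups, scores, subset=["AD"])
        assert out["m"]["n"].iloc[0] == 7
        assert out["m"]["r"].loc[1] == pytest.approx(1.0)

    def test_all_missing_score_skipped(self, rng):
        vals = rng.normal(size=(6, 3))
        pmv, groups = table_from(vals, ["AD"] * 6)
        scores = pd.DataFrame({"m": [np.nan] * 6}, index=pmv.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = clinical_correlation_map(pmv, groups, scores, subset=["AD"])
        assert out == {}


def zmap_from(values, n_a=10, n_b=10):
    values = np.asarray(values, dtype=float)
    return ZMap(values=values, region_ids=np.arange(1, values.size + 1),
                group_a="NC", group_b="AD", n_a=n_a, n_b=n_b)


class TestCompareZmaps:
    def test_identical_maps(self, rng):
        v = rng.normal(size=30)
        r, p = compare_zmaps(zmap_from(v), zmap_from(v))
        assert r == pytest.approx(1.0)

    def test_negated_maps(self, rng):
        v = rng.normal(size=30)
        r, _ = compare_zmaps(zmap_from(v), zmap_from(-v))
        assert r == pytest.approx(-1.0)

    def test_independent_maps_weakly_correlated(self, rng):
        n = 100
        small = sum(
            abs(compare_zmaps(zmap_from(rng.normal(size=n)),
                              zmap_from(rng.normal(size=n)))[0]) < 2 / np.sqrt(n)
            for _ in range(100))
        assert small >= 90

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_zmaps(zmap_from(rng.normal(size=5)),
                          zmap_from(rng.normal(size=6)))


class TestStoufferMeta:
    def test_two_identical_sites_scale_by_sqrt2(self, rng):
        v = rng.normal(size=12)
        meta = stouffer_meta([zmap_from(v), zmap_from(v)], weights=[1, 1])
        assert np.allclose(meta.values, v * np.sqrt(2))

    def test_single_site_identity(self, rng):
        v = rng.normal(size=12)
        meta = stouffer_meta([zmap_from(v)])
        assert np.allclose(meta.values, v)

    def test_null_meta_is_standard_normal(self, rng):
        sites = [zmap_from(rng.normal(size=1000), n_a=20 + 5 * i, n_b=20)
                 for i in range(4)]
        meta = stouffer_meta(sites)
        assert 0.9 < meta.values.std() < 1.1

    def test_weight_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stouffer_meta([zmap_from(rng.normal(size=5))], weights=[1, 2])


class TestPartitionSummary:
    def test_label_sizes_sum_to_n(self, rng):
        atlas = generate_atlas(40, seed=2)
        vals = rng.normal(size=(6, 40))
        pmv = pd.DataFrame(vals, index=[f"s{i}" for i in range(6)],
                           columns=atlas.region_ids)
        summary, _ = summarize_by_partition(pmv, atlas, "anatomical")
        assert summary["n"].sum() == 40

    def test_planted_subcortex_positive_shift(self, rng):
        atlas = generate_atlas(60, seed=3)
        vals = rng.normal(size=(8, 60))
        sub = atlas.anatomical_label == "subcortex"
        vals[:, sub] += 2.0
        pmv = pd.DataFrame(vals, index=[f"s{i}" for i in range(8)],
                           columns=atlas.region_ids)
        summary, pairwise = summarize_by_partition(pmv, atlas, "anatomical")
        means = summary.set_index("label")["mean"]
        cortical = means.drop("subcortex")
        assert means["subcortex"] > cortical.max()

    def test_unknown_partition_rejected(self, rng):
        atlas = generate_atlas(10, seed=4)
        pmv = pd.DataFrame(rng.normal(size=(3, 10)), columns=atlas.region_ids)
        with pytest.raises(ValueError):
            summarize_by_partition(pmv, atlas, "histological")
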
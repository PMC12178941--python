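"""PLS1 association, bootstrap gene ranking and map correlation panels."""

import numpy as np
import pytest
from scipy import stats as sps

from pmvnet.spatial import (
    bootstrap_gene_zscores,
    high_risk_gene_panel,
    map_correlation_panel,
    parse_gene_panel,
    pls1_association,
)
from pmvnet.synthetic import generate_atlas, generate_spatial_maps
from pmvnet.types import SpatialMapSet


def map_set(matrix, names=None, region_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    if names is None:
        names = [f"g{j}" for j in range(matrix.shape[1])]
    if region_ids is None:
        region_ids = np.arange(1, matrix.shape[0] + 1)
    return SpatialMapSet(names=names, matrix=matrix, region_ids=region_ids)


class TestGenePanel:
    def test_panel_has_28_distinct_symbols(self):
        panel = high_risk_gene_panel()
        assert len(panel) == 28
        assert len(set(panel)) == 28
        assert {"APP", "MAPT", "PSEN1", "SORL1"} <= set(panel)

    def test_parser_handles_prose_list(self):
        assert parse_gene_panel("A2M, ACE, and SORL1") == ["A2M", "ACE", "SORL1"]

    def test_parser_deduplicates_preserving_order(self):
        assert parse_gene_panel("APP, MAPT, APP") == ["APP", "MAPT"]

    def test_parser_rejects_junk(self):
        with pytest.raises(ValueError):
            parse_gene_panel("APP, not_a_gene!")


class TestPLS1:
    def test_single_predictor_reduces_to_simple_correlation(self, rng):
        x = rng.normal(size=(50, 1))
        y = 0.6 * x[:, 0] + rng.normal(size=50)
        res = pls1_association(map_set(x), y, n_perm=99, seed=1)
        assert abs(res.r_with_target) == pytest.approx(
            abs(sps.pearsonr(x[:, 0], y).statistic), abs=1e-10)

    def test_matches_sklearn_reference(self, rng):
        """Closed-form component equals scikit-learn's iterative fit."""
        from sklearn.cross_decomposition import PLSRegression
        from pmvnet.spatial import _pls1, _zscore_cols
        x = _zscore_cols(rng.normal(size=(40, 12)))
        y = _zscore_cols(rng.normal(size=(40, 1)))[:, 0]
        scores, weights, _ = _pls1(x, y)
        ref = PLSRegression(n_components=1, scale=False).fit(x, y)
        assert np.allclose(np.abs(weights), np.abs(ref.x_weights_[:, 0]),
                           atol=1e-10)
        assert np.allclose(np.abs(scores), np.abs(ref.x_scores_[:, 0]),
                           atol=1e-8)

    def test_planted_target_column_found(self):
        atlas = generate_atlas(80, seed=1)
        rng = np.random.default_rng(2)
        target = rng.normal(size=80)
        noise = generate_spatial_maps(atlas, target, n_maps=20,
                                      target_corr=0.0, seed=3, exact_corr=True)
        mat = np.column_stack([target, noise.matrix])
        res = pls1_association(
            map_set(mat, names=["planted"] + noise.names,
                    region_ids=atlas.region_ids),
            target, n_perm=999, seed=4)
        assert res.r_with_target > 0.99
        assert res.p_perm <= 2 / 1000

    def test_supplied_permutations_match_uniform_mode(self, rng):
        x = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        gen = np.random.default_rng(42)
        perms = np.vstack([gen.permutation(30) for _ in range(99)])
        a = pls1_association(map_set(x), y, permutations=perms)
        gen2 = np.random.default_rng(42)
        assert np.array_equal(
            perms, np.vstack([gen2.permutation(30) for _ in range(99)]))
        b = pls1_association(map_set(x), y, n_perm=99, seed=42)
        assert a.p_perm == b.p_perm
        assert a.permutation_scheme == "supplied"
        assert b.permutation_scheme == "uniform"

    def test_invalid_permutation_rows_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        bad = np.zeros((5, 10), dtype=int)
        with pytest.raises(ValueError, match="permutation"):
            pls1_association(map_set(x), rng.normal(size=10), permutations=bad)

    def test_scores_invariant_to_column_order_and_scale(self, rng):
        x = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        a = pls1_association(map_set(x), y, n_perm=9, seed=0)
        perm = [3, 1, 5, 0, 2, 4]
        scaled = x[:, perm] * np.array([2.0, 5.0, 1.5, 3.0, 0.5, 7.0])
        b = pls1_association(map_set(scaled), y, n_perm=9, seed=0)
        assert np.allclose(a.component_scores, b.component_scores, atol=1e-10)
        assert np.allclose(a.gene_weights[perm], b.gene_weights, atol=1e-10)


class TestBootstrapZ:
    def test_duplicated_gene_gets_matching_z(self):
        atlas = generate_atlas(60, seed=5)
        rng = np.random.default_rng(6)
        target = rng.normal(size=60)
        maps = generate_spatial_maps(atlas, target, n_maps=10,
                                     target_corr=0.4, seed=7)
        mat = np.column_stack([maps.matrix, maps.matrix[:, 0]])
        sms = map_set(mat, names=maps.names + ["dup_of_first"],
                      region_ids=atlas.region_ids)
        table, _ = bootstrap_gene_zscores(sms, target, n_boot=1000, seed=8,
                                          top_k=11)
        z = table.set_index("gene")["Z"]
        assert abs(z[maps.names[0]] - z["dup_of_first"]) < 0.2

    def test_planted_signal_ranks_first(self):
        atlas = generate_atlas(70, seed=9)
        rng = np.random.default_rng(10)
        target = rng.normal(size=70)
        noise = generate_spatial_maps(atlas, target, n_maps=15,
                                      target_corr=0.0, seed=11, exact_corr=True)
        mat = np.column_stack([target, noise.matrix])
        sms = map_set(mat, names=["planted"] + noise.names,
                      region_ids=atlas.region_ids)
        table, top = bootstrap_gene_zscores(sms, target, n_boot=300, seed=12,
                                            top_k=5)
        assert table.iloc[0]["gene"] == "planted"
        assert top[0] == "planted"

    def test_top_k_capped_with_warning(self, rng):
        x = rng.normal(size=(30, 6))
        with pytest.warns(UserWarning, match="exceeds gene count"):
            _, top = bootstrap_gene_zscores(map_set(x), rng.normal(size=30),
                                            n_boot=100, seed=1, top_k=500)
        assert len(top) == 6

    def test_small_n_boot_rejected(self, rng):
        x = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            bootstrap_gene_zscores(map_set(x), rng.normal(size=20), n_boot=10)


class TestCorrelationPanel:
    def test_target_in_panel_gives_r_one(self, rng):
        target = rng.normal(size=40)
        mat = np.column_stack([target, rng.normal(size=(40, 2))])
        out = map_correlation_panel(target, map_set(mat), n_perm=99, seed=1)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_28_map_panel_yields_28_rows(self):
        atlas = generate_atlas(50, seed=13)
        rng = np.random.default_rng(14)
        target = rng.normal(size=50)
        maps = generate_spatial_maps(atlas, target, n_maps=28,
                                     target_corr=0.3, seed=15,
                                     names=high_risk_gene_panel())
        out = map_correlation_panel(target, maps, n_perm=99, seed=16)
        assert len(out) == 28
        assert set(out["name"]) == set(high_risk_gene_panel())

    def test_null_panel_rarely_significant(self):
        atlas = generate_atlas(60, seed=17)
        rng = np.random.default_rng(18)
        rejections = 0
        for rep in range(20):
            target = rng.normal(size=60)
            maps = generate_spatial_maps(atlas, target, n_maps=10,
                                         target_corr=0.0, seed=100 + rep)
            out = map_correlation_panel(target, maps, n_perm=199,
                                        seed=200 + rep)
            rejections += int(out["significant"].any())
        assert rejections / 20 <= 0.15

    def test_region_mismatch_names_offender(self, rng):
        maps = map_set(rng.normal(size=(20, 2)), names=["SERT", "DAT"])
        with pytest.raises(ValueError, match="SERT"):
            map_correlation_panel(rng.normal(size=19), maps, n_perm=9, seed=0)

    def test_spearman_flag(self, rng):
        target = rng.normal(size=30)
        mat = target[:, None] ** 3  # monotone transform
        out = map_correlation_panel(target, map_set(mat), n_perm=49, seed=2,
                                    method="spearman")
        assert out.loc[0, "r"] == pytest.approx(1.0)
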
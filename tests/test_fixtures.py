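"""Generator contracts: symmetry, contiguity, determinism, planted effects."""

import numpy as np
import pytest
from scipy import ndimage, stats

from gliotopo import fixtures
from gliotopo.containers import NETWORKS

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lgg_fraction=1.5),
            dict(lgg_fraction=-0.1),
            dict(n_genes=0),
            dict(n_subcortical=40),
            dict(smoothness_mm=-1),
            dict(effect_sizes={"hub": 1.5}),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_config(**kwargs)

    def test_odd_midline_axis_rejected(self):
        with pytest.raises(ValueError):
            small_config(grid_shape=(31, 32, 32))


class TestParcellation:
    def test_counts_match_requested(self, small_parc):
        assert small_parc.n_parcels == 80
        assert len(small_parc.ids("left")) == 40
        tab = small_parc.table
        assert int((~tab["is_cortical"] & (tab["hemisphere"] == "L")).sum()) == 4
        assert int((~tab["is_cortical"] & (tab["hemisphere"] == "R")).sum()) == 4

    def test_left_right_flip_maps_homotopic_partners(self, small_parc):
        flipped = small_parc.labels[::-1, :, :]
        partner = small_parc.table["homotopic_id"]
        fg = small_parc.labels > 0
        orig = small_parc.labels[fg]
        mirrored = flipped[fg]
        assert np.all(mirrored > 0)
        expected = partner.loc[orig].to_numpy()
        assert np.array_equal(mirrored, expected)

    def test_parcels_contiguous_by_flood_fill(self):
        parc = fixtures.make_parcellation(
            small_config(seed=5, n_parcels_per_hemisphere=4, n_subcortical=1)
        )
        assert parc.n_parcels == 8
        structure = ndimage.generate_binary_structure(3, 1)
        for pid in parc.parcel_ids:
            _, n_comp = ndimage.label(parc.labels == pid, structure=structure)
            assert n_comp == 1

    def test_networks_drawn_from_canonical_seven(self, small_parc):
        assert set(small_parc.table["network"]) <= set(NETWORKS)

    def test_cortical_centroids_on_unit_sphere(self, small_parc):
        cort = small_parc.ids("left", cortical_only=True)
        pts = small_parc.sphere_centroids(cort)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_infeasible_parcel_count_raises(self):
        with pytest.raises(fixtures.SizingError):
            fixtures.make_parcellation(
                small_config(grid_shape=(8, 8, 8), n_parcels_per_hemisphere=100,
                             n_subcortical=2)
            )

    def test_niche_structures_tagged(self, small_parc):
        tags = small_parc.table["structure"]
        assert (tags == "hippocampus").sum() == 2  # one per hemisphere
        assert (tags == "caudate").sum() == 2
        assert not small_parc.table.loc[tags == "hippocampus", "is_cortical"].any()


class TestDeterminism:
    def test_identical_config_bit_identical_outputs(self, small_cfg, small_parc):
        parc2 = fixtures.make_parcellation(small_config())
        assert np.array_equal(small_parc.labels, parc2.labels)
        assert small_parc.table.equals(parc2.table)
        f1 = fixtures.make_ground_truth_fields(small_cfg, small_parc)
        f2 = fixtures.make_ground_truth_fields(small_cfg, parc2)
        for k in f1:
            assert np.array_equal(f1[k].values, f2[k].values)
        c1 = fixtures.make_lesion_cohort(small_cfg, small_parc, f1["frequency"])
        c2 = fixtures.make_lesion_cohort(small_cfg, parc2, f2["frequency"])
        assert [g for _, g in c1] == [g for _, g in c2]
        assert all(np.array_equal(a.values, b.values) for (a, _), (b, _) in zip(c1, c2))
        a1 = fixtures.make_expression_atlas(small_cfg, small_parc, f1["frequency"])
        a2 = fixtures.make_expression_atlas(small_cfg, parc2, f2["frequency"])
        assert a1[0].expression.equals(a2[0].expression)
        assert a1[0].coords.equals(a2[0].coords)


class TestGroundTruthFields:
    def test_unsmoothed_field_has_null_morans_i(self, small_parc):
        from oracles import morans_i_loop

        cfg = small_config(smoothness_mm=0.0)
        fields = fixtures.make_ground_truth_fields(cfg, small_parc)
        ids = small_parc.ids("left", cortical_only=True)
        pts = small_parc.sphere_centroids(ids)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0)
        w /= w.sum(1, keepdims=True)
        vals = fields["hub"].align_to(ids).values
        i_obs = morans_i_loop(vals, w)
        assert abs(i_obs - (-1.0 / (len(ids) - 1))) < 0.12

    def test_smooth_field_positive_autocorrelation(self, small_cfg, small_parc, small_fields):
        from gliotopo.spatialnull import morans_i

        i_obs, p = morans_i(small_fields["hub"], small_parc, n_perm=500, seed=3)
        assert i_obs > 0
        assert p < 0.01

    def test_planted_pairwise_correlation_recovered(self, parc167):
        # smooth fields have few effective dof, so the band is on the mean
        rs = []
        for seed in range(20):
            cfg = fixtures.SyntheticConfig(
                seed=100 + seed, effect_sizes={"hub": 0.5, "opc": 0.5, "driver": 0.5})
            f = fixtures.make_ground_truth_fields(cfg, parc167)
            rs.append(np.corrcoef(f["frequency"].values, f["hub"].values)[0, 1])
        assert 0.3 <= np.mean(rs) <= 0.7

    def test_frequency_field_nonnegative(self, small_fields):
        assert np.all(small_fields["frequency"].values >= 0)


class TestLesionCohort:
    def test_concentrated_truth_places_blobs_in_target_parcel(self, small_parc):
        cfg = small_config(n_patients=50, lesion_radius_median_mm=5.0)
        left_ids = small_parc.ids("left")
        target = left_ids[3]
        truth = fixtures.ParcelVector(
            left_ids, np.where(left_ids == target, 1.0, 0.0))
        cohort = fixtures.make_lesion_cohort(cfg, small_parc, truth)
        partner = int(small_parc.table.loc[target, "homotopic_id"])
        hits = 0
        for mask, _ in cohort:
            overlap = [
                (np.logical_and(mask.values, small_parc.labels == pid).sum(), pid)
                for pid in (target, partner)
            ]
            best_other = max(
                np.logical_and(mask.values, small_parc.labels == pid).sum()
                for pid in small_parc.parcel_ids if pid not in (target, partner)
            )
            if max(o for o, _ in overlap) >= best_other:
                hits += 1
        assert hits >= 45  # >= 90%

    def test_masks_are_single_contiguous_blobs(self, small_cohort):
        structure = ndimage.generate_binary_structure(3, 1)
        for mask, _ in small_cohort[:20]:
            _, n = ndimage.label(mask.values, structure=structure)
            assert n == 1

    def test_zero_patients_empty_cohort(self, small_parc, small_fields):
        cfg = small_config(n_patients=0)
        assert fixtures.make_lesion_cohort(cfg, small_parc, small_fields["frequency"]) == []

    def test_lgg_count_binomial_at_study_fraction(self, small_parc, small_fields):
        cfg = small_config(n_patients=335, lgg_fraction=0.23, lesion_radius_median_mm=6.0)
        cohort = fixtures.make_lesion_cohort(cfg, small_parc, small_fields["frequency"])
        n_lgg = sum(g == "LGG" for _, g in cohort)
        sd = np.sqrt(335 * 0.23 * 0.77)
        assert abs(n_lgg - 0.23 * 335) < 4 * sd

    def test_all_zero_truth_rejected(self, small_parc):
        left_ids = small_parc.ids("left")
        truth = fixtures.ParcelVector(left_ids, np.zeros(len(left_ids)))
        with pytest.raises(fixtures.DegenerateFieldError):
            fixtures.make_lesion_cohort(small_config(), small_parc, truth)


class TestConnectomeSource:
    def test_modular_structure_planted(self, small_cfg, small_parc, small_fields):
        load = fixtures.make_connectome_source(small_cfg, small_parc, small_fields["hub"])
        w = np.corrcoef(load.to_numpy())
        np.fill_diagonal(w, 0)
        w[w < 0] = 0
        nets = small_parc.table.loc[load.index, "network"].to_numpy()
        same = nets[:, None] == nets[None, :]
        np.fill_diagonal(same, False)
        assert w[same].mean() > w[~same & (np.ones_like(same, bool))].mean()

    def test_hub_effect_calibration(self, full_cfg, parc167):
        rhos = []
        for seed in range(8):
            cfg = fixtures.SyntheticConfig(
                seed=200 + seed, effect_sizes={"hub": 0.8, "opc": 0.5, "driver": 0.5})
            f = fixtures.make_ground_truth_fields(cfg, parc167)
            load = fixtures.make_connectome_source(cfg, parc167, f["hub"])
            w = np.corrcoef(load.to_numpy())
            np.fill_diagonal(w, 0)
            w[w < 0] = 0
            hub_by_id = dict(zip(f["hub"].ids, f["hub"].values))
            tab = parc167.table
            hub = np.array([
                hub_by_id[pid if tab.loc[pid, "hemisphere"] == "L"
                          else int(tab.loc[pid, "homotopic_id"])]
                for pid in load.index
            ])
            rhos.append(stats.spearmanr(w.sum(1), hub).statistic)
        assert all(0.6 <= r <= 0.95 for r in rhos)

    def test_too_few_components_rejected(self, small_parc, small_fields):
        with pytest.raises(ValueError):
            fixtures.make_connectome_source(
                small_config(n_components=1), small_parc, small_fields["hub"])


class TestExpressionAtlas:
    def test_marker_set_coexpression_beats_random_sets(self, small_atlas_bundle, rng):
        atlas, sets, _ = small_atlas_bundle
        genes = sets["opc_markers"].genes
        expr = atlas.expression
        data = expr.to_numpy()

        def mean_pairwise(cols):
            c = np.corrcoef(data[:, cols].T)
            iu = np.triu_indices(len(cols), 1)
            return c[iu].mean()

        name_to_col = {g: k for k, g in enumerate(expr.columns)}
        observed = mean_pairwise([name_to_col[g] for g in genes])
        null = np.array([
            mean_pairwise(rng.choice(expr.shape[1], size=len(genes), replace=False))
            for _ in range(1000)
        ])
        assert observed > np.percentile(null, 97.5)

    def test_zero_effect_gives_null_score_correlation(self, small_parc):
        rs = []
        for seed in range(10):
            cfg = small_config(seed=300 + seed,
                               effect_sizes={"hub": 0.5, "opc": 0.0, "driver": 0.5})
            f = fixtures.make_ground_truth_fields(cfg, small_parc)
            atlas, sets, planted = fixtures.make_expression_atlas(cfg, small_parc, f["frequency"])
            expr = atlas.expression[sets["opc_markers"].genes].to_numpy()
            z = (expr - expr.mean(0)) / expr.std(0, ddof=1)
            score = np.median(z, axis=1)
            rs.append(np.corrcoef(score, planted["sample_target"])[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_samples_left_hemisphere_only(self, small_atlas_bundle, small_parc):
        atlas, _, _ = small_atlas_bundle
        mid_mm = (small_parc.shape[0] - 1) * small_parc.voxel_size_mm[0] / 2
        assert (atlas.coords["x"] <= mid_mm + 1e-9).all()

    def test_sizing_error_when_sets_exceed_genes(self, small_parc, small_fields):
        with pytest.raises(fixtures.SizingError):
            fixtures.make_expression_atlas(
                small_config(n_genes=10), small_parc, small_fields["frequency"])

    def test_undersampled_atlas_warns(self, small_parc, small_fields):
        with pytest.warns(UserWarning):
            fixtures.make_expression_atlas(
                small_config(n_samples=10), small_parc, small_fields["frequency"])
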
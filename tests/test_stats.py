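"""Presence filtering, imputation, t maps, clusters, permutation FWER."""

import numpy as np
import pytest

from voxnet import (
    GroupSample,
    MetricImage,
    clusters_from_tmap,
    generate_null_metric_images,
    impute_missing,
    permutation_cluster_test,
    presence_filter,
    t_map,
)
from voxnet.stats import _t_from_stack


def image_from(values, measure="degree", space_tag="native", missing=None):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = ~np.isfinite(values)
    return MetricImage(
        values=values, missing_mask=missing, measure=measure, space_tag=space_tag
    )


def group_of(arrays, **kwargs):
    return GroupSample(images=[image_from(a, **kwargs) for a in arrays])


class TestPresenceFilter:
    def make_groups(self, n_missing_g1):
        shape = (2, 2, 1)
        g1 = []
        for i in range(10):
            vals = np.ones(shape)
            if i < n_missing_g1:
                vals[0, 0, 0] = np.nan
            g1.append(vals)
        g2 = [np.ones(shape) for _ in range(10)]
        return group_of(g1), group_of(g2)

    def test_one_of_ten_missing_is_included(self):
        s1, s2 = self.make_groups(1)
        assert presence_filter(s1, s2)[0, 0, 0]  # 0.9 >= 0.9 boundary

    def test_two_of_ten_missing_is_excluded(self):
        s1, s2 = self.make_groups(2)
        assert not presence_filter(s1, s2)[0, 0, 0]

    def test_no_missing_includes_all(self):
        s1, s2 = self.make_groups(0)
        assert presence_filter(s1, s2).all()


class TestImpute:
    # voxel_size chosen so the 10 mm sphere holds exactly the centre voxel
    # and its +/-x, +/-y neighbours (5 locations)
    VS = (10.0, 10.0, 100.0)

    def make_group(self, donor_missing=0):
        shape = (3, 3, 1)
        recipient = np.full(shape, 2.0)
        recipient[1, 1, 0] = np.nan
        donor = np.full(shape, 2.0)
        if donor_missing:
            donor[1, 0, 0] = np.nan  # one of the 5 in-sphere candidates
        return GroupSample(
            images=[
                image_from(recipient, space_tag="standard"),
                image_from(donor, space_tag="standard"),
            ],
            voxel_size=self.VS,
        )

    def test_all_drawn_values_equal_mean(self):
        s = impute_missing(self.make_group(), seed=0, radius_mm=10.0)
        assert s.images[0].values[1, 1, 0] == pytest.approx(2.0)
        assert not s.images[0].missing_mask[1, 1, 0]

    def test_four_of_five_present_stays_missing(self):
        s = impute_missing(self.make_group(donor_missing=1), seed=0, radius_mm=10.0)
        assert s.images[0].missing_mask[1, 1, 0]  # 0.8 < 0.9

    def test_seeded_determinism(self):
        a = impute_missing(self.make_group(), seed=7)
        b = impute_missing(self.make_group(), seed=7)
        np.testing.assert_array_equal(a.images[0].values, b.images[0].values)

    def test_never_alters_present_values(self):
        base = self.make_group()
        out = impute_missing(base, seed=1)
        keep = ~base.images[1].missing_mask
        np.testing.assert_array_equal(
            out.images[1].values[keep], base.images[1].values[keep]
        )

    def test_native_space_rejected(self):
        g = group_of([np.ones((2, 2, 1))], space_tag="native")
        with pytest.raises(ValueError):
            impute_missing(g)

    def test_single_subject_warns(self):
        g = group_of([np.ones((2, 2, 1))], space_tag="standard")
        with pytest.warns(UserWarning):
            impute_missing(g)


class TestTMap:
    def test_identical_groups_give_zero(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2) + 1
        s1 = group_of([vals, vals + 1, vals + 2])
        s2 = group_of([vals, vals + 1, vals + 2])
        t = t_map(s1, s2)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_hand_computed_pooled_t(self):
        shape = (1, 1, 1)
        s1 = group_of([np.full(shape, v) for v in (1.0, 2.0, 3.0)])
        s2 = group_of([np.full(shape, v) for v in (4.0, 5.0, 6.0)])
        t = t_map(s1, s2)
        assert t[0, 0, 0] == pytest.approx(-3.674235, abs=1e-5)

    def test_swapping_groups_negates_t(self, rng):
        a = [rng.normal(size=(3, 3, 2)) for _ in range(4)]
        b = [rng.normal(size=(3, 3, 2)) for _ in range(4)]
        t_ab = t_map(group_of(a), group_of(b))
        t_ba = t_map(group_of(b), group_of(a))
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)

    def test_excluding_a_subject_reduces_df(self, rng):
        imgs = [image_from(rng.normal(size=(2, 2, 1))) for _ in range(4)]
        full = GroupSample(images=imgs)
        dropped = GroupSample(images=imgs, excluded=[True, False, False, False])
        other = group_of([rng.normal(size=(2, 2, 1)) for _ in range(3)])
        _, df_full = _t_from_stack(full.stacked(), other.stacked())
        _, df_drop = _t_from_stack(dropped.stacked(), other.stacked())
        assert np.nanmax(df_full) - np.nanmax(df_drop) == 1

    def test_zero_variance_voxel_dropped_with_warning(self):
        shape = (1, 1, 1)
        s1 = group_of([np.full(shape, 1.0), np.full(shape, 1.0)])
        s2 = group_of([np.full(shape, 1.0), np.full(shape, 1.0)])
        with pytest.warns(UserWarning, match="dropped"):
            t = t_map(s1, s2, mask=np.ones(shape, dtype=bool))
        assert np.isnan(t[0, 0, 0])


class TestClusters:
    def test_subthreshold_image_has_no_clusters(self):
        assert clusters_from_tmap(np.full((4, 4, 2), 2.5)) == []

    def test_block_cluster_size_four(self):
        t = np.zeros((4, 4, 2))
        t[1:3, 1:3, 0] = 5.0
        cs = clusters_from_tmap(t)
        assert len(cs) == 1 and cs[0].size == 4 and cs[0].sign == 1

    def test_diagonal_voxels_join_under_26_connectivity(self):
        t = np.zeros((4, 4, 2))
        t[0, 0, 0] = 4.0
        t[1, 1, 1] = 4.0
        assert len(clusters_from_tmap(t, connectivity=26)) == 1
        assert len(clusters_from_tmap(t, connectivity=6)) == 2

    def test_signed_clusters_reported_separately(self):
        t = np.zeros((5, 1, 1))
        t[0] = 4.0
        t[4] = -4.0
        signs = sorted(c.sign for c in clusters_from_tmap(t))
        assert signs == [-1, 1]


class TestPermutationTest:
    def test_exact_enumeration_reproducible_without_seed(self):
        g1, g2 = generate_null_metric_images((3, 3), (4, 4, 2), seed=5)
        s1, s2 = GroupSample(images=g1), GroupSample(images=g2)
        a = permutation_cluster_test(s1, s2, n_perm=50, seed=None)
        b = permutation_cluster_test(s1, s2, n_perm=50, seed=None)
        assert a.exact and b.exact
        assert a.n_permutations == 20  # C(6,3) relabelings
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)

    def test_planted_difference_recovered(self, rng):
        shape = (6, 6, 3)
        effect = np.zeros(shape)
        effect[1:4, 1:4, :] = 4.0
        g1 = [rng.normal(size=shape) + effect for _ in range(8)]
        g2 = [rng.normal(size=shape) for _ in range(8)]
        rpt = permutation_cluster_test(
            group_of(g1), group_of(g2), n_perm=300, seed=1
        )
        assert rpt.significant
        top = rpt.significant[0]
        assert top.sign == 1
        planted = {(x, y, z) for x in range(1, 4) for y in range(1, 4) for z in range(3)}
        found = {tuple(v) for v in top.voxels}
        assert len(found & planted) / len(planted) > 0.5

    def test_minimum_p_is_one_over_permutations(self, rng):
        shape = (5, 5, 2)
        g1 = [rng.normal(size=shape) + 10.0 for _ in range(6)]
        g2 = [rng.normal(size=shape) for _ in range(6)]
        rpt = permutation_cluster_test(group_of(g1), group_of(g2), n_perm=200, seed=3)
        assert rpt.significant
        p = rpt.cluster_p(rpt.significant[0].size)
        assert p >= 1.0 / rpt.n_permutations

    def test_all_voxels_filtered_out_yields_empty_report(self):
        shape = (3, 3, 1)
        empty = np.full(shape, np.nan)
        s1 = group_of([empty, empty, empty])
        s2 = group_of([empty, empty, empty])
        rpt = permutation_cluster_test(s1, s2, n_perm=20)
        assert rpt.clusters == [] and rpt.significant == []

    def test_too_few_subjects_rejected(self, rng):
        s1 = group_of([rng.normal(size=(2, 2, 1))])
        s2 = group_of([rng.normal(size=(2, 2, 1)) for _ in range(3)])
        with pytest.raises(ValueError):
            permutation_cluster_test(s1, s2, n_perm=10)
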
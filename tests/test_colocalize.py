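import numpy as np
import pytest

from obcacount.colocalize import (
    ColocConfig,
    count_coloc_pairs,
    count_coloc_triples,
    expand_points,
    run_automated_pipeline,
    run_semiauto_pipeline,
)
from obcacount.containers import ChannelImage, PointSet
from obcacount.exceptions import ShapeMismatchError
from obcacount.maxima import MaximaConfig
from obcacount.synth import SceneSpec, generate_scene
from oracles import coloc_pairs_oracle, coloc_triples_oracle


SHAPE = (512, 512)


def ps(points, category=1, shape=SHAPE):
    return PointSet(np.asarray(points, dtype=np.float64), category=category, source_shape=shape)


def random_ps(rng, n, category, shape=SHAPE):
    pts = np.column_stack(
        [rng.uniform(0, shape[0] - 1, n), rng.uniform(0, shape[1] - 1, n)]
    )
    return ps(pts, category=category, shape=shape)


class TestExpandPoints:
    def test_disk_area_is_lattice_count(self):
        # closed disk of radius 5 around a lattice point holds 81 pixels
        lm = expand_points(ps([[50, 50]]), 5.0, (101, 101))
        assert lm.n_objects == 1
        assert (lm.labels == 1).sum() == 81

    def test_far_points_make_disjoint_disks(self):
        lm = expand_points(ps([[50, 50], [50, 150]]), 5.0, (256, 256))
        assert lm.n_objects == 2
        assert (lm.labels == 1).sum() == 81
        assert (lm.labels == 2).sum() == 81

    def test_close_points_partition_union_by_nearest(self):
        lm = expand_points(ps([[50, 50], [50, 53]]), 5.0, (128, 128))
        assert lm.n_objects == 2
        own1 = np.argwhere(lm.labels == 1)
        own2 = np.argwhere(lm.labels == 2)
        assert len(own1) and len(own2)
        # every pixel is closer to (or tied with) its owner
        d1 = np.hypot(own1[:, 0] - 50, own1[:, 1] - 50)
        d2 = np.hypot(own1[:, 0] - 50, own1[:, 1] - 53)
        assert (d1 <= d2).all()  # ties go to the lower index
        # the union is exactly the union of both closed disks
        yy, xx = np.mgrid[0:128, 0:128]
        in_union = (
            ((yy - 50) ** 2 + (xx - 50) ** 2 <= 25) | ((yy - 50) ** 2 + (xx - 53) ** 2 <= 25)
        )
        np.testing.assert_array_equal(lm.labels > 0, in_union)


class TestCountColocPairs:
    def test_identical_sets_all_colocalized(self, rng):
        a = random_ps(rng, 20, 1)
        b = ps(a.points.copy(), category=2)
        res = count_coloc_pairs(a, b)
        assert res.n_coloc == 20

    def test_far_apart_sets_give_zero(self):
        a = ps([[10, 10], [10, 100]], 1)
        b = ps([[200, 200], [400, 400]], 2)
        assert count_coloc_pairs(a, b).n_coloc == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = random_ps(r, 150, 1)
        b = random_ps(r, 150, 2)
        res = count_coloc_pairs(a, b, ColocConfig(expand_px=5))
        assert res.n_coloc == coloc_pairs_oracle(a.points, b.points, 5.0, SHAPE)

    def test_overlay_mode_uses_radius_sum(self):
        a = ps([[100, 100]], 1)
        b = ps([[100, 190]], 2)
        near = ColocConfig(mode="overlay", overlay_radius={1: 50.0, 2: 50.0})
        far = ColocConfig(mode="overlay", overlay_radius={1: 50.0, 2: 30.0})
        assert count_coloc_pairs(a, b, near).n_coloc == 1  # 90 <= 100
        assert count_coloc_pairs(a, b, far).n_coloc == 0   # 90 > 80

    def test_max_dist_override_applies_literal_distance(self):
        a = ps([[100, 100]], 1)
        b = ps([[100, 107]], 2)
        assert count_coloc_pairs(a, b, ColocConfig(expand_px=5)).n_coloc == 1
        literal = ColocConfig(expand_px=5, max_dist=5.0)
        assert count_coloc_pairs(a, b, literal).n_coloc == 0

    def test_monotone_in_expand_px(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = random_ps(r, 40, 1, (256, 256))
            b = random_ps(r, 40, 2, (256, 256))
            counts = [
                count_coloc_pairs(a, b, ColocConfig(expand_px=e), (256, 256)).n_coloc
                for e in (2, 5, 9)
            ]
            assert counts == sorted(counts), seed

    def test_permutation_invariance(self, rng):
        a = random_ps(rng, 30, 1)
        b = random_ps(rng, 30, 2)
        perm = rng.permutation(30)
        a2 = ps(a.points[perm], 1)
        b2 = ps(b.points[rng.permutation(30)], 2)
        assert count_coloc_pairs(a, b).n_coloc == count_coloc_pairs(a2, b2).n_coloc

    def test_counting_unit_bound(self, rng):
        a = random_ps(rng, 25, 1)
        b = random_ps(rng, 60, 2)
        res = count_coloc_pairs(a, b)
        assert res.n_coloc <= len(a)

    def test_shape_mismatch_rejected(self):
        a = ps([[1, 1]], 1, (64, 64))
        b = ps([[1, 1]], 2, (32, 32))
        with pytest.raises(ShapeMismatchError):
            count_coloc_pairs(a, b, shape=(64, 64))


class TestCountColocTriples:
    def test_three_identical_sets(self, rng):
        a = random_ps(rng, 15, 1)
        b = ps(a.points.copy(), 2)
        c = ps(a.points.copy(), 3)
        assert count_coloc_triples(a, b, c).n_coloc == 15

    def test_conjunction_requires_both_partners(self):
        a = ps([[100, 100]], 1)
        b = ps([[102, 102]], 2)   # colocalized with a
        c = ps([[400, 400]], 3)   # far from everything
        assert count_coloc_triples(a, b, c).n_coloc == 0

    def test_matches_bruteforce_triple_scan(self):
        r = np.random.default_rng(7)
        # 50 seeded triples + 50 decoys per marker channel
        anchors = np.column_stack([r.uniform(20, 490, 50), r.uniform(20, 490, 50)])
        jitter = lambda: r.uniform(-3, 3, (50, 2))
        a = ps(anchors, 1)
        b = ps(np.vstack([anchors + jitter(), np.column_stack(
            [r.uniform(0, 511, 50), r.uniform(0, 511, 50)])]), 2)
        c = ps(np.vstack([anchors + jitter(), np.column_stack(
            [r.uniform(0, 511, 50), r.uniform(0, 511, 50)])]), 3)
        res = count_coloc_triples(a, b, c, ColocConfig(expand_px=5))
        assert res.n_coloc == coloc_triples_oracle(a.points, b.points, c.points, 5.0, SHAPE)
        assert res.n_coloc <= count_coloc_pairs(a, b).n_coloc
        assert res.n_coloc <= count_coloc_pairs(a, c).n_coloc


class TestAutomatedPipeline:
    def test_easy_scene_recovers_all_colocalized_pairs(self):
        scene = generate_scene(SceneSpec(n_nuclei=50, coloc_fraction=1.0, seed=3))
        res = run_automated_pipeline(scene.channels, field_id="f", marker="CD4")
        assert res.n_coloc == 50
        assert res.n_per_category == {1: 50, 2: 50}

    def test_disjoint_placements_count_zero(self):
        scene = generate_scene(
            SceneSpec(n_nuclei=30, coloc_fraction=0.0, n_decoys=30, seed=11)
        )
        res = run_automated_pipeline(scene.channels)
        assert res.n_coloc == 0

    def test_three_channel_scene_recovers_triples(self):
        scene = generate_scene(
            SceneSpec(n_nuclei=20, coloc_fraction=1.0, n_channels=3, seed=9)
        )
        res = run_automated_pipeline(scene.channels)
        assert res.n_coloc == 20
        assert set(res.n_per_category) == {1, 2, 3}

    def test_illumination_gradient_handled(self):
        scene = generate_scene(
            SceneSpec(
                n_nuclei=40, coloc_fraction=1.0, seed=21,
                illumination=(0.6, 0.5, 0.3, 0.0, 0.0, 0.0),
            )
        )
        res = run_automated_pipeline(scene.channels, illum="divide")
        assert res.n_coloc == 40


class TestSemiAutoPipeline:
    CFGS = [MaximaConfig(pre_blur_radius=2.0, noise_tolerance=60.0)] * 2

    def test_easy_scene_recovers_all_colocalized_pairs(self):
        scene = generate_scene(SceneSpec(n_nuclei=50, coloc_fraction=1.0, seed=3))
        res = run_semiauto_pipeline(scene.channels, self.CFGS)
        assert res.n_coloc == 50

    def test_removal_edits_reduce_count(self):
        # tight overlay radii so each nucleus can only pair with its own
        # marker (nuclei are >= 24 px apart, markers within 3 px of theirs)
        from obcacount.colocalize import ColocConfig

        tight = ColocConfig(mode="overlay", overlay_radius={1: 5.0, 2: 5.0})
        scene = generate_scene(SceneSpec(n_nuclei=10, coloc_fraction=1.0, seed=13))
        base = run_semiauto_pipeline(scene.channels, self.CFGS, coloc_cfg=tight)
        assert base.n_coloc == 10
        # removing a nucleus's only partner drops the count by exactly one
        targets = [tuple(p) for p in scene.truth_centers[1][:3]]
        edited = run_semiauto_pipeline(
            scene.channels, self.CFGS,
            edits=[None, {"remove": targets, "snap_radius": 4.0}],
            coloc_cfg=tight,
        )
        assert edited.n_coloc == base.n_coloc - 3

    def test_empty_images_count_zero(self):
        blank = ChannelImage(np.zeros((128, 128), dtype=np.uint8), bit_depth=8)
        res = run_semiauto_pipeline([blank, blank], self.CFGS)
        assert res.n_coloc == 0
        assert res.n_per_category == {1: 0, 2: 0}
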
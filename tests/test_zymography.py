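"""Object segmentation and the total-protease-activity statistic, checked
against generator ground truth and brute-force voxel oracles."""

import numpy as np
import pytest

import ecmquant as eq
from ecmquant.errors import EmptySegmentationWarning

from conftest import bfs_component_count


def zero_background_stack(n_spots=5, seed=3, **kw):
    return eq.generate_spot_stack(
        eq.SpotStackParams(n_spots=n_spots, background_level=0.0, seed=seed, **kw)
    )


class TestSegmentObjects:
    def test_empty_stack_gives_no_objects(self):
        stack, _ = eq.generate_spot_stack(eq.SpotStackParams(n_spots=0, seed=0))
        assert eq.segment_objects(stack) == []

    def test_recovers_generator_ground_truth_exactly(self):
        stack, gt = zero_background_stack()
        min_amp = min(s["mean_intensity"] for s in gt)
        objs = eq.segment_objects(stack, threshold=min_amp / 2.0)
        assert len(objs) == len(gt)
        assert sorted(o.voxel_count for o in objs) == sorted(s["voxel_count"] for s in gt)
        assert sorted(o.volume_um3 for o in objs) == sorted(s["volume_um3"] for s in gt)

    def test_touching_spots_merge_into_one_component(self):
        """Two balls placed to touch are one 26-connected object; a BFS
        flood-fill oracle on the same mask agrees."""
        vox = np.zeros((16, 32, 32))
        zz, yy, xx = np.mgrid[0:16, 0:32, 0:32]
        for cy in (12.0, 17.0):  # centers 5 px apart, radius 3 -> overlap
            vox[(zz - 8.0) ** 2 + (yy - cy) ** 2 + (xx - 16.0) ** 2 <= 9.0] += 100.0
        stack = eq.ImageStack3D(vox)
        objs = eq.segment_objects(stack, threshold=50.0)
        assert len(objs) == 1
        assert bfs_component_count(vox > 50.0) == 1

    def test_min_voxels_filters_small_components(self):
        vox = np.zeros((4, 32, 32))
        vox[1, 4, 4] = 100.0  # single voxel speck
        vox[2, 10:14, 10:14] = 100.0  # 16-voxel plate
        objs = eq.segment_objects(eq.ImageStack3D(vox), threshold=50.0, min_voxels=5)
        assert len(objs) == 1
        assert objs[0].voxel_count == 16

    def test_fixed_threshold_outside_range_warns_empty(self):
        stack, _ = zero_background_stack()
        with pytest.warns(EmptySegmentationWarning):
            assert eq.segment_objects(stack, threshold=1e6) == []

    def test_volume_conservation_invariant(self):
        stack, _ = zero_background_stack(n_spots=6, seed=9)
        thr = 10.0
        objs = eq.segment_objects(stack, threshold=thr, min_voxels=1)
        assert sum(o.voxel_count for o in objs) == int((stack.voxels > thr).sum())


class TestMeanFluorescenceIntensity:
    @pytest.mark.parametrize(
        "means,expected",
        [([100.0, 200.0], 150.0), ([], 0.0), ([42.0], 42.0)],
    )
    def test_unweighted_mean_of_object_means(self, means, expected):
        objs = [
            eq.FluorObject(voxel_count=10, volume_um3=10.0, mean_intensity=m, centroid=(0, 0, 0))
            for m in means
        ]
        assert eq.mean_fluorescence_intensity(objs) == expected

    def test_voxel_weighted_variant_differs(self):
        objs = [
            eq.FluorObject(voxel_count=1, volume_um3=1.0, mean_intensity=100.0, centroid=(0, 0, 0)),
            eq.FluorObject(voxel_count=9, volume_um3=9.0, mean_intensity=200.0, centroid=(0, 0, 0)),
        ]
        assert eq.mean_fluorescence_intensity(objs) == 150.0
        assert eq.mean_fluorescence_intensity(objs, voxel_weighted=True) == 190.0


class TestTotalProteaseActivity:
    def test_direct_substitution_example(self):
        stack = eq.ImageStack3D(np.zeros((10, 10, 10)))  # image volume 1000 um3
        obj = eq.FluorObject(voxel_count=50, volume_um3=50.0, mean_intensity=100.0, centroid=(0, 0, 0))
        res = eq.total_protease_activity([obj], stack)
        assert res.total_activity == 5.0

    def test_no_objects_zero_activity(self):
        stack, _ = eq.generate_spot_stack(eq.SpotStackParams(n_spots=0, seed=0))
        res = eq.total_protease_activity([], stack)
        assert res.total_activity == 0.0

    def test_matches_brute_force_voxel_recomputation(self):
        """Per-object means averaged x summed volumes / stack volume,
        recomputed from raw voxels and ground-truth membership."""
        stack, gt = zero_background_stack(n_spots=5, seed=11)
        min_amp = min(s["mean_intensity"] for s in gt)
        objs = eq.segment_objects(stack, threshold=min_amp / 2.0)
        res = eq.total_protease_activity(objs, stack)

        per_object_means = []
        total_vox = 0
        for spot in gt:
            c = spot["voxels"]
            per_object_means.append(stack.voxels[c[:, 0], c[:, 1], c[:, 2]].mean())
            total_vox += len(c)
        expected = (
            np.mean(per_object_means)
            * (total_vox * stack.voxel_volume_um3)
            / stack.image_volume_um3
        )
        assert res.total_activity == pytest.approx(expected, abs=1e-9)

    def test_intensity_scaling_scales_activity_not_volume(self):
        stack, gt = zero_background_stack(seed=5)
        thr = min(s["mean_intensity"] for s in gt) / 2.0
        r1 = eq.total_protease_activity(eq.segment_objects(stack, threshold=thr), stack)
        scaled = eq.ImageStack3D(3.0 * stack.voxels, stack.voxel_size_um)
        r2 = eq.total_protease_activity(eq.segment_objects(scaled, threshold=3.0 * thr), scaled)
        assert r2.total_volume_um3 == r1.total_volume_um3
        assert r2.mean_fluorescence_intensity == pytest.approx(3.0 * r1.mean_fluorescence_intensity)
        assert r2.total_activity == pytest.approx(3.0 * r1.total_activity)

    def test_pure_background_padding_dilutes_activity(self):
        stack, gt = zero_background_stack(seed=6)
        thr = min(s["mean_intensity"] for s in gt) / 2.0
        objs = eq.segment_objects(stack, threshold=thr)
        base = eq.total_protease_activity(objs, stack).total_activity
        padded = eq.ImageStack3D(
            np.concatenate([stack.voxels, np.zeros_like(stack.voxels)], axis=0),
            stack.voxel_size_um,
        )
        diluted = eq.total_protease_activity(objs, padded).total_activity
        assert diluted < base
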
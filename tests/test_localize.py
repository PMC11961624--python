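import dataclasses

import numpy as np
import pytest

from coroscreen.localize import (compute_crop_box, crop_case, crop_volume, find_root_point,
                                 naive_segment)
from coroscreen.phantom import PhantomConfig, generate_phantom
from coroscreen.volume import ImageVolume, Label


def _sphere(shape, center, radius):
    idx = np.indices(shape)
    return np.sum((idx - np.asarray(center)[:, None, None, None]) ** 2, axis=0) <= radius**2


class TestFindRootPoint:
    def test_tangent_spheres_contact_at_known_voxel(self):
        """Two spheres touching at exactly one voxel: the root point is that
        voxel's world coordinate and the adjusted point adds (10, 0, 10) mm."""
        shape = (40, 40, 40)
        a = _sphere(shape, (14, 20, 20), 5)      # rightmost voxel at x=19
        b = _sphere(shape, (25, 20, 20), 5)      # leftmost voxel at x=20
        spacing, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
        root = find_root_point(a, b, spacing, origin)
        # contact set = {(19,20,20), (20,20,20)}; centroid at x=19.5
        assert np.allclose(root.point_mm, (19.5, 20.0, 20.0))
        assert np.allclose(root.adjusted_point_mm, (29.5, 20.0, 30.0))

    def test_identical_masks_give_common_centroid(self):
        m = _sphere((30, 30, 30), (15, 15, 15), 6)
        root = find_root_point(m, m, (2.0, 2.0, 2.0), (-10.0, 0.0, 0.0))
        com = np.array(np.nonzero(m), dtype=float).mean(axis=1)
        assert np.allclose(root.point_mm, com * 2.0 + np.array([-10.0, 0.0, 0.0]))

    def test_distant_masks_raise(self):
        a = _sphere((40, 40, 40), (8, 20, 20), 4)
        b = _sphere((40, 40, 40), (30, 20, 20), 4)   # 10 voxels of gap
        with pytest.raises(ValueError, match="no aorto-ventricular contact"):
            find_root_point(a, b, (1, 1, 1), max_dilation=3)

    def test_empty_mask_raises(self):
        m = _sphere((20, 20, 20), (10, 10, 10), 4)
        with pytest.raises(ValueError, match="non-empty"):
            find_root_point(np.zeros_like(m), m, (1, 1, 1))

    def test_zero_offset_centers_box_on_contact(self):
        a = _sphere((40, 40, 40), (14, 20, 20), 5)
        b = _sphere((40, 40, 40), (25, 20, 20), 5)
        root = find_root_point(a, b, (1, 1, 1), offset_mm=(0, 0, 0))
        assert np.allclose(root.adjusted_point_mm, root.point_mm)


class TestCropBox:
    def test_default_extent_is_80_80_60(self):
        from coroscreen.localize import DEFAULT_EXTENT_MM
        assert DEFAULT_EXTENT_MM == (80.0, 80.0, 60.0)

    @pytest.mark.parametrize("spacing,expected", [
        ((1.0, 1.0, 1.0), (80, 80, 60)),
        ((0.5, 0.5, 1.0), (160, 160, 60)),
        ((1.25, 1.25, 1.25), (64, 64, 48)),
    ])
    def test_voxel_extent_from_spacing(self, spacing, expected):
        grid = ImageVolume(np.zeros((256, 256, 128), dtype=np.float32), spacing=spacing)
        from coroscreen.localize import RootPoint
        root = RootPoint((0, 0, 0), (120.0, 120.0, 70.0))
        box = compute_crop_box(root, grid)
        assert box.voxel_shape == expected

    def test_rejects_nonpositive_extent(self):
        from coroscreen.localize import RootPoint
        grid = ImageVolume(np.zeros((10, 10, 10), dtype=np.float32))
        with pytest.raises(ValueError):
            compute_crop_box(RootPoint((0, 0, 0), (5, 5, 5)), grid, extent_mm=(0, 10, 10))


class TestCropVolume:
    def _vol(self, shape=(60, 60, 40)):
        rng = np.random.default_rng(0)
        return ImageVolume(rng.normal(size=shape).astype(np.float32))

    def test_interior_box_is_pure_indexing(self):
        vol = self._vol()
        from coroscreen.localize import RootPoint
        root = RootPoint((0, 0, 0), (30.0, 30.0, 20.0))
        box = compute_crop_box(root, vol, extent_mm=(20, 20, 10))
        out = crop_volume(vol, box)
        assert out.shape == box.voxel_shape
        s, e = box.voxel_start, box.voxel_stop
        assert np.array_equal(out.data, vol.data[s[0]:e[0], s[1]:e[1], s[2]:e[2]])
        assert out.origin == tuple(float(v) for v in s)

    def test_corner_box_pads_exactly_the_outside_octant(self):
        vol = self._vol()
        from coroscreen.localize import RootPoint
        root = RootPoint((0, 0, 0), (0.0, 0.0, 0.0))   # image corner
        box = compute_crop_box(root, vol, extent_mm=(20, 20, 20))
        out = crop_volume(vol, box, pad_value=-1024.0)
        padded = out.data == -1024.0
        # box spans [-10, 10) per axis: exactly the 7 outside octants padded
        expected_frac = 1.0 - (10 / 20) ** 3
        assert abs(padded.mean() - expected_frac) < 1e-12

    def test_padded_mean_matches_overlap_fraction(self):
        vol = ImageVolume(np.zeros((40, 40, 40), dtype=np.float32))
        from coroscreen.localize import RootPoint
        root = RootPoint((0, 0, 0), (0.0, 20.0, 20.0))  # half outside in x
        box = compute_crop_box(root, vol, extent_mm=(20, 20, 20))
        out = crop_volume(vol, box, pad_value=-1024.0)
        assert np.isclose(out.data.mean(), -1024.0 * 0.5)

    def test_fully_outside_box_raises(self):
        vol = self._vol()
        from coroscreen.localize import RootPoint
        root = RootPoint((0, 0, 0), (500.0, 500.0, 500.0))
        box = compute_crop_box(root, vol, extent_mm=(10, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            crop_volume(vol, box)


@pytest.fixture(scope="module")
def noisefree():
    return generate_phantom(PhantomConfig(noise_sigma_hu=0.0, seed=2))


class TestPhantomIntegration:
    def test_naive_segment_dice_against_ground_truth(self, normal_record):
        seg = naive_segment(normal_record.volumes[0])
        for lab in (Label.AORTA, Label.LV_CAVITY):
            gt = normal_record.label_map.mask(lab)
            pr = seg.mask(lab)
            dice = 2 * (gt & pr).sum() / (gt.sum() + pr.sum())
            assert dice >= 0.95, Label.NAMES[lab]

    def test_all_air_volume_raises(self):
        vol = ImageVolume(np.full((32, 32, 32), -1000.0, dtype=np.float32))
        with pytest.raises(ValueError, match="contrast"):
            naive_segment(vol)

    def test_ground_truth_and_naive_paths_agree_on_noise_free_phantom(self, noisefree):
        vol = noisefree.volumes[0]
        root_gt = find_root_point(noisefree.label_map.mask(Label.AORTA),
                                  noisefree.label_map.mask(Label.LV_CAVITY),
                                  vol.spacing, vol.origin)
        seg = naive_segment(vol)
        root_seg = find_root_point(seg.mask(Label.AORTA), seg.mask(Label.LV_CAVITY),
                                   vol.spacing, vol.origin)
        box_gt = compute_crop_box(root_gt, vol)
        box_seg = compute_crop_box(root_seg, vol)
        assert np.all(np.abs(np.array(box_gt.voxel_start) - box_seg.voxel_start) <= 1)

    def test_crop_translation_equivariance(self, noisefree):
        """Shifting the masks by whole voxels shifts voxel_start equally."""
        vol = noisefree.volumes[0]
        aorta = noisefree.label_map.mask(Label.AORTA)
        lv = noisefree.label_map.mask(Label.LV_CAVITY)
        root = find_root_point(aorta, lv, vol.spacing, vol.origin)
        box = compute_crop_box(root, vol, extent_mm=(40, 40, 30))
        shift = (3, 2, 1)
        aorta_s = np.roll(aorta, shift, axis=(0, 1, 2))
        lv_s = np.roll(lv, shift, axis=(0, 1, 2))
        root_s = find_root_point(aorta_s, lv_s, vol.spacing, vol.origin)
        box_s = compute_crop_box(root_s, vol, extent_mm=(40, 40, 30))
        assert tuple(np.array(box_s.voxel_start) - box.voxel_start) == shift

    def test_crop_physical_size_within_one_voxel(self, noisefree):
        for spacing_scale in (1.0, 1.6):
            vol = dataclasses.replace(
                noisefree.volumes[0],
                data=noisefree.volumes[0].data,
                spacing=tuple(s * spacing_scale for s in noisefree.volumes[0].spacing))
            labels = dataclasses.replace(noisefree.label_map, data=noisefree.label_map.data,
                                         spacing=vol.spacing)
            crop = crop_case(vol, labels)
            size = np.asarray(crop.shape) * np.asarray(vol.spacing)
            assert np.all(np.abs(size - (80, 80, 60)) <= np.asarray(vol.spacing))
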
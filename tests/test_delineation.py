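import numpy as np
import pytest

from imquant.delineation import (CannySpec, PropagationSpec, Rectangle2D, Seed,
                                 canny_edges, init_interactive, morph_modify,
                                 propagate_annotation, roi_boolean,
                                 roi_duplicate, roi_separate, update_with_seeds)
from imquant.grid import ImageVolume, LabelMask
from imquant.phantoms import PhantomSpec, make_geometric_phantom


def disk_slice(radius=12, size=64, fg=200.0, bg=10.0, noise=5.0, seed=0):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    img = np.where(disk, fg, bg) + np.random.default_rng(seed).normal(0, noise, (size, size))
    return img, disk


def dice2d(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestCanny:
    def test_constant_image_has_no_edges(self):
        assert not canny_edges(np.full((20, 20), 7.0)).any()

    def test_vertical_step_gives_thin_vertical_line(self):
        img = np.zeros((21, 21))
        img[:, 11:] = 100.0
        edges = canny_edges(img, CannySpec(gaussian_sigma=1.0))
        cols = np.unique(np.nonzero(edges)[1])
        assert len(cols) <= 2  # thin line at the step
        assert edges.sum() >= 15  # spans (nearly) the full height

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CannySpec(low_threshold=5.0, high_threshold=1.0)


class TestInteractive:
    def test_disk_segmentation_accuracy_and_seed_layout(self):
        img, disk = disk_slice()
        rect = Rectangle2D(0, (14, 14), (50, 50))
        mask, seeds = init_interactive(img, rect)
        assert dice2d(mask, disk) >= 0.90
        assert sum(s.polarity == "positive" for s in seeds) == 1
        assert [s.position for s in seeds if s.polarity == "negative"] == rect.vertices
        # mask confined to the rectangle
        outside = np.ones_like(mask)
        outside[14:51, 14:51] = False
        assert not (mask & outside).any()

    def test_flat_rectangle_returns_empty_mask_and_seeds(self, caplog):
        img = np.full((40, 40), 5.0)
        rect = Rectangle2D(0, (5, 5), (30, 30))
        mask, seeds = init_interactive(img, rect)
        assert not mask.any()
        assert len(seeds) == 5

    def test_update_is_deterministic_and_respects_polarity(self):
        img, disk = disk_slice(seed=3)
        rect = Rectangle2D(0, (14, 14), (50, 50))
        seeds = [Seed((32, 32), "positive"), Seed((20, 40), "negative")]
        m1 = update_with_seeds(img, rect, seeds)
        m2 = update_with_seeds(img, rect, seeds)
        np.testing.assert_array_equal(m1, m2)
        assert m1[32, 32]
        assert not m1[20, 40]

    def test_negative_seed_removes_region(self):
        img, _ = disk_slice(seed=4)
        rect = Rectangle2D(0, (14, 14), (50, 50))
        base = update_with_seeds(img, rect, [Seed((32, 32), "positive")])
        inside = np.argwhere(base)
        pick = tuple(inside[len(inside) // 3])
        upd = update_with_seeds(img, rect, [Seed((32, 32), "positive"),
                                            Seed(pick, "negative")])
        assert not upd[pick]

    def test_two_disks_with_two_positive_seeds(self):
        yy, xx = np.mgrid[0:64, 0:64]
        d1 = (yy - 25) ** 2 + (xx - 20) ** 2 <= 8**2
        d2 = (yy - 40) ** 2 + (xx - 45) ** 2 <= 8**2
        img = np.where(d1 | d2, 200.0, 10.0) \
            + np.random.default_rng(0).normal(0, 4, (64, 64))
        rect = Rectangle2D(0, (10, 8), (55, 58))
        mask = update_with_seeds(img, rect, [Seed((25, 20), "positive"),
                                             Seed((40, 45), "positive")])
        assert dice2d(mask, d1 | d2) >= 0.9

    def test_seed_polarity_contracts_hold_for_random_placements(self):
        img, disk = disk_slice(seed=5)
        rect = Rectangle2D(0, (14, 14), (50, 50))
        rng = np.random.default_rng(11)
        for _ in range(10):
            pos = tuple(rng.integers(20, 45, 2))
            neg = tuple(rng.integers(15, 50, 2))
            if pos == neg:
                continue
            mask = update_with_seeds(img, rect, [Seed(pos, "positive"),
                                                 Seed(neg, "negative")])
            assert mask[pos] and not mask[neg]

    def test_positive_seed_required(self):
        img, _ = disk_slice()
        with pytest.raises(ValueError, match="positive"):
            update_with_seeds(img, Rectangle2D(0, (14, 14), (50, 50)),
                              [Seed((20, 20), "negative")])


class TestPropagation:
    @pytest.fixture
    def sphere(self):
        return make_geometric_phantom(
            PhantomSpec(shape=(40, 40, 40), radius_mm=12.0, noise_sd=5.0, seed=2))

    def test_slicewise_dice_on_sphere(self, sphere):
        vol, mask3d, _ = sphere
        z0 = 20
        out = propagate_annotation(vol, mask3d.data[z0] > 0, z0, PropagationSpec())
        for z in range(40):
            true = mask3d.data[z] > 0
            if true.sum() == 0 or abs(z - z0) > 9:  # within 2 slices of poles
                continue
            assert dice2d(out.data[z] > 0, true) >= 0.80, f"slice {z}"

    def test_halts_beyond_object(self, sphere):
        vol, mask3d, _ = sphere
        out = propagate_annotation(vol, mask3d.data[20] > 0, 20, PropagationSpec())
        for z in range(40):
            if (mask3d.data[z] > 0).sum() == 0:
                # may overrun by the dilation margin only; never empty-marked
                assert out.data[z].sum() == 0 or (out.data[z] > 0).sum() > 0

    def test_keep_largest_leaves_single_component(self):
        from scipy import ndimage

        vol_data = np.full((5, 30, 30), 0.0)
        vol_data[0, 10:20, 5:25] = 100.0
        vol_data[1, 10:20, 5:12] = 100.0
        vol_data[1, 10:20, 18:25] = 100.0
        vol = ImageVolume(vol_data)
        start = vol_data[0] > 0
        out = propagate_annotation(vol, start, 0,
                                   PropagationSpec(direction="up",
                                                   keep_component="largest"))
        _, n = ndimage.label(out.data[1] > 0)
        assert n == 1

    def test_empty_start_rejected(self, sphere):
        vol, _, _ = sphere
        with pytest.raises(ValueError):
            propagate_annotation(vol, np.zeros((40, 40), bool), 20)


class TestMorphology:
    def test_zero_distance_identity(self, noisy_sphere):
        _, mask, _ = noisy_sphere
        out = morph_modify(mask, "dilate", (0, 0, 0))
        np.testing.assert_array_equal(out.binary(), mask.binary())

    def test_dilated_sphere_volume(self):
        _, mask, _ = make_geometric_phantom(
            PhantomSpec(shape=(56, 56, 56), spacing=(0.5, 0.5, 0.5),
                        radius_mm=10.0))
        out = morph_modify(mask, "dilate", (2.0, 2.0, 2.0))
        expected = 4.0 / 3.0 * np.pi * 12.0**3
        got = out.binary().sum() * 0.125
        assert abs(got - expected) < 0.05 * expected

    def test_erosion_empties_thin_slab(self, caplog):
        data = np.zeros((10, 20, 20), dtype=np.int16)
        data[4:7] = 1  # 3 voxels thick at 1 mm
        mask = LabelMask(data)
        out = morph_modify(mask, "erode", (5.0, 5.0, 5.0))
        assert not out.binary().any()

    def test_extensive_antiextensive_and_closing(self, noisy_sphere):
        _, mask, _ = noisy_sphere
        d = morph_modify(mask, "dilate", (2, 1, 2))
        e = morph_modify(mask, "erode", (2, 1, 2))
        assert (d.binary() | mask.binary()).sum() == d.binary().sum()
        assert (e.binary() & mask.binary()).sum() == e.binary().sum()
        closed = morph_modify(d, "erode", (2, 1, 2))
        assert not (mask.binary() & ~closed.binary()).any()


class TestBoolean:
    def rand_masks(self, seed, n=3):
        r = np.random.default_rng(seed)
        return [LabelMask((r.random((8, 8, 8)) > 0.5).astype(np.int16))
                for _ in range(n)]

    def test_union_idempotent(self):
        a, *_ = self.rand_masks(0)
        out = roi_boolean([a, a], "union")
        np.testing.assert_array_equal(out.binary(), a.binary())

    def test_complement_identity(self):
        for seed in range(5):
            a, b, _ = self.rand_masks(seed)
            inner = roi_boolean([a, b], "complement")
            out = roi_boolean([a, inner], "complement")
            np.testing.assert_array_equal(out.binary(), a.binary() & b.binary())

    def test_de_morgan_on_random_masks(self):
        for seed in range(5):
            a, b, u = self.rand_masks(seed)
            u = LabelMask(np.ones((8, 8, 8), dtype=np.int16))
            lhs = roi_boolean([u, roi_boolean([a, b], "union")], "complement")
            rhs = roi_boolean([roi_boolean([u, a], "complement"),
                               roi_boolean([u, b], "complement")], "intersection")
            np.testing.assert_array_equal(lhs.binary(), rhs.binary())

    def test_disjoint_intersection_empty(self):
        z = np.zeros((4, 4, 4), dtype=np.int16)
        a = z.copy(); a[0] = 1
        b = z.copy(); b[3] = 1
        out = roi_boolean([LabelMask(a), LabelMask(b)], "intersection")
        assert not out.binary().any()

    def test_grid_mismatch_rejected(self):
        a = LabelMask(np.ones((4, 4, 4), dtype=np.int16))
        b = LabelMask(np.ones((4, 4, 4), dtype=np.int16), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            roi_boolean([a, b], "union")


class TestSeparate:
    def test_intensity_split_matches_populations(self):
        data = np.full((6, 6, 6), 100.0)
        data[3:] = 300.0
        vol = ImageVolume(data)
        mask = LabelMask(np.ones((6, 6, 6), dtype=np.int16))
        out = roi_separate(mask, vol, "intensity_intervals", intervals=[200.0])
        assert set(np.unique(out.data[:3])) == {1}
        assert set(np.unique(out.data[3:])) == {2}

    def test_two_blobs_two_labels(self):
        data = np.zeros((10, 10, 10), dtype=np.int16)
        data[1:3, 1:3, 1:3] = 1
        data[7:9, 7:9, 7:9] = 1
        out = roi_separate(LabelMask(data), by="connectivity", connectivity=26)
        assert len(out.labels) == 2

    def test_min_size_above_largest_empties(self):
        data = np.zeros((6, 6, 6), dtype=np.int16)
        data[0:2, 0:2, 0:2] = 1
        out = roi_separate(LabelMask(data), by="min_size", min_size=100)
        assert not out.binary().any()

    def test_unsorted_intervals_rejected(self):
        mask = LabelMask(np.ones((4, 4, 4), dtype=np.int16))
        vol = ImageVolume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            roi_separate(mask, vol, "intensity_intervals", intervals=[3.0, 1.0])


class TestDuplicate:
    def test_same_grid_identity(self, noisy_sphere):
        vol, mask, _ = noisy_sphere
        out = roi_duplicate(mask, vol)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_finer_grid_round_trip_dice(self, noisy_sphere):
        vol, mask, _ = noisy_sphere
        fine = ImageVolume(np.zeros((80, 80, 80)), spacing=(0.5, 0.5, 0.5))
        up = roi_duplicate(mask, fine)
        back = roi_duplicate(up, vol)
        inter = (back.binary() & mask.binary()).sum()
        dice = 2 * inter / (back.binary().sum() + mask.binary().sum())
        assert dice >= 0.95

    def test_whole_voxel_translation_shifts_mask(self, noisy_sphere):
        vol, mask, _ = noisy_sphere
        target = ImageVolume(np.zeros_like(vol.data), origin=(3.0, 0.0, 0.0))
        out = roi_duplicate(mask, target)
        np.testing.assert_array_equal(out.data[:, :, :-3], mask.data[:, :, 3:])

    def test_zero_overlap_rejected(self, noisy_sphere):
        vol, mask, _ = noisy_sphere
        far = ImageVolume(np.zeros((10, 10, 10)), origin=(500.0, 500.0, 500.0))
        with pytest.raises(ValueError, match="overlap"):
            roi_duplicate(mask, far)
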
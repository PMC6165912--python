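import numpy as np
import pytest
from scipy import stats

from parotidseg.netarch import ArchSpec
from parotidseg.sampling import (
    SamplingConfig,
    compute_roi,
    sample_balanced_patches,
    sample_roi_slices,
    select_training_subsets,
)
from parotidseg.volume_io import BinaryMask, GridGeometry, VolumeGrid


def _mask_with_fg(shape, lo, hi, axis=2):
    """Foreground on slices lo..hi (inclusive) along the given axis."""
    vox = np.zeros(shape, bool)
    sl = [slice(s // 2, s // 2 + 1) for s in shape]
    sl[axis] = slice(lo, hi + 1)
    vox[tuple(sl)] = True
    return BinaryMask(vox, GridGeometry(shape, (1.0, 1.0, 2.0)))


class TestComputeRoi:
    def test_axial_margin_arithmetic(self):
        mask = _mask_with_fg((10, 10, 100), 40, 49, axis=2)
        roi = compute_roi(mask, SamplingConfig(view="axial"))
        assert roi.intervals[2] == (35, 55)
        assert roi.intervals[0] == (0, 10) and roi.intervals[1] == (0, 10)

    def test_clipped_at_volume_start(self):
        mask = _mask_with_fg((10, 10, 30), 0, 3, axis=2)
        roi = compute_roi(mask, SamplingConfig(view="axial"))
        assert roi.intervals[2] == (0, 9)

    def test_sagittal_transverse_restriction(self):
        vox = np.zeros((40, 10, 200), bool)
        vox[18:22, 4:6, 30:40] = True
        mask = BinaryMask(vox, GridGeometry((40, 10, 200), (1, 1, 2)))
        roi = compute_roi(mask, SamplingConfig(view="sagittal"))
        assert roi.intervals[0] == (13, 27)  # 18-5, 21+5+1
        assert roi.intervals[2] == (5, 65)  # 30-25, 39+25+1
        assert roi.intervals[1] == (0, 10)

    def test_empty_mask_rejected(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), GridGeometry((5, 5, 5), (1, 1, 1)))
        with pytest.raises(ValueError, match="empty"):
            compute_roi(mask, SamplingConfig())

    @pytest.mark.parametrize("view", ["axial", "coronal", "sagittal"])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, view, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(12, 40, 3))
        vox = np.zeros(shape, bool)
        n = rng.integers(1, 20)
        idx = tuple(rng.integers(0, s, n) for s in shape)
        vox[idx] = True
        mask = BinaryMask(vox, GridGeometry(shape, (1, 1, 2)))
        cfg = SamplingConfig(view=view)
        roi = compute_roi(mask, cfg)
        from parotidseg.sampling import VIEW_AXES

        ax = VIEW_AXES[view]
        fg = [i for i in range(shape[ax]) if np.take(vox, i, axis=ax).any()]
        lo = max(0, fg[0] - 5)
        hi = min(shape[ax], fg[-1] + 6)
        assert roi.intervals[ax] == (lo, hi)


class TestSampleRoiSlices:
    @pytest.fixture()
    def case(self):
        rng = np.random.default_rng(7)
        shape = (24, 24, 60)
        vol = VolumeGrid(rng.normal(0, 50, shape).astype(np.float32), (1, 1, 2))
        vox = np.zeros(shape, bool)
        vox[10:16, 10:16, 25:33] = True
        return vol, BinaryMask(vox, vol.geometry)

    def test_indices_within_roi(self, case):
        vol, mask = case
        cfg = SamplingConfig(view="axial", rng_seed=0)
        roi = compute_roi(mask, cfg)
        lo, hi = roi.intervals[2]
        rng = np.random.default_rng(0)
        pairs = sample_roi_slices(vol, mask, cfg, n=1000, rng=rng)
        assert len(pairs) == 1000
        # every drawn slice must be reproducible from an in-ROI index
        for img, lab in pairs[:50]:
            assert img.shape == lab.shape

    def test_deterministic_under_seed(self, case):
        vol, mask = case
        cfg = SamplingConfig(view="coronal", rng_seed=123)
        a = sample_roi_slices(vol, mask, cfg, n=20)
        b = sample_roi_slices(vol, mask, cfg, n=20)
        for (ia, la), (ib, lb) in zip(a, b):
            assert np.array_equal(ia, ib) and np.array_equal(la, lb)

    def test_uniform_over_roi(self, case):
        vol, mask = case
        cfg = SamplingConfig(view="axial", rng_seed=5)
        roi = compute_roi(mask, cfg)
        lo, hi = roi.intervals[2]
        # identify each sampled index by tagging the volume with its z-index
        tagged = VolumeGrid(
            np.broadcast_to(np.arange(vol.shape[2], dtype=np.float32), vol.shape).copy(),
            vol.spacing,
        )
        pairs = sample_roi_slices(tagged, mask, cfg, n=10000)
        idxs = np.array([int(img[0, 0]) for img, _ in pairs])
        assert idxs.min() >= lo and idxs.max() < hi
        counts = np.bincount(idxs - lo, minlength=hi - lo)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestBalancedPatches:
    @pytest.fixture()
    def case(self):
        rng = np.random.default_rng(8)
        shape = (48, 48, 40)
        vol = VolumeGrid(rng.normal(0, 50, shape).astype(np.float32), (1, 1, 2))
        vox = np.zeros(shape, bool)
        vox[20:30, 18:28, 16:24] = True
        return vol, BinaryMask(vox, vol.geometry)

    ARCH = ArchSpec(dimensionality=3)
    CFG = SamplingConfig(patch_extent=(48, 48, 48), batch_size=8, fg_fraction=0.5)

    def test_exact_fg_count_every_batch(self, case):
        vol, mask = case
        rng = np.random.default_rng(0)
        for _ in range(100):
            batch = sample_balanced_patches(vol, mask, self.CFG, arch=self.ARCH, rng=rng)
            n_fg = sum(1 for _, lab in batch if lab.any())
            assert n_fg == self.CFG.foreground_per_batch == 4

    def test_fg_zero_plain_uniform(self, case):
        vol, mask = case
        cfg = SamplingConfig(patch_extent=(48, 48, 48), batch_size=8, fg_fraction=0.0)
        empty = BinaryMask(np.zeros(vol.shape, bool), vol.geometry)
        batch = sample_balanced_patches(vol, empty, cfg, arch=self.ARCH, rng=np.random.default_rng(1))
        assert len(batch) == 8

    def test_no_fg_with_positive_fraction_errors(self, case):
        vol, _ = case
        empty = BinaryMask(np.zeros(vol.shape, bool), vol.geometry)
        with pytest.raises(ValueError, match="no foreground"):
            sample_balanced_patches(vol, empty, self.CFG, arch=self.ARCH)

    def test_shapes(self, case):
        vol, mask = case
        batch = sample_balanced_patches(vol, mask, self.CFG, arch=self.ARCH,
                                        rng=np.random.default_rng(2))
        for patch, lab in batch:
            assert patch.shape == (48, 48, 48)
            assert lab.shape == (8, 8, 8)

    def test_deterministic_under_seed(self, case):
        vol, mask = case
        cfg = SamplingConfig(patch_extent=(48, 48, 48), batch_size=4, rng_seed=9)
        a = sample_balanced_patches(vol, mask, cfg, arch=self.ARCH)
        b = sample_balanced_patches(vol, mask, cfg, arch=self.ARCH)
        for (pa, la), (pb, lb) in zip(a, b):
            assert np.array_equal(pa, pb) and np.array_equal(la, lb)

    def test_fg_centers_within_dilated_bounding_box(self):
        # geometric necessity: a center overlapping foreground must start
        # within the mask bounding box dilated by the center extent; tag
        # the volume with its linear voxel index to recover patch positions
        shape = (40, 40, 40)
        tag = np.arange(np.prod(shape), dtype=np.float32).reshape(shape)
        vol = VolumeGrid(tag, (1, 1, 1))
        vox = np.zeros(shape, bool)
        vox[15:20, 12:18, 22:26] = True
        mask = BinaryMask(vox, vol.geometry)
        cfg = SamplingConfig(patch_extent=(44, 44, 44), batch_size=6, fg_fraction=1.0)
        center = np.array([4, 4, 4])
        margin = np.array([20, 20, 20])
        bb_lo = np.array([15, 12, 22]) - (center - 1)
        bb_hi = np.array([19, 17, 25])
        rng = np.random.default_rng(4)
        for _ in range(20):
            batch = sample_balanced_patches(vol, mask, cfg, arch=self.ARCH, rng=rng)
            for patch, lab in batch:
                assert lab.any()
                # the patch center voxel is never in a mirrored border region
                mid = patch[tuple(margin + center // 2)]
                start = np.array(np.unravel_index(int(mid), shape)) - center // 2
                assert np.all(start >= bb_lo) and np.all(start <= bb_hi)


class TestTrainingSubsets:
    def test_nested(self):
        ids = [f"c{i}" for i in range(6)]
        subsets = select_training_subsets(ids, [2, 4], seed=0)
        assert set(subsets[2]) <= set(subsets[4])
        assert len(subsets[2]) == 2 and len(subsets[4]) == 4

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(20)]
        assert select_training_subsets(ids, [5, 10], seed=3) == select_training_subsets(
            ids, [5, 10], seed=3
        )

    def test_paper_scale_sizes(self):
        ids = [f"case{i:03d}" for i in range(467)]
        sizes = [50, 150, 250, 350, 450]
        subsets = select_training_subsets(ids, sizes, seed=1)
        for s in sizes:
            assert len(subsets[s]) == s
        for small, big in zip(sizes, sizes[1:]):
            assert set(subsets[small]) <= set(subsets[big])

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="available"):
            select_training_subsets(["a", "b"], [3], seed=0)
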
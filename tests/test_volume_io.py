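import numpy as np
import pytest

from parotidseg.volume_io import (
    BinaryMask,
    GridGeometry,
    VolumeFormatError,
    VolumeGrid,
    VolumeIOError,
    apply_body_mask,
    mirror_pad,
    mirror_sagittal,
    read_mask,
    read_volume,
    remove_couch,
    resample_mask_to_grid,
    resample_transverse,
    write_mask,
    write_volume,
)


def _random_volume(rng, shape=(9, 8, 7), spacing=(1.0, 1.0, 3.0)):
    return VolumeGrid(
        rng.normal(0, 100, size=shape).astype(np.float32), spacing, (1.0, -2.0, 3.0)
    )


class TestReadWrite:
    @pytest.mark.parametrize("suffix", [".nii", ".nii.gz", ".mha"])
    def test_round_trip(self, tmp_path, suffix):
        rng = np.random.default_rng(0)
        vol = _random_volume(rng)
        path = str(tmp_path / f"vol{suffix}")
        write_volume(vol, path)
        back = read_volume(path)
        assert back.shape == vol.shape
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert np.allclose(back.voxels, vol.voxels, atol=1e-3)

    def test_spacing_from_header(self, tmp_path):
        vol = _random_volume(np.random.default_rng(1), spacing=(1.0, 1.0, 3.0))
        path = str(tmp_path / "v.nii.gz")
        write_volume(vol, path)
        assert read_volume(path).spacing == (1.0, 1.0, 3.0)

    def test_4d_file_rejected(self, tmp_path):
        import nibabel as nib

        path = str(tmp_path / "v4.nii")
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4)), path)
        with pytest.raises(VolumeFormatError):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(VolumeIOError, match="nowhere"):
            read_volume(str(tmp_path / "nowhere.nii"))

    def test_meta_missing_spacing(self, tmp_path):
        path = tmp_path / "bad.mha"
        path.write_bytes(
            b"ObjectType = Image\nNDims = 3\nDimSize = 2 2 2\n"
            b"ElementType = MET_UCHAR\nElementDataFile = LOCAL\n" + bytes(8)
        )
        with pytest.raises(VolumeFormatError, match="ElementSpacing"):
            read_volume(str(path))

    def test_mask_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        vox = rng.random((6, 5, 4)) > 0.5
        mask = BinaryMask(vox, GridGeometry((6, 5, 4), (1, 1, 2)), "left")
        path = str(tmp_path / "m.nii.gz")
        write_mask(mask, path)
        back = read_mask(path, "left")
        assert np.array_equal(back.voxels, vox)
        assert back.laterality == "left"


class TestResampleTransverse:
    def test_identity_when_spacing_matches(self):
        vol = _random_volume(np.random.default_rng(3), spacing=(1, 1, 2.0))
        out = resample_transverse(vol, 2.0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_constant_preserved(self):
        vol = VolumeGrid(np.full((5, 5, 10), 37.0, np.float32), (1, 1, 3.0))
        out = resample_transverse(vol, 2.0)
        assert np.allclose(out.voxels, 37.0, atol=1e-5)

    def test_slice_count_from_physical_extent(self):
        # 31 slices at 3 mm span 90 mm; at 2 mm that grid holds floor(90/2)+1
        vol = VolumeGrid(np.zeros((4, 4, 31), np.float32), (1, 1, 3.0))
        out = resample_transverse(vol, 2.0)
        physical_extent = (vol.shape[2] - 1) * vol.spacing[2]
        assert out.shape[2] == int(physical_extent // 2.0) + 1 == 46

    def test_in_plane_untouched(self):
        vol = _random_volume(np.random.default_rng(4), shape=(7, 6, 12), spacing=(0.97, 0.97, 3.0))
        out = resample_transverse(vol, 2.0)
        assert out.shape[:2] == vol.shape[:2]
        assert out.spacing[:2] == vol.spacing[:2]
        # physical z-extent changes by less than one target spacing
        assert abs((out.shape[2] - 1) * 2.0 - (vol.shape[2] - 1) * 3.0) < 2.0

    def test_single_slice_error(self):
        vol = VolumeGrid(np.zeros((4, 4, 1), np.float32), (1, 1, 3.0))
        with pytest.raises(ValueError, match="single-slice"):
            resample_transverse(vol, 2.0)

    def test_interpolates_linear_ramp(self):
        # Lanczos reproduces a linear ramp away from the boundary
        z = np.arange(30, dtype=np.float32) * 3.0
        vol = VolumeGrid(np.broadcast_to(z, (4, 4, 30)).copy(), (1, 1, 3.0))
        out = resample_transverse(vol, 2.0)
        expect = np.arange(out.shape[2]) * 2.0
        interior = slice(4, -4)
        # renormalized Lanczos is close to (not exactly) linear-exact
        assert np.allclose(out.voxels[0, 0, interior], expect[interior], atol=0.1)


def _brute_force_nearest(mask: BinaryMask, target: GridGeometry) -> np.ndarray:
    """Exhaustive nearest-center search; ties go to the lower index, and a
    position whose nearest candidate would be a (virtual) voxel outside the
    source grid is background."""
    src = mask.grid
    out = np.zeros(target.shape, dtype=bool)
    src_centers = [src.voxel_centers(ax) for ax in range(3)]
    for idx in np.ndindex(*target.shape):
        phys = [target.origin[ax] + idx[ax] * target.spacing[ax] for ax in range(3)]
        nearest = []
        inside = True
        for ax in range(3):
            half = src.spacing[ax] / 2.0
            # virtual neighbors one step beyond each edge take part in the
            # nearest/tie competition and map outside
            if phys[ax] <= src_centers[ax][0] - half or phys[ax] > src_centers[ax][-1] + half:
                inside = False
                break
            dist = np.abs(src_centers[ax] - phys[ax])
            j = int(np.argmin(dist))
            if j > 0 and dist[j - 1] == dist[j]:
                j -= 1
            nearest.append(j)
        out[idx] = inside and bool(mask.voxels[tuple(nearest)])
    return out


class TestResampleMaskToGrid:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(5)
        geom = GridGeometry((5, 6, 7), (1, 1, 2))
        mask = BinaryMask(rng.random((5, 6, 7)) > 0.5, geom)
        out = resample_mask_to_grid(mask, geom)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_empty_stays_empty(self):
        mask = BinaryMask(np.zeros((4, 4, 4), bool), GridGeometry((4, 4, 4), (1, 1, 2)))
        target = GridGeometry((6, 3, 9), (0.7, 1.3, 1.1))
        assert resample_mask_to_grid(mask, target).count == 0

    def test_single_voxel_matches_brute_force(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 2, 2] = True
        mask = BinaryMask(vox, GridGeometry((5, 5, 5), (1, 1, 2)))
        target = GridGeometry((5, 5, 4), (1, 1, 3))
        out = resample_mask_to_grid(mask, target)
        assert np.array_equal(out.voxels, _brute_force_nearest(mask, target))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_grids_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        src_shape = tuple(rng.integers(3, 9, 3))
        src = GridGeometry(src_shape, tuple(rng.uniform(0.5, 3.0, 3)), tuple(rng.uniform(-2, 2, 3)))
        mask = BinaryMask(rng.random(src_shape) > 0.6, src)
        tgt_shape = tuple(rng.integers(3, 10, 3))
        tgt = GridGeometry(tgt_shape, tuple(rng.uniform(0.5, 3.0, 3)), tuple(rng.uniform(-2, 2, 3)))
        out = resample_mask_to_grid(mask, tgt)
        assert np.array_equal(out.voxels, _brute_force_nearest(mask, tgt))


class TestRemoveCouch:
    def test_couch_excluded(self):
        from parotidseg.phantom import PhantomConfig, generate_phantom

        ph = generate_phantom(PhantomConfig(couch=True, seed=11))
        body = remove_couch(ph.volume)
        assert not (body.voxels & ph.couch_mask).any()
        # the actual body is retained
        assert (body.voxels & ph.body_mask).sum() > 0.99 * ph.body_mask.sum()

    def test_no_couch_equals_threshold_up_to_holes(self):
        from parotidseg.phantom import PhantomConfig, generate_phantom

        ph = generate_phantom(PhantomConfig(couch=False, noise_sigma=0.0, seed=12))
        body = remove_couch(ph.volume)
        assert np.array_equal(body.voxels, ph.volume.voxels > -300)

    def test_all_air_errors(self):
        vol = VolumeGrid(np.full((4, 4, 4), -1024.0, np.float32), (1, 1, 2))
        with pytest.raises(ValueError, match="no body"):
            remove_couch(vol)

    def test_apply_body_mask_fills_air(self):
        from parotidseg.phantom import PhantomConfig, generate_phantom

        ph = generate_phantom(PhantomConfig(couch=True, seed=13))
        body = remove_couch(ph.volume)
        cleaned = apply_body_mask(ph.volume, body)
        assert np.all(cleaned.voxels[ph.couch_mask] == -1024.0)


class TestMirrorSagittal:
    def test_involution(self):
        rng = np.random.default_rng(6)
        vol = _random_volume(rng)
        mask = BinaryMask(rng.random(vol.shape) > 0.5, vol.geometry, "right")
        v1, m1 = mirror_sagittal(vol, mask)
        v2, m2 = mirror_sagittal(v1, m1)
        assert np.array_equal(v2.voxels, vol.voxels)
        assert np.array_equal(m2.voxels, mask.voxels)
        assert m1.laterality == "left" and m2.laterality == "right"

    def test_index_arithmetic_exhaustive(self):
        nx = 5
        for k in range(nx):
            vox = np.zeros((nx, 5, 5), bool)
            vox[k, 2, 2] = True
            mask = BinaryMask(vox, GridGeometry((nx, 5, 5), (1, 1, 1)))
            vol = VolumeGrid(vox.astype(np.float32), (1, 1, 1))
            _, m = mirror_sagittal(vol, mask)
            assert m.voxels[nx - 1 - k, 2, 2]
            assert m.count == 1

    def test_joint_consistency_with_phantom(self):
        from parotidseg.phantom import PhantomConfig, generate_phantom

        ph = generate_phantom(PhantomConfig(seed=14))
        _, mirrored_right = mirror_sagittal(ph.volume, ph.right_mask)
        # mirroring the right gland of a symmetric construction lands on the
        # left side of the volume
        xs = np.argwhere(mirrored_right.voxels)[:, 0]
        assert xs.mean() > ph.volume.shape[0] / 2


class TestMirrorPad:
    def test_pad_wider_than_array(self):
        arr = np.arange(3.0)
        out = mirror_pad(arr, ((5, 5),))
        assert out.shape == (13,)
        assert out[5:8].tolist() == [0, 1, 2]

    def test_zero_pad_is_identity(self):
        arr = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(mirror_pad(arr, ((0, 0), (0, 0))), arr)
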
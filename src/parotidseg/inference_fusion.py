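"""Full-volume inference, orthogonal-view majority voting and postprocessing.

Tiled and whole-volume prediction agree exactly (up to float summation
order) because the networks use only valid convolutions: a tile's output
depends only on its mirrored-padded context, which is taken from the same
padded volume a whole-volume pass would see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from parotidseg.netarch.arch import PatchSpec, full_pass_geometry, valid_output_size
from parotidseg.netarch.model import UNet, normalize_hu
from parotidseg.sampling import VIEW_AXES
from parotidseg.volume_io import BinaryMask, GridGeometry, VolumeGrid, mirror_pad, resample_mask_to_grid

__all__ = [
    "ProbabilityMap",
    "PostprocessConfig",
    "PostprocessResult",
    "predict_2d",
    "predict_3d_tiled",
    "predict_3d_full",
    "ensemble_vote",
    "postprocess",
]


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probabilities on a volume grid."""

    voxels: np.ndarray
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError("probability map extents differ from grid extents")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"probabilities outside [0, 1]: [{lo}, {hi}]")

    def binarize(self, threshold: float = 0.5) -> BinaryMask:
        return BinaryMask(self.voxels >= threshold, self.grid)


@dataclass(frozen=True)
class PostprocessConfig:
    threshold: float = 0.5
    connectivity: int = 6  # face connectivity in 3-D

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PostprocessResult:
    mask: BinaryMask
    empty: bool


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def _check_model_dim(model: UNet, d: int) -> None:
    if model.spec.dimensionality != d:
        raise ValueError(
            f"model dimensionality {model.spec.dimensionality} does not match a {d}-D prediction"
        )


def predict_3d_tiled(
    model: UNet, vol: VolumeGrid, patch: PatchSpec | None = None
) -> ProbabilityMap:
    """Tile the volume by non-overlapping output blocks of the patch
    geometry, each predicted from its mirrored-padded input context."""
    _check_model_dim(model, 3)
    if patch is None:
        patch = PatchSpec.for_spec(model.spec, (72, 72, 56))
    patch.check_consistent(model.spec)
    out = np.array(patch.output_extent)
    margin = np.array(patch.margin)
    shape = np.array(vol.shape)
    n_tiles = -(-shape // out)  # ceil
    covered = n_tiles * out
    pads = tuple(
        (int(m), int(m + c - s)) for m, c, s in zip(margin, covered, shape)
    )
    padded = mirror_pad(normalize_hu(vol.voxels), pads)
    prob = np.empty(tuple(covered), dtype=np.float32)
    for tx in range(n_tiles[0]):
        for ty in range(n_tiles[1]):
            for tz in range(n_tiles[2]):
                b = np.array([tx, ty, tz]) * out
                in_sl = tuple(
                    slice(int(bb), int(bb) + ie) for bb, ie in zip(b, patch.input_extent)
                )
                p = model.predict_proba(padded[in_sl][None, None])[0]
                out_sl = tuple(slice(int(bb), int(bb) + oe) for bb, oe in zip(b, out))
                prob[out_sl] = p
    crop = tuple(slice(0, int(s)) for s in shape)
    return ProbabilityMap(prob[crop], vol.geometry)


def predict_3d_full(model: UNet, vol: VolumeGrid) -> ProbabilityMap:
    """Single whole-volume forward pass (mirror-padded to a feasible extent).

    Reference path for the tiling-consistency property; memory-hungrier
    than :func:`predict_3d_tiled` but mathematically identical.
    """
    _check_model_dim(model, 3)
    _, pads = full_pass_geometry(model.spec, vol.shape)
    padded = mirror_pad(normalize_hu(vol.voxels), pads)
    p = model.predict_proba(padded[None, None])[0]
    crop = tuple(slice(0, s) for s in vol.shape)
    return ProbabilityMap(p[crop], vol.geometry)


def _predict_slices(model: UNet, planes: np.ndarray, tile_extent: int | None) -> np.ndarray:
    """Predict a stack of equally-sized 2-D planes ``(N, H, W)`` -> probabilities."""
    n, h, w = planes.shape
    if tile_extent is None:
        _, pads = full_pass_geometry(model.spec, (h, w))
        padded = np.stack([mirror_pad(p, pads) for p in planes])
        probs = _batched_proba(model, padded[:, None])
        return probs[:, :h, :w]
    # in-plane tiling by square output blocks of tile_extent
    out_e = int(tile_extent)
    in_e = None
    for cand in range(out_e, out_e + 4096):
        try:
            if valid_output_size(model.spec, cand) == out_e:
                in_e = cand
                break
        except Exception:
            continue
    if in_e is None:
        raise ValueError(f"no feasible input extent for tile output {out_e}")
    m = (in_e - out_e) // 2
    nty, ntx = -(-h // out_e), -(-w // out_e)
    pads = ((m, m + nty * out_e - h), (m, m + ntx * out_e - w))
    prob = np.empty((n, nty * out_e, ntx * out_e), dtype=np.float32)
    padded = np.stack([mirror_pad(p, pads) for p in planes])
    for ty in range(nty):
        for tx in range(ntx):
            by, bx = ty * out_e, tx * out_e
            tile = padded[:, None, by : by + in_e, bx : bx + in_e]
            prob[:, by : by + out_e, bx : bx + out_e] = _batched_proba(model, tile)
    return prob[:, :h, :w]


def _batched_proba(model: UNet, x: np.ndarray, chunk: int = 16) -> np.ndarray:
    outs = [model.predict_proba(x[i : i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def predict_2d(
    model: UNet, vol: VolumeGrid, view: str = "axial", tile_extent: int | None = None
) -> ProbabilityMap:
    """Predict every reformatted slice along the view axis and reassemble.

    Slices are mirror-padded to a feasible extent and pushed through the
    network in one pass each (or tiled in-plane when ``tile_extent`` is
    given); the output volume is aligned with the input grid.
    """
    _check_model_dim(model, 2)
    if view not in VIEW_AXES:
        raise ValueError(f"unknown view {view!r}")
    ax = VIEW_AXES[view]
    planes = np.moveaxis(normalize_hu(vol.voxels), ax, 0)
    probs = _predict_slices(model, planes, tile_extent)
    return ProbabilityMap(np.moveaxis(probs, 0, ax), vol.geometry)


def ensemble_vote(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Per-voxel 2-of-3 majority vote over binarized per-view predictions."""
    if len(masks) != 3:
        raise ValueError(f"majority vote expects exactly 3 masks, got {len(masks)}")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("ensemble members live on different grids")
    votes = sum(m.voxels.astype(np.uint8) for m in masks)
    return BinaryMask(votes >= 2, grid)


def postprocess(
    prob: ProbabilityMap,
    cfg: PostprocessConfig | None = None,
    original_grid: GridGeometry | None = None,
) -> PostprocessResult:
    """Threshold at 0.5, keep the largest connected component, and resample
    to the original grid by nearest neighbor.

    An empty binarization is a valid result (flagged, not an error).  Ties
    between equal-sized components break to the component containing the
    lowest linear voxel index, which is deterministic.
    """
    if cfg is None:
        cfg = PostprocessConfig()
    binary = prob.voxels >= cfg.threshold
    empty = not binary.any()
    if not empty:
        structure = ndimage.generate_binary_structure(3, _CONN_RANK[cfg.connectivity])
        labels, n = ndimage.label(binary, structure=structure)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            # labels are assigned in raster-scan order, so argmax resolves
            # equal sizes toward the lowest first linear index
            binary = labels == int(np.argmax(sizes))
    mask = BinaryMask(binary, prob.grid)
    if original_grid is not None and original_grid != prob.grid:
        mask = resample_mask_to_grid(mask, original_grid)
    return PostprocessResult(mask, empty)
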
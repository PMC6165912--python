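"""Class-balancing training strategies.

Two samplers raise the foreground frequency seen during training:

* ROI-restricted 2-D slice sampling: slices are drawn only from the range
  of slices containing the target structure, widened by a margin of five
  slices on each side in view direction (plus a 25-voxel transverse
  restriction for sagittal/coronal views).
* 3-D patch sampling with controlled batch composition: a fixed fraction
  of the patches in every minibatch (50% by default) has a classified
  center overlapping the target mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from parotidseg.netarch.arch import ArchSpec, PatchSpec, valid_output_size
from parotidseg.volume_io import BinaryMask, VolumeGrid, mirror_pad

__all__ = [
    "SamplingConfig",
    "ROIBox",
    "VIEW_AXES",
    "compute_roi",
    "sample_roi_slices",
    "sample_balanced_patches",
    "select_training_subsets",
]

View = Literal["axial", "coronal", "sagittal"]

# slices are stacked along the view axis; internal array order is (x, y, z)
VIEW_AXES: dict[str, int] = {"sagittal": 0, "coronal": 1, "axial": 2}

_TRANSVERSE_AXIS = 2


@dataclass(frozen=True)
class SamplingConfig:
    view: View = "axial"
    slice_margin: int = 5
    transverse_margin: int = 25
    patch_extent: tuple[int, int, int] = (72, 72, 56)
    fg_fraction: float = 0.5
    batch_size: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEW_AXES:
            raise ValueError(f"unknown view {self.view!r}")
        if not 0.0 <= self.fg_fraction <= 1.0:
            raise ValueError("fg_fraction must lie in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def foreground_per_batch(self) -> int:
        """Patches per batch required to overlap foreground (ties-to-even)."""
        return int(round(self.batch_size * self.fg_fraction))


@dataclass(frozen=True)
class ROIBox:
    """Per-axis half-open voxel index intervals on a volume grid."""

    intervals: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if lo >= hi:
                raise ValueError(f"degenerate ROI interval [{lo}, {hi})")

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, hi) for lo, hi in self.intervals)


def _axis_fg_range(mask: np.ndarray, axis: int) -> tuple[int, int]:
    other = tuple(i for i in range(mask.ndim) if i != axis)
    hit = np.where(mask.any(axis=other))[0]
    return int(hit[0]), int(hit[-1])


def compute_roi(mask: BinaryMask, cfg: SamplingConfig) -> ROIBox:
    """Training ROI: gland slice range widened by ``slice_margin`` on each
    side along the view axis; sagittal/coronal views additionally restrict
    the transverse axis by ``transverse_margin`` voxels above and below."""
    if not mask.voxels.any():
        raise ValueError("cannot compute an ROI for an empty mask (case excluded)")
    shape = mask.grid.shape
    view_ax = VIEW_AXES[cfg.view]
    intervals = [(0, shape[0]), (0, shape[1]), (0, shape[2])]
    first, last = _axis_fg_range(mask.voxels, view_ax)
    intervals[view_ax] = (
        max(0, first - cfg.slice_margin),
        min(shape[view_ax], last + cfg.slice_margin + 1),
    )
    if view_ax != _TRANSVERSE_AXIS:
        zf, zl = _axis_fg_range(mask.voxels, _TRANSVERSE_AXIS)
        intervals[_TRANSVERSE_AXIS] = (
            max(0, zf - cfg.transverse_margin),
            min(shape[_TRANSVERSE_AXIS], zl + cfg.transverse_margin + 1),
        )
    return ROIBox(tuple(intervals))


def sample_roi_slices(
    vol: VolumeGrid,
    mask: BinaryMask,
    cfg: SamplingConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` reformatted (image, label) slice pairs from within the ROI.

    View-axis indices are uniform over the ROI interval; the returned
    slices are cropped to the ROI on the remaining axes (full extent
    except for the transverse restriction of sagittal/coronal views).
    """
    roi = compute_roi(mask, cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    view_ax = VIEW_AXES[cfg.view]
    lo, hi = roi.intervals[view_ax]
    crop = tuple(sl for ax, sl in enumerate(roi.slices()) if ax != view_ax)
    pairs = []
    for idx in rng.integers(lo, hi, size=n):
        img = np.take(vol.voxels, int(idx), axis=view_ax)[crop]
        lab = np.take(mask.voxels, int(idx), axis=view_ax)[crop]
        pairs.append((img, lab))
    return pairs


def sample_balanced_patches(
    vol: VolumeGrid,
    mask: BinaryMask,
    cfg: SamplingConfig,
    arch: ArchSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One minibatch of (input patch, center label) pairs with controlled
    batch composition.

    Exactly ``round(batch_size * fg_fraction)`` patches per batch have a
    classified center containing at least one foreground voxel; the
    remainder is drawn uniformly over the volume and redrawn if its center
    touches foreground, so the per-batch composition is exact rather than
    merely expected (with ``fg_fraction == 0`` sampling is plain uniform
    with no constraint).  The input patch is the architectural context
    around the center; context reaching beyond the volume is mirror-padded.
    """
    if arch is None:
        arch = ArchSpec(dimensionality=3)
    patch = PatchSpec(
        tuple(cfg.patch_extent), tuple(valid_output_size(arch, cfg.patch_extent))
    )
    center = np.array(patch.output_extent)
    margin = np.array(patch.margin)
    shape = np.array(vol.shape)
    if np.any(center > shape):
        raise ValueError(
            f"volume extents {tuple(shape)} smaller than the classified center {tuple(center)}"
        )
    n_fg = cfg.foreground_per_batch
    if n_fg > 0 and not mask.voxels.any():
        raise ValueError("no foreground in volume but fg_fraction > 0")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    padded = mirror_pad(vol.voxels, tuple((int(m), int(m)) for m in margin))

    fg_coords = np.argwhere(mask.voxels) if n_fg > 0 else None
    starts = []
    for b in range(cfg.batch_size):
        if b < n_fg:
            vox = fg_coords[rng.integers(0, len(fg_coords))]
            # jitter the center so the chosen foreground voxel stays inside it
            offset = rng.integers(0, center)
            start = np.clip(vox - offset, 0, shape - center)
        else:
            for _attempt in range(1000):
                start = np.array(
                    [rng.integers(0, s - c + 1) for s, c in zip(shape, center)]
                )
                if n_fg == 0:
                    break
                sl = tuple(slice(int(s), int(s) + int(c)) for s, c in zip(start, center))
                if not mask.voxels[sl].any():
                    break
            else:
                raise ValueError(
                    "could not place a background patch; foreground dominates the volume"
                )
        starts.append(start)
    order = rng.permutation(cfg.batch_size)
    batch = []
    for start in (starts[i] for i in order):
        in_sl = tuple(slice(int(s), int(s) + ie) for s, ie in zip(start, patch.input_extent))
        lab_sl = tuple(slice(int(s), int(s) + ce) for s, ce in zip(start, center))
        batch.append((padded[in_sl], mask.voxels[lab_sl]))
    return batch


def select_training_subsets(
    case_ids: Sequence[str], sizes: Sequence[int], seed: int = 0
) -> dict[int, list[str]]:
    """Nested training subsets for the data-quantity experiment.

    Cases are shuffled once (reproducibly by ``seed``); each subset is a
    prefix of the shuffle, so smaller subsets are contained in larger ones
    and learning curves are comparable.
    """
    ids = list(case_ids)
    if not sizes:
        return {}
    if max(sizes) > len(ids):
        raise ValueError(
            f"requested subset of {max(sizes)} cases but only {len(ids)} are available"
        )
    if min(sizes) < 1:
        raise ValueError("subset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return {int(s): shuffled[: int(s)] for s in sizes}
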
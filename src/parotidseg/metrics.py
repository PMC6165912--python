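"""Evaluation: Dice overlap, signed average surface distance, paired tests.

Conventions
-----------
* ``dice(X, Y) = 2|X n Y| / (|X| + |Y|)``.
* Border voxels are foreground voxels with a face-adjacent (6-neighbor)
  background or out-of-volume neighbor.
* The signed distance of a voxel to a mask is the Euclidean distance (mm,
  between voxel centers) to the nearest border voxel, negative inside the
  mask and positive outside.
* ``assd(X, Y)`` with prediction ``X`` and reference ``Y`` is
  ``(sum_{x in dX} d(x, Y) - sum_{y in dY} d(y, X)) / (|dX| + |dY|)``:
  positive when X overestimates the reference, negative when it
  underestimates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from parotidseg.volume_io import BinaryMask

__all__ = [
    "EvalRecord",
    "BorderSet",
    "dice",
    "border_voxels",
    "signed_distance",
    "assd",
    "wilcoxon_compare",
    "evaluate_case",
    "run_size_experiment",
    "SizeExperimentResult",
]


@dataclass
class EvalRecord:
    case_id: str
    dice: float | None
    assd_mm: float | None
    empty_result: bool = False

    def __post_init__(self) -> None:
        if self.dice is not None and not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice {self.dice} outside [0, 1]")


@dataclass
class BorderSet:
    """Voxel indices of a mask border, with spacing for physical distances."""

    indices: np.ndarray  # (n, 3) integer voxel indices
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.indices)

    def physical(self) -> np.ndarray:
        return self.indices * np.asarray(self.spacing)


def _check_grids(x: BinaryMask, y: BinaryMask) -> None:
    if x.grid != y.grid:
        raise ValueError("masks live on different grids")


def dice(x: BinaryMask, y: BinaryMask) -> float:
    _check_grids(x, y)
    nx, ny = x.count, y.count
    if nx == 0 and ny == 0:
        raise ValueError("Dice undefined: both masks are empty")
    if nx == 0 or ny == 0:
        return 0.0
    inter = int(np.logical_and(x.voxels, y.voxels).sum())
    return 2.0 * inter / (nx + ny)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def _border_mask(vox: np.ndarray) -> np.ndarray:
    # border_value=0: the volume boundary counts as background
    interior = ndimage.binary_erosion(vox, structure=_FACE_STRUCTURE, border_value=0)
    return vox & ~interior


def border_voxels(x: BinaryMask) -> BorderSet:
    if not x.voxels.any():
        raise ValueError("border of an empty mask is undefined")
    return BorderSet(np.argwhere(_border_mask(x.voxels)), x.grid.spacing)


def _signed_distance_map(y: BinaryMask) -> np.ndarray:
    """d(., Y) sampled on the whole grid via a Euclidean distance transform."""
    border = _border_mask(y.voxels)
    dist = ndimage.distance_transform_edt(~border, sampling=y.grid.spacing)
    return np.where(y.voxels, -dist, dist)


def signed_distance(x: Sequence[int], y: BinaryMask) -> float:
    """Signed Euclidean distance (mm) of voxel index ``x`` to the mask ``y``."""
    if not y.voxels.any():
        raise ValueError("distance to an empty mask is undefined")
    d = _signed_distance_map(y)[tuple(int(i) for i in x)]
    return float(d) + 0.0  # normalize -0.0


def assd(x: BinaryMask, y: BinaryMask) -> float:
    """Signed average surface distance (mm) of prediction ``x`` to reference ``y``."""
    _check_grids(x, y)
    if not x.voxels.any() or not y.voxels.any():
        raise ValueError("ASSD undefined for empty masks")
    bx = _border_mask(x.voxels)
    by = _border_mask(y.voxels)
    d_to_y = _signed_distance_map(y)
    d_to_x = _signed_distance_map(x)
    s1 = float(d_to_y[bx].sum())
    s2 = float(d_to_x[by].sum())
    return (s1 - s2) / (int(bx.sum()) + int(by.sum()))


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired per-case metrics.

    Zero-difference pairs are dropped; if every difference is zero the
    result is not significant with p = 1 by convention.  The exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        return 0.0, 1.0, False
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def evaluate_case(pred: BinaryMask, ref: BinaryMask, case_id: str = "") -> EvalRecord:
    """Per-case Dice and ASSD; an empty prediction yields Dice 0, no ASSD."""
    if not pred.voxels.any():
        return EvalRecord(case_id, 0.0 if ref.voxels.any() else None, None, True)
    return EvalRecord(case_id, dice(pred, ref), assd(pred, ref), False)


# ---------------------------------------------------------------------------
# Training-set-size experiment
# ---------------------------------------------------------------------------


@dataclass
class SizeExperimentResult:
    per_size: dict[int, list[EvalRecord]] = field(default_factory=dict)
    comparisons: list[tuple[int, int, float, float, bool]] = field(default_factory=list)
    errors: dict[int, str] = field(default_factory=dict)

    def median_dice(self, size: int) -> float:
        return float(np.median([r.dice for r in self.per_size[size] if r.dice is not None]))


def run_size_experiment(
    train_cases: dict[str, tuple],
    eval_cases: dict[str, tuple],
    sizes: Sequence[int],
    train_config,
    seed: int = 0,
) -> SizeExperimentResult:
    """Train one 3-D model per nested subset size and evaluate Dice on a
    fixed evaluation set; adjacent sizes are compared with the Wilcoxon
    signed-rank test (unadjusted for multiple comparisons).

    ``train_cases`` / ``eval_cases`` map case ids to ``(VolumeGrid,
    BinaryMask)`` pairs.  A failing training run is recorded and the
    remaining sizes continue.
    """
    from parotidseg.inference_fusion import postprocess, predict_3d_tiled
    from parotidseg.netarch.arch import PatchSpec
    from parotidseg.sampling import select_training_subsets
    from parotidseg.training import train_patch_model

    subsets = select_training_subsets(sorted(train_cases), sizes, seed=seed)
    result = SizeExperimentResult()
    for size in sizes:
        try:
            cases = [train_cases[cid] for cid in subsets[int(size)]]
            model, _losses = train_patch_model(cases, train_config)
            patch = PatchSpec.for_spec(model.spec, train_config.patch_extent)
            records = []
            for cid in sorted(eval_cases):
                vol, ref = eval_cases[cid]
                prob = predict_3d_tiled(model, vol, patch)
                pred = postprocess(prob).mask
                records.append(evaluate_case(pred, ref, cid))
            result.per_size[int(size)] = records
        except Exception as exc:  # keep going for the remaining sizes
            result.errors[int(size)] = str(exc)
    done = [s for s in sizes if int(s) in result.per_size]
    for s1, s2 in zip(done, done[1:]):
        a = [r.dice for r in result.per_size[int(s1)]]
        b = [r.dice for r in result.per_size[int(s2)]]
        stat, p, sig = wilcoxon_compare(a, b)
        result.comparisons.append((int(s1), int(s2), stat, p, sig))
    return result
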
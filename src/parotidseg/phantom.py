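"""Synthetic CT-like head phantoms with exact ground-truth gland masks.

A phantom is an elliptical soft-tissue body cross-section in air, one
ellipsoidal target structure per side, and optional similar-intensity
distractor structures, a couch slab below the body, streak artifacts and
Gaussian noise — enough structure to exercise every pipeline stage
(couch removal, ROI sampling, balanced patches, tiled inference, largest
component selection) without clinical data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from parotidseg.volume_io import (
    AIR_HU,
    BinaryMask,
    GridGeometry,
    VolumeGrid,
    write_mask,
    write_volume,
)

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "generate_cohort"]

# invented HU palette: low gland/soft-tissue contrast on purpose
BODY_HU = 40.0
GLAND_HU = 60.0
COUCH_HU = 200.0
DISTRACTOR_HU = (54.0, 60.0)


@dataclass(frozen=True)
class PhantomConfig:
    extents: tuple[int, int, int] = (64, 64, 44)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    body_axes_fraction: tuple[float, float] = (0.86, 0.74)  # of the half-extents
    body_hu: float = BODY_HU
    gland_hu: float = GLAND_HU
    # left-right asymmetry: the contralateral gland is fainter by default so
    # the left-only segmentation task is locally decidable
    gland_hu_right: float = 46.0
    gland_radii_range: tuple[tuple[float, float], ...] = ((7.5, 9.5), (7.5, 9.5), (4.5, 6.0))
    gland_lateral_offset: float = 0.35  # fraction of x half-extent
    # distractors are z-elongated rods with gland-like in-plane appearance:
    # indistinguishable from the target in a single axial slice, separable
    # only through 3-D context
    n_distractors: int = 0
    distractor_radii_range: tuple[tuple[float, float], ...] = (
        (4.5, 6.5),
        (4.5, 6.5),
        (7.0, 11.0),
    )
    distractor_z_clearance: float = 5.0  # slices between gland range and blob edge
    couch: bool = False
    couch_thickness: int = 3
    artifact_streaks: bool = False
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 8 for n in self.extents):
            raise ValueError("phantom extents must be at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class Phantom:
    """Generated volume, per-side gland masks and construction metadata."""

    volume: VolumeGrid
    left_mask: BinaryMask
    right_mask: BinaryMask
    body_mask: np.ndarray
    couch_mask: np.ndarray
    distractor_mask: np.ndarray


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(cfg: PhantomConfig) -> Phantom:
    """Deterministically rasterize one phantom from its config seed.

    Air background at -1024 HU, elliptical-cylinder body, two lateralized
    gland ellipsoids (the right gland is generated explicitly, not
    mirrored), then optional distractors/couch/streaks and noise.  Masks
    are the exact noiseless ellipsoid rasterizations.
    """
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.extents
    shape = (nx, ny, nz)
    geom = GridGeometry(shape, cfg.spacing)

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    bx = cfg.body_axes_fraction[0] * nx / 2.0
    by = cfg.body_axes_fraction[1] * ny / 2.0
    xg, yg = np.ogrid[0:nx, 0:ny]
    body2d = ((xg - cx) / bx) ** 2 + ((yg - cy) / by) ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], nz, axis=2)

    def draw_gland(sign: int) -> np.ndarray:
        radii = [rng.uniform(lo, hi) for lo, hi in cfg.gland_radii_range]
        center = (
            cx + sign * cfg.gland_lateral_offset * nx / 2.0 + rng.uniform(-1.5, 1.5),
            cy + rng.uniform(-1.5, 1.5),
            (nz - 1) / 2.0 + rng.uniform(-1.5, 1.5),
        )
        gl = _ellipsoid(shape, center, radii)
        if not (gl <= body).all():
            raise ValueError("infeasible geometry: gland extends outside the body")
        return gl

    # x increases toward the patient's left
    left = draw_gland(+1)
    right = draw_gland(-1)

    vol = np.full(shape, AIR_HU, dtype=np.float32)
    vol[body] = cfg.body_hu
    vol[left] = cfg.gland_hu
    vol[right] = cfg.gland_hu_right

    distractors = np.zeros(shape, dtype=bool)
    gland_z = np.where((left | right).any(axis=(0, 1)))[0]
    g_mean = float(gland_z.mean()) if gland_z.size else (nz - 1) / 2.0
    g_half = gland_z.size / 2.0
    for _ in range(cfg.n_distractors):
        for _attempt in range(30):
            r = [rng.uniform(lo, hi) for lo, hi in cfg.distractor_radii_range]
            guard = g_half + r[2] + cfg.distractor_z_clearance
            # admissible z-center intervals: distant from the gland range
            bands = []
            if g_mean - guard > 0:
                bands.append((0.0, g_mean - guard))
            if g_mean + guard < nz - 1:
                bands.append((g_mean + guard, nz - 1.0))
            if not bands:
                continue
            widths = np.array([hi - lo for lo, hi in bands])
            lo, hi = bands[rng.choice(len(bands), p=widths / widths.sum())]
            center = (
                cx + rng.uniform(-0.35, 0.35) * bx,
                cy + rng.uniform(-0.35, 0.35) * by,
                rng.uniform(lo, hi),
            )
            blob = _ellipsoid(shape, center, r) & body
            if not blob.any() or (blob & (left | right)).any():
                continue
            distractors |= blob
            vol[blob] = rng.uniform(*DISTRACTOR_HU)
            break

    couch = np.zeros(shape, dtype=bool)
    if cfg.couch:
        y_lo = ny - cfg.couch_thickness
        if body2d[:, y_lo:].any():
            raise ValueError("infeasible geometry: couch slab would touch the body")
        x_lo, x_hi = int(nx * 0.2), int(nx * 0.8)
        couch[x_lo:x_hi, y_lo:, :] = True
        vol[couch] = COUCH_HU

    if cfg.artifact_streaks and gland_z.size:
        # additive bright/dark line pairs through the gland slices
        z0 = int(gland_z.mean())
        for sign in (+1.0, -1.0):
            angle = rng.uniform(0, np.pi)
            t = np.arange(-max(nx, ny), max(nx, ny))
            sx = np.clip(np.round(cx + t * np.cos(angle)).astype(int), 0, nx - 1)
            sy = np.clip(np.round(cy + t * np.sin(angle)).astype(int), 0, ny - 1)
            for dz in (-1, 0, 1):
                z = np.clip(z0 + dz, 0, nz - 1)
                vol[sx, sy, z] += sign * 100.0

    if cfg.noise_sigma > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sigma, size=shape).astype(np.float32)

    return Phantom(
        volume=VolumeGrid(vol.astype(np.float32), cfg.spacing),
        left_mask=BinaryMask(left, geom, "left"),
        right_mask=BinaryMask(right, geom, "right"),
        body_mask=body & ~couch,
        couch_mask=couch,
        distractor_mask=distractors,
    )


def generate_cohort(
    n: int,
    out_dir: str | os.PathLike,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n`` phantoms (volume + left/right masks) and a manifest CSV.

    Per-phantom parameters are drawn by reseeding the base config; the
    manifest has one row per case with columns ``case_id, volume,
    mask_left, mask_right``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cfg is None:
        cfg = PhantomConfig()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        case = f"case{i:04d}"
        ph = generate_phantom(replace(cfg, seed=seed * 100003 + i))
        vol_path = os.path.join(out_dir, f"{case}_ct.nii.gz")
        left_path = os.path.join(out_dir, f"{case}_parotid_l.nii.gz")
        right_path = os.path.join(out_dir, f"{case}_parotid_r.nii.gz")
        write_volume(ph.volume, vol_path)
        write_mask(ph.left_mask, left_path)
        write_mask(ph.right_mask, right_path)
        rows.append(
            {"case_id": case, "volume": vol_path, "mask_left": left_path, "mask_right": right_path}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
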
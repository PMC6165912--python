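"""Training harness: Adam optimizer and the two training strategies.

The 3-D network trains on balanced patches (controlled batch
composition); the 2-D networks train on ROI-restricted reformatted
slices.  Hyperparameters (optimizer, learning rate, step count) are
config values — Adam at 1e-3 by default — since they only need to reach
convergence at the scale of the problem at hand.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from parotidseg.netarch.arch import ArchSpec, full_pass_geometry
from parotidseg.netarch.loss import soft_dice_grad, soft_dice_loss, softmax_probs
from parotidseg.netarch.model import UNet, build_unet, calibrate_batchnorm, normalize_hu
from parotidseg.sampling import SamplingConfig, sample_balanced_patches, sample_roi_slices
from parotidseg.volume_io import BinaryMask, VolumeGrid, mirror_pad

__all__ = ["TrainConfig", "Adam", "train_patch_model", "train_roi_slice_model"]


@dataclass
class TrainConfig:
    """Hyperparameters for one training run (YAML-serializable)."""

    dimensionality: int = 3
    levels: int = 3
    base_channels: int = 8
    batch_norm: bool = True
    patch_extent: tuple[int, int, int] = (48, 48, 48)
    fg_fraction: float = 0.5
    batch_size: int = 8
    view: str = "axial"
    slice_margin: int = 5
    transverse_margin: int = 25
    steps: int = 200
    learning_rate: float = 1e-3
    # piecewise-constant decay: multiply by lr_decay_factor at each
    # milestone (fractions of the total step count)
    lr_milestones: tuple[float, ...] = (0.6, 0.85)
    lr_decay_factor: float = 0.3
    seed: int = 0

    def lr_at(self, step: int) -> float:
        passed = sum(1 for m in self.lr_milestones if step >= m * self.steps)
        return self.learning_rate * self.lr_decay_factor**passed

    def arch_spec(self) -> ArchSpec:
        return ArchSpec(
            dimensionality=self.dimensionality,
            levels=self.levels,
            base_channels=self.base_channels,
            batch_norm=self.batch_norm,
        )

    def sampling_config(self) -> SamplingConfig:
        return SamplingConfig(
            view=self.view,
            slice_margin=self.slice_margin,
            transverse_margin=self.transverse_margin,
            patch_extent=tuple(self.patch_extent),
            fg_fraction=self.fg_fraction,
            batch_size=self.batch_size,
            rng_seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "patch_extent" in data:
            data["patch_extent"] = tuple(data["patch_extent"])
        if "lr_milestones" in data:
            data["lr_milestones"] = tuple(data["lr_milestones"])
        return cls(**data)


class Adam:
    """Adam with the usual defaults, over a model's parameter iterator."""

    def __init__(self, model: UNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p, _ in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, p, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p, g in self.model.parameters():
            m = self.m[k]
            v = self.v[k]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _dice_step(model: UNet, x: np.ndarray, target: np.ndarray, opt: Adam) -> float:
    """One forward/backward/update on soft Dice loss; returns the loss."""
    logits = model.forward(x, train=True)
    probs = softmax_probs(logits)
    p_fg = probs[:, 1]
    loss = soft_dice_loss(p_fg, target)
    g = soft_dice_grad(p_fg, target)
    # two-channel softmax: dL/dz_fg = g * p_fg * p_bg, dL/dz_bg = -dL/dz_fg
    gz = g * p_fg * probs[:, 0]
    g_logits = np.stack([-gz, gz], axis=1)
    model.zero_grad()
    model.backward(g_logits)
    opt.step()
    return loss


def train_patch_model(
    cases: list[tuple[VolumeGrid, BinaryMask]], config: TrainConfig
) -> tuple[UNet, list[float]]:
    """Train a 3-D U-Net with controlled batch composition.

    Each step draws a balanced patch batch from one randomly chosen
    training case.  Returns the model and the per-step loss history;
    fully deterministic under ``config.seed``.
    """
    if config.dimensionality != 3:
        raise ValueError("train_patch_model trains 3-D models")
    spec = config.arch_spec()
    scfg = config.sampling_config()
    model = build_unet(spec, seed=config.seed)
    opt = Adam(model, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    losses = []
    for step in range(config.steps):
        opt.lr = config.lr_at(step)
        vol, mask = cases[rng.integers(0, len(cases))]
        batch = sample_balanced_patches(vol, mask, scfg, arch=spec, rng=rng)
        x = np.stack([normalize_hu(p) for p, _ in batch])[:, None]
        t = np.stack([lab for _, lab in batch]).astype(np.float32)
        losses.append(_dice_step(model, x, t, opt))
    _calibrate_on_volumes(model, cases, rng)
    return model, losses


def _calibrate_on_volumes(model: UNet, cases, rng, k: int = 2) -> None:
    """Recompute batch-norm statistics on inference-sized inputs."""
    picks = [cases[i] for i in rng.choice(len(cases), size=min(k, len(cases)), replace=False)]
    def inputs():
        for vol, _mask in picks:
            _, pads = full_pass_geometry(model.spec, vol.shape)
            yield mirror_pad(normalize_hu(vol.voxels), pads)[None, None]
    calibrate_batchnorm(model, inputs())


def train_roi_slice_model(
    cases: list[tuple[VolumeGrid, BinaryMask]], config: TrainConfig
) -> tuple[UNet, list[float]]:
    """Train a 2-D U-Net on ROI-restricted reformatted slices.

    Slices within one batch may differ in extent between cases, so each
    batch is drawn from a single case; slices are mirror-padded to a
    feasible valid-convolution input and the loss is computed on the full
    slice output.
    """
    if config.dimensionality != 2:
        raise ValueError("train_roi_slice_model trains 2-D models")
    spec = config.arch_spec()
    scfg = config.sampling_config()
    model = build_unet(spec, seed=config.seed)
    opt = Adam(model, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    losses = []
    for step in range(config.steps):
        opt.lr = config.lr_at(step)
        vol, mask = cases[rng.integers(0, len(cases))]
        pairs = sample_roi_slices(vol, mask, scfg, n=config.batch_size, rng=rng)
        shape = pairs[0][0].shape
        _, pads = full_pass_geometry(spec, shape)
        x = np.stack([mirror_pad(normalize_hu(img), pads) for img, _ in pairs])[:, None]
        t = np.stack([lab for _, lab in pairs]).astype(np.float32)
        logits = model.forward(x, train=True)
        # crop the valid output down to the slice extent
        crop = (slice(None), slice(None)) + tuple(slice(0, s) for s in shape)
        probs = softmax_probs(logits)
        p_fg = probs[(slice(None), 1) + crop[2:]]
        loss = soft_dice_loss(p_fg, t)
        g = soft_dice_grad(p_fg, t)
        gz_full = np.zeros(logits.shape[:1] + logits.shape[2:], dtype=np.float32)
        gz_full[(slice(None),) + crop[2:]] = g * p_fg * probs[(slice(None), 0) + crop[2:]]
        g_logits = np.stack([-gz_full, gz_full], axis=1)
        model.zero_grad()
        model.backward(g_logits)
        opt.step()
        losses.append(loss)
    _calibrate_on_slices(model, cases, config.view, rng)
    return model, losses


def _calibrate_on_slices(model: UNet, cases, view: str, rng, k: int = 2) -> None:
    """Recompute batch-norm statistics on full-volume slice stacks."""
    from parotidseg.sampling import VIEW_AXES

    ax = VIEW_AXES[view]
    picks = [cases[i] for i in rng.choice(len(cases), size=min(k, len(cases)), replace=False)]

    def inputs():
        for vol, _mask in picks:
            planes = np.moveaxis(normalize_hu(vol.voxels), ax, 0)
            _, pads = full_pass_geometry(model.spec, planes.shape[1:])
            padded = np.stack([mirror_pad(p, pads) for p in planes])[:, None]
            for i in range(0, len(padded), 16):
                yield padded[i : i + 16]

    calibrate_batchnorm(model, inputs())
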
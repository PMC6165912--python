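"""The valid-convolution U-Net model (2-D and 3-D), checkpoints and probes.

The network follows the traced architecture of
:mod:`parotidseg.netarch.arch` exactly: per resolution level two (by
default) valid convolutions with batch norm and ReLU, 2x max pooling
between encoder levels, nearest-neighbor upsampling with center-cropped
skip concatenation on the decoder, and a two-channel 1-voxel output
convolution followed by softmax.
"""

from __future__ import annotations

import copy
import json
import os

import numpy as np

from parotidseg.netarch.arch import ArchSpec, SizingError, valid_output_size
from parotidseg.netarch.layers import BatchNorm, ConvValid, MaxPool, ReLU, Upsample
from parotidseg.netarch.loss import softmax_probs

__all__ = [
    "UNet",
    "build_unet",
    "normalize_hu",
    "save_checkpoint",
    "load_checkpoint",
    "measure_receptive_field",
    "positivized",
]


def normalize_hu(voxels: np.ndarray) -> np.ndarray:
    """Soft-tissue windowing of Hounsfield units for network input.

    Clips to [-160, 240] HU and scales by 1/100, so the low gland/tissue
    contrast is not dwarfed by the air/tissue edge signal.
    """
    v = np.clip(np.asarray(voxels, dtype=np.float32), -160.0, 240.0)
    return (v / 100.0).astype(np.float32)


class _Block:
    """convs_per_block x (valid conv [+ batch norm] + ReLU)."""

    def __init__(self, spec: ArchSpec, c_in: int, c_out: int, rng, name: str):
        self.layers = []
        d, k = spec.dimensionality, spec.kernel_extent
        for c in range(spec.convs_per_block):
            self.layers.append(ConvValid(c_in if c == 0 else c_out, c_out, k, d, rng, f"{name} conv {c}"))
            if spec.batch_norm:
                self.layers.append(BatchNorm(c_out, f"{name} bn {c}"))
            self.layers.append(ReLU(f"{name} relu {c}"))

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet:
    """Trainable valid-convolution U-Net honoring the ArchSpec contract."""

    def __init__(self, spec: ArchSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d = spec.dimensionality
        base = spec.base_channels
        L = spec.levels
        ch = [base * 2**lv for lv in range(L)]

        self.enc_blocks = []
        self.pools = []
        for lv in range(L - 1):
            c_in = 1 if lv == 0 else ch[lv - 1]
            self.enc_blocks.append(_Block(spec, c_in, ch[lv], rng, f"encoder level {lv}"))
            self.pools.append(MaxPool(spec.pool_extent, d, f"pool after encoder level {lv}"))
        bottom_in = 1 if L == 1 else ch[L - 2]
        self.bottom = _Block(spec, bottom_in, ch[L - 1], rng, f"bottom level {L - 1}")
        self.ups = []
        self.dec_blocks = []
        for lv in reversed(range(L - 1)):
            self.ups.append(Upsample(spec.pool_extent, d, f"upsample to level {lv}"))
            self.dec_blocks.append(
                _Block(spec, ch[lv + 1] + ch[lv], ch[lv], rng, f"decoder level {lv}")
            )
        rng_final = rng
        self.final = ConvValid(ch[0], spec.output_channels, 1, d, rng_final, "output conv")
        self._crop_cache = None

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk.layers
        yield from self.pools
        yield from self.bottom.layers
        yield from self.ups
        for blk in self.dec_blocks:
            yield from blk.layers
        yield self.final

    def parameters(self):
        """Yield ``(key, param_array, grad_array)`` for every trainable tensor."""
        for i, layer in enumerate(self._all_layers()):
            p, g = layer.params(), layer.grads()
            for k in p:
                yield f"{i}:{layer.name}:{k}", p[k], g[k]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in {**layer.params(), **layer.state()}.items():
                out[f"{i}:{layer.name}:{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        mine = self.state_dict()
        if set(mine) != set(state):
            raise ValueError("checkpoint parameter names do not match the architecture")
        for k, v in mine.items():
            v[...] = state[k]

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    @property
    def num_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input ``(N, 1, *spatial)`` -> logits ``(N, 2, *valid_spatial)``.

        Raises :class:`SizingError` for infeasible input extents, with the
        same diagnosis as the symbolic tracer.
        """
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        d = self.spec.dimensionality
        if x.ndim != d + 2:
            raise ValueError(f"expected (batch, channel, {d} spatial axes), got shape {x.shape}")
        valid_output_size(self.spec, x.shape[2:])  # fail early with a traced diagnosis
        skips = []
        crops = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottom.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            off = tuple((skip.shape[2 + i] - x.shape[2 + i]) // 2 for i in range(d))
            sl = (slice(None), slice(None)) + tuple(
                slice(off[i], off[i] + x.shape[2 + i]) for i in range(d)
            )
            x = np.concatenate([skip[sl], x], axis=1)
            crops.append((skip.shape, sl, skip.shape[1]))
            x = blk.forward(x, train)
        x = self.final.forward(x, train)
        if train:
            self._crop_cache = crops
        return x

    def backward(self, g_logits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits; accumulates parameter grads."""
        crops = self._crop_cache
        self._crop_cache = None
        g = np.asarray(g_logits)
        if not np.issubdtype(g.dtype, np.floating):
            g = g.astype(np.float32)
        g = self.final.backward(g)
        g_skips = []
        # decoder blocks were built deep-to-shallow; backward runs shallow-to-deep
        for up, blk, (skip_shape, sl, skip_ch) in zip(
            self.ups[::-1], self.dec_blocks[::-1], crops[::-1]
        ):
            g = blk.backward(g)
            g_skip_crop, g = g[:, :skip_ch], g[:, skip_ch:]
            g_full = np.zeros(skip_shape, dtype=g.dtype)
            g_full[sl] = g_skip_crop
            g_skips.append(g_full)
            g = up.backward(g)
        g = self.bottom.backward(g)
        # g_skips were collected shallow-to-deep; the encoder backward runs deep-to-shallow
        for pool, blk, g_skip in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(g_skips)
        ):
            g = pool.backward(g)
            g = g + g_skip
            g = blk.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax foreground probability ``(N, *valid_spatial)`` in eval mode."""
        logits = self.forward(x, train=False)
        return softmax_probs(logits)[:, 1]


def build_unet(spec: ArchSpec, seed: int = 0) -> UNet:
    """Construct a U-Net with reproducible, seed-determined initial weights."""
    return UNet(spec, seed)


def calibrate_batchnorm(model: UNet, inputs) -> None:
    """Recompute batch-norm running statistics from the given inputs.

    Training batches are small and their per-channel statistics noisy; a
    calibration pass over a few inference-sized inputs replaces the
    momentum-averaged running moments with exact ones, after which the
    statistics stay frozen (so tiled and whole-volume inference agree).
    """
    from parotidseg.netarch.layers import BatchNorm

    bns = [layer for layer in model._all_layers() if isinstance(layer, BatchNorm)]
    if not bns:
        return
    for bn in bns:
        bn.begin_calibration()
    for x in inputs:
        model.forward(np.asarray(x), train=True)
        model._crop_cache = None
    for bn in bns:
        bn.end_calibration()


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: UNet, path: str | os.PathLike) -> None:
    """Single-file checkpoint with the ArchSpec embedded for reload safety."""
    meta = json.dumps({"arch": model.spec.to_dict(), "seed": model.seed})
    np.savez_compressed(os.fspath(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **model.state_dict())


def load_checkpoint(path: str | os.PathLike) -> UNet:
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path_try = path + ".npz"
        path = path_try if os.path.exists(path_try) else path
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = UNet(ArchSpec.from_dict(meta["arch"]), meta.get("seed", 0))
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# Empirical receptive-field probing
# ---------------------------------------------------------------------------


def positivized(model: UNet) -> UNet:
    """Deep copy with all conv weights made non-negative and biases zeroed.

    Guarantees that a large positive single-voxel perturbation propagates
    through ReLU and max pooling wherever a connection exists, so the
    measured influence region equals the architectural receptive field.
    """
    clone = copy.deepcopy(model)
    for layer in clone._all_layers():
        params = layer.params()
        if "w" in params:
            params["w"][...] = np.abs(params["w"]) + 1e-3
            params["b"][...] = 0.0
    return clone


def measure_receptive_field(
    model: UNet,
    probe_extent: int = 64,
    delta: float = 1e6,
    batch: int = 8,
    seed: int = 0,
) -> tuple[int, ...]:
    """Measure the receptive field by single-voxel occlusion probing.

    A fixed output voxel (the output center) is observed while each input
    voxel along a central line through its receptive field is perturbed by
    ``delta``; the count of influencing positions per axis is returned.
    Use :func:`positivized` on the probed model to make propagation
    through ReLU/max-pool deterministic.
    """
    spec = model.spec
    d = spec.dimensionality
    shape = (probe_extent,) * d
    out_shape = valid_output_size(spec, shape)
    reduction = probe_extent - out_shape[0]
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, size=shape).astype(np.float32)
    out_center = tuple(n // 2 for n in out_shape)
    base_out = model.forward(base[None, None])[
        (0, slice(None)) + out_center
    ]
    # input window of output voxel j spans [j, j + reduction + 1) per axis
    probe_fix = tuple(oc + reduction // 2 for oc in out_center)
    counts = []
    for ax in range(d):
        changed = 0
        positions = list(range(probe_extent))
        for start in range(0, len(positions), batch):
            chunk = positions[start : start + batch]
            xs = np.repeat(base[None, None], len(chunk), axis=0)
            for bi, pos in enumerate(chunk):
                idx = list(probe_fix)
                idx[ax] = pos
                xs[(bi, 0) + tuple(idx)] += delta
            outs = model.forward(xs)[(slice(None), slice(None)) + out_center]
            diff = np.abs(outs - base_out[None]) > 1e-4 * max(1.0, float(np.abs(base_out).max()))
            changed += int(diff.any(axis=1).sum())
        counts.append(changed)
    return tuple(counts)
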
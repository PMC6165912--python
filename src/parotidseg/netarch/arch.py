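"""Symbolic extent and receptive-field arithmetic for valid-convolution U-Nets.

Every operation here traces the encoder-decoder layer list of an
:class:`ArchSpec` without constructing a network, so that patch geometry
(input 72x72x56 -> classified center 32x32x16 for the defaults) and the
maximum receptive field (44 voxels per axis for the defaults) can be
derived and checked independently of the tensor implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "ArchSpec",
    "PatchSpec",
    "SizingError",
    "trace_layers",
    "valid_output_size",
    "receptive_field",
    "receptive_field_mm",
    "min_input_for_output",
    "full_pass_geometry",
]


class SizingError(ValueError):
    """An input extent is infeasible for the traced architecture."""


@dataclass(frozen=True)
class ArchSpec:
    """Topology of the 3-resolution-level valid-convolution U-Net family.

    ``padding_mode`` is fixed to ``"valid"`` and the network always ends in
    a two-channel (foreground/background) 1-voxel convolution followed by
    softmax.
    """

    dimensionality: int = 3
    levels: int = 3
    convs_per_block: int = 2
    kernel_extent: int = 3
    pool_extent: int = 2
    base_channels: int = 32
    batch_norm: bool = True
    padding_mode: str = "valid"
    output_channels: int = 2

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {self.dimensionality}")
        # levels >= 1 so that a plain conv stack can be traced too
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if self.kernel_extent < 1 or self.kernel_extent % 2 == 0:
            raise ValueError("kernel_extent must be odd and >= 1")
        if self.pool_extent < 2:
            raise ValueError("pool_extent must be >= 2")
        if self.padding_mode != "valid":
            raise ValueError("only valid (unpadded) convolutions are supported")
        if self.output_channels != 2:
            raise ValueError("the network is fixed to 2 output channels (fg/bg)")

    def to_dict(self) -> dict:
        return {
            "dimensionality": self.dimensionality,
            "levels": self.levels,
            "convs_per_block": self.convs_per_block,
            "kernel_extent": self.kernel_extent,
            "pool_extent": self.pool_extent,
            "base_channels": self.base_channels,
            "batch_norm": self.batch_norm,
            "padding_mode": self.padding_mode,
            "output_channels": self.output_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        return cls(**d)


def trace_layers(spec: ArchSpec) -> list[tuple[str, str, int]]:
    """Flatten the architecture into ``(name, kind, extent)`` tuples.

    ``kind`` is one of ``conv`` (valid convolution of the given kernel
    extent), ``pool`` (max-pool, stride = extent) or ``up`` (nearest
    upsampling by the given factor).  The trailing 1-voxel output
    convolution is included.
    """
    k, p = spec.kernel_extent, spec.pool_extent
    ops: list[tuple[str, str, int]] = []
    for lv in range(spec.levels - 1):
        for c in range(spec.convs_per_block):
            ops.append((f"encoder level {lv} conv {c}", "conv", k))
        ops.append((f"pool after encoder level {lv}", "pool", p))
    for c in range(spec.convs_per_block):
        ops.append((f"bottom level {spec.levels - 1} conv {c}", "conv", k))
    for lv in reversed(range(spec.levels - 1)):
        ops.append((f"upsample to level {lv}", "up", p))
        for c in range(spec.convs_per_block):
            ops.append((f"decoder level {lv} conv {c}", "conv", k))
    ops.append(("output conv", "conv", 1))
    return ops


def _trace_extent(spec: ArchSpec, n: int) -> int:
    """Trace one axis extent through the network, checking feasibility."""
    if n < 1:
        raise SizingError(f"input extent must be >= 1, got {n}")
    k, p = spec.kernel_extent, spec.pool_extent
    enc: list[int] = []
    x = n
    for lv in range(spec.levels - 1):
        for c in range(spec.convs_per_block):
            x -= k - 1
            if x < 1:
                raise SizingError(
                    f"feature map vanishes at encoder level {lv} conv {c} (extent {x})"
                )
        enc.append(x)
        if x % p:
            raise SizingError(
                f"extent {x} before pool after encoder level {lv} is not divisible by {p}"
            )
        x //= p
    for c in range(spec.convs_per_block):
        x -= k - 1
        if x < 1:
            raise SizingError(
                f"feature map vanishes at bottom level {spec.levels - 1} conv {c} (extent {x})"
            )
    for lv in reversed(range(spec.levels - 1)):
        x *= p
        if enc[lv] < x:
            raise SizingError(
                f"decoder extent {x} exceeds encoder skip extent {enc[lv]} at level {lv}"
            )
        if (enc[lv] - x) % 2:
            raise SizingError(
                f"skip crop at level {lv} is odd ({enc[lv]} -> {x}); extent infeasible"
            )
        for c in range(spec.convs_per_block):
            x -= k - 1
            if x < 1:
                raise SizingError(
                    f"feature map vanishes at decoder level {lv} conv {c} (extent {x})"
                )
    return x


def valid_output_size(
    spec: ArchSpec, input_extent: int | Sequence[int]
) -> int | tuple[int, ...]:
    """Extent of the classified center for a given input extent.

    Accepts a scalar extent (applied per axis) or a per-axis sequence; the
    per-axis traces are independent.  Raises :class:`SizingError` naming
    the failing layer for infeasible extents.
    """
    if isinstance(input_extent, Sequence) and not isinstance(input_extent, (str, bytes)):
        return tuple(_trace_extent(spec, int(n)) for n in input_extent)
    return _trace_extent(spec, int(input_extent))


def receptive_field(spec: ArchSpec) -> int:
    """Maximum input extent (voxels, per axis) influencing one output voxel.

    Computed by the standard kernel/stride recursion over the traced layer
    list; upsampling contributes a fractional stride.
    """
    rf = Fraction(1)
    jump = Fraction(1)
    for _name, kind, extent in trace_layers(spec):
        if kind == "conv":
            rf += (extent - 1) * jump
        elif kind == "pool":
            rf += (extent - 1) * jump
            jump *= extent
        elif kind == "up":
            jump /= extent
    if rf.denominator != 1:
        raise SizingError(f"non-integral receptive field {rf}; malformed trace")
    return int(rf)


def receptive_field_mm(
    spec: ArchSpec, spacing: Sequence[float]
) -> tuple[float, ...]:
    """Physical receptive-field extent per axis for a given voxel spacing."""
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing components must be positive")
    rf = receptive_field(spec)
    return tuple(float(rf * s) for s in spacing)


def min_input_for_output(spec: ArchSpec, desired_output: int) -> int:
    """Smallest feasible input extent whose valid output is >= ``desired_output``."""
    if desired_output < 1:
        raise ValueError("desired_output must be >= 1")
    # the search space is bounded: reduction is fixed, feasibility is periodic
    # with period pool_extent**(levels-1)
    period = spec.pool_extent ** (spec.levels - 1)
    upper = desired_output + 2 * period + (
        receptive_field(spec) + spec.levels * spec.convs_per_block * spec.kernel_extent
    )
    for n in range(desired_output, upper + 1):
        try:
            if _trace_extent(spec, n) >= desired_output:
                return n
        except SizingError:
            continue
    raise SizingError(f"no feasible input extent found for output {desired_output}")


def full_pass_geometry(
    spec: ArchSpec, shape: Sequence[int]
) -> tuple[tuple[int, ...], tuple[tuple[int, int], ...]]:
    """Padded input extents and per-axis (before, after) pads so that a
    single forward pass yields an output covering an image of ``shape``.

    The symmetric valid reduction is split evenly before the image; the
    output region ``[0, shape)`` then aligns voxel-for-voxel with the
    image and any surplus output (from rounding up to a feasible extent)
    lies beyond it.
    """
    inputs = []
    pads = []
    for n in shape:
        i = min_input_for_output(spec, int(n))
        out = _trace_extent(spec, i)
        red = i - out
        if red % 2:
            raise SizingError(f"asymmetric valid reduction {red} for extent {i}")
        before = red // 2
        inputs.append(i)
        pads.append((before, i - int(n) - before))
    return tuple(inputs), tuple(pads)


@dataclass(frozen=True)
class PatchSpec:
    """Input patch extent and the classified center it maps to."""

    input_extent: tuple[int, ...] = (72, 72, 56)
    output_extent: tuple[int, ...] = (32, 32, 16)

    def __post_init__(self) -> None:
        if len(self.input_extent) != len(self.output_extent):
            raise ValueError("input and output extents must have equal rank")
        for i, o in zip(self.input_extent, self.output_extent):
            m = i - o
            if o < 1 or m < 0 or m % 2:
                raise ValueError(
                    f"margins must be non-negative and even, got input {i} -> output {o}"
                )

    @property
    def margin(self) -> tuple[int, ...]:
        return tuple((i - o) // 2 for i, o in zip(self.input_extent, self.output_extent))

    @classmethod
    def for_spec(cls, spec: ArchSpec, input_extent: Sequence[int]) -> "PatchSpec":
        """Derive the consistent center extent for an input extent."""
        out = tuple(_trace_extent(spec, int(n)) for n in input_extent)
        return cls(tuple(int(n) for n in input_extent), out)

    def check_consistent(self, spec: ArchSpec) -> None:
        traced = tuple(_trace_extent(spec, n) for n in self.input_extent)
        if traced != tuple(self.output_extent):
            raise SizingError(
                f"patch output {self.output_extent} inconsistent with traced {traced}"
            )
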
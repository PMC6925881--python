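"""Multispectral image cube container and TIFF I/O.

A stack is an H x W x C cube of nonnegative pixel values, one plane per
spectral channel, acquired at 16-bit depth.  Raw stacks hold integer digital
numbers; preparation steps (flat-field division, variance stabilisation)
return real-valued stacks, tracked by the dtype of ``pixels``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

from .channels import ChannelSet

__all__ = ["MultispectralStack", "read_stack", "write_stack"]


@dataclass
class MultispectralStack:
    pixels: np.ndarray  # (H, W, C)
    channels: ChannelSet
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if px.shape[2] != len(self.channels):
            raise ValueError(
                f"stack has {px.shape[2]} planes but channel set has "
                f"{len(self.channels)}")
        if np.any(px < 0):
            raise ValueError("pixel values must be nonnegative")
        if np.issubdtype(px.dtype, np.integer):
            if px.max(initial=0) > self.max_value:
                raise ValueError("pixel values exceed bit depth")
        self.pixels = px

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def astype_float(self) -> "MultispectralStack":
        return replace(self, pixels=self.pixels.astype(float))

    def copy(self) -> "MultispectralStack":
        return replace(self, pixels=self.pixels.copy())


def write_stack(stack: MultispectralStack, path) -> None:
    """Write as a multi-page TIFF, one page per channel."""
    planes = np.moveaxis(stack.pixels, 2, 0)
    tifffile.imwrite(path, planes)


def read_stack(path, channels: ChannelSet, bit_depth: int = 16) -> MultispectralStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    return MultispectralStack(np.moveaxis(planes, 0, 2), channels, bit_depth)
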
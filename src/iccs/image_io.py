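"""Reading, writing and pre-processing of two-channel fluorescence images.

Images are held as a pair of co-registered floating-point pixel grids.
Rectangular regions of interest (ROIs) use 0-based, row-major, half-open
coordinates ``[origin, origin + extent)``.  Background is estimated per ROI
from the low tail of the pixel-value distribution, which is robust to
sparse bright emitters, and subtracted before any fluctuation analysis so
that a constant offset does not deflate the normalized correlation
amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

MIN_ROI_EXTENT = 16


@dataclass
class TwoChannelImage:
    """Co-registered intensity grids for detection channels a and b.

    Parameters
    ----------
    pixels_a, pixels_b
        2D arrays of non-negative intensities (arbitrary units), identical
        shape.  Stored as float64.
    pixel_size
        Physical length per pixel, if known.  Not used by the correlation
        math (which works in pixel units) but carried through metadata.
    excitation_power_a, excitation_power_b
        Scalar normalization factors for intensity quantification.
    """

    pixels_a: np.ndarray
    pixels_b: np.ndarray
    pixel_size: float | None = None
    excitation_power_a: float = 1.0
    excitation_power_b: float = 1.0
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        self.pixels_a = np.asarray(self.pixels_a, dtype=np.float64)
        self.pixels_b = np.asarray(self.pixels_b, dtype=np.float64)
        if self.pixels_a.ndim != 2 or self.pixels_b.ndim != 2:
            raise ValueError("channel pixel grids must be 2D")
        if self.pixels_a.shape != self.pixels_b.shape:
            raise ValueError(
                f"channel shapes differ: {self.pixels_a.shape} vs {self.pixels_b.shape}"
            )
        if not (np.all(np.isfinite(self.pixels_a)) and np.all(np.isfinite(self.pixels_b))):
            raise ValueError("pixel intensities must be finite")
        if self.excitation_power_a <= 0 or self.excitation_power_b <= 0:
            raise ValueError("excitation powers must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels_a.shape


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open."""

    origin_row: int
    origin_col: int
    height: int = 64
    width: int = 64

    def __post_init__(self) -> None:
        if self.height < MIN_ROI_EXTENT or self.width < MIN_ROI_EXTENT:
            raise ValueError(
                f"ROI extents must be >= {MIN_ROI_EXTENT} pixels for fluctuation analysis"
            )
        if self.origin_row < 0 or self.origin_col < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, shape: tuple[int, int]) -> None:
        if self.origin_row + self.height > shape[0] or self.origin_col + self.width > shape[1]:
            raise ValueError(f"ROI {self} does not fit inside image of shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.origin_row, self.origin_row + self.height),
            slice(self.origin_col, self.origin_col + self.width),
        )

    @classmethod
    def parse(cls, text: str) -> "ROI":
        """Parse ``origin_row:origin_col:height:width``."""
        parts = [int(p) for p in text.strip().split(":")]
        if len(parts) != 4:
            raise ValueError(f"expected origin_row:origin_col:height:width, got {text!r}")
        return cls(*parts)

    def __str__(self) -> str:  # round-trips through parse()
        return f"{self.origin_row}:{self.origin_col}:{self.height}:{self.width}"


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel scalar background level and how it was obtained."""

    value_a: float
    value_b: float
    method: str = "user-supplied"

    def __post_init__(self) -> None:
        if self.value_a < 0 or self.value_b < 0:
            raise ValueError("background values must be non-negative")


def read_image(path: str | Path, channel_indices: tuple[int, int] = (0, 1)) -> TwoChannelImage:
    """Read two channel planes from a multichannel TIFF.

    The channel axis is taken to be the first axis of a 3D stack unless the
    last axis is small (<= 8) and the first is not, in which case the image
    is treated as channel-last.  Channels are returned in the order given by
    ``channel_indices`` (``pixels_a`` from the first index).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    elif arr.ndim == 3:
        if arr.shape[0] > 8 and arr.shape[-1] <= 8:
            arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"unsupported image dimensionality: {arr.shape}")
    ia, ib = channel_indices
    n_chan = arr.shape[0]
    for idx in (ia, ib):
        if not 0 <= idx < n_chan:
            raise IndexError(f"channel index {idx} out of range (file has {n_chan} channels)")
    return TwoChannelImage(
        pixels_a=arr[ia].astype(np.float64),
        pixels_b=arr[ib].astype(np.float64),
    )


def write_image(path: str | Path, image: TwoChannelImage) -> None:
    """Write the two channels as a 2-plane TIFF.

    Integer-valued images within the 16-bit range are stored as uint16 so a
    read/write round trip is bit-exact; everything else is stored float32.
    """
    stack = np.stack([image.pixels_a, image.pixels_b])
    if np.all(stack == np.round(stack)) and stack.min() >= 0 and stack.max() <= 65535:
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    tifffile.imwrite(Path(path), stack)


def estimate_background(
    image: TwoChannelImage, roi: ROI, percentile: float = 0.10
) -> BackgroundEstimate:
    """Estimate per-channel background as the mean of the lowest-value pixels.

    ``percentile`` is the fraction (in (0, 1)) of ROI pixels, taken from the
    bottom of the intensity distribution, that are averaged.  With sparse
    emitters the low tail is dominated by emitter-free pixels, making this a
    robust estimate of the additive offset.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    roi.validate(image.shape)
    values = []
    for pixels in (image.pixels_a, image.pixels_b):
        block = np.sort(pixels[roi.slices], axis=None)
        k = max(1, int(np.ceil(percentile * block.size)))
        values.append(float(block[:k].mean()))
    return BackgroundEstimate(value_a=values[0], value_b=values[1], method="low-percentile")


def subtract_background(image: TwoChannelImage, bg: BackgroundEstimate) -> TwoChannelImage:
    """Subtract a constant background per channel, clipping negatives to zero.

    Raises if the background exceeds a channel's mean intensity, which
    indicates a mis-estimated background rather than a dark image.
    """
    for value, pixels, label in (
        (bg.value_a, image.pixels_a, image.label_a),
        (bg.value_b, image.pixels_b, image.label_b),
    ):
        if value > pixels.mean():
            raise ValueError(
                f"background {value:.3g} exceeds mean intensity of channel {label!r}"
            )
    out_a = np.clip(image.pixels_a - bg.value_a, 0.0, None)
    out_b = np.clip(image.pixels_b - bg.value_b, 0.0, None)
    clipped = (
        np.count_nonzero(image.pixels_a < bg.value_a)
        + np.count_nonzero(image.pixels_b < bg.value_b)
    ) / (2 * image.pixels_a.size)
    if clipped > 0:
        logger.debug("background subtraction clipped %.1f%% of pixels", 100 * clipped)
    return replace(image, pixels_a=out_a, pixels_b=out_b)


def quantify_intensity(
    image: TwoChannelImage, roi: ROI, bg: BackgroundEstimate
) -> tuple[float, float]:
    """Background-corrected ROI mean intensity normalized to excitation power.

    Returns ``max(<I> - background, 0) / excitation_power`` per channel, so
    values acquired at different laser powers are directly comparable.
    """
    roi.validate(image.shape)
    out = []
    for pixels, value, power in (
        (image.pixels_a, bg.value_a, image.excitation_power_a),
        (image.pixels_b, bg.value_b, image.excitation_power_b),
    ):
        out.append(max(float(pixels[roi.slices].mean()) - value, 0.0) / power)
    return out[0], out[1]
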
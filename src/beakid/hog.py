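"""Histogram-of-oriented-gradients descriptors at the study geometry.

Gradients are centred differences with the (-1, 0, 1) kernel and replicated
borders; gradient magnitude |G| = sqrt(Gx^2 + Gy^2); orientation is the
unsigned angle of (Gx, Gy) folded to [0°, 180°).  The image is partitioned
into full square cells (default 128×128 px, partial edge cells dropped);
each pixel votes its magnitude into a 9-bin orientation histogram with the
vote split linearly between the two nearest bin centres (circular over
180°).  2×2-cell blocks slide with stride one cell; each 36-value block is
L2-normalised (all-zero blocks pass through) and the blocks are
concatenated row-major.

At the study's working resolution (~532×299 px) this geometry yields a
4×2 cell grid, 3 blocks, and a 108-value descriptor.

The colour variant computes gradients per RGB channel and lets the channel
with the largest magnitude at each pixel supply (|G|, Θ), so the descriptor
length equals the grey-HOG length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class HogParams:
    """HOG geometry: cell edge in pixels, orientation bins over 180°,
    block edge in cells, and block stride in cells."""

    cell_size: int = 128
    bins: int = 9
    block_size: int = 2
    block_stride: int = 1
    #: Orientation as printed transposes the gradient ratio
    #: (arctan Gx/Gy instead of arctan Gy/Gx); kept as an opt-in toggle.
    as_printed_orientation: bool = False
    #: Hard-assign each vote to the nearest bin instead of splitting it.
    hard_assignment: bool = False

    def __post_init__(self):
        if self.cell_size < 1 or self.bins < 1 or self.block_size < 1 or self.block_stride < 1:
            raise InvalidParameterError("HOG geometry values must be >= 1")

    @property
    def bin_width(self) -> float:
        return 180.0 / self.bins

    @property
    def bin_angles(self) -> np.ndarray:
        return np.arange(self.bins) * self.bin_width


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradients: Gx, Gy, magnitude and orientation in [0°, 180°)."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray


def gradients(gray: np.ndarray, as_printed: bool = False) -> GradientField:
    """Centred-difference gradients with replicated borders.

    Θ is the unsigned angle of the gradient vector, arctan(Gy/Gx) folded to
    [0°, 180°); zero-gradient pixels get Θ = 0 (they carry no vote weight).
    ``as_printed`` swaps the ratio to arctan(Gx/Gy).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or min(gray.shape) < 3:
        raise InvalidParameterError(f"need a 2-D image of at least 3x3 px, got shape {gray.shape}")
    padded = np.pad(gray, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    mag = np.hypot(gx, gy)
    if as_printed:
        theta = np.degrees(np.arctan2(gx, gy)) % 180.0
    else:
        theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    theta[mag == 0] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, orientation=theta)


def _colour_gradients(img: np.ndarray, as_printed: bool = False) -> GradientField:
    """Dominant-channel gradients: at each pixel the RGB channel with the
    largest gradient magnitude supplies (Gx, Gy); ties go to the lowest
    channel index."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected an (H, W, 3) image, got shape {img.shape}")
    fields = [gradients(img[..., ch], as_printed) for ch in range(3)]
    mags = np.stack([f.magnitude for f in fields])
    winner = np.argmax(mags, axis=0)  # argmax takes the first maximum: lowest channel wins ties
    gx = np.choose(winner, [f.gx for f in fields])
    gy = np.choose(winner, [f.gy for f in fields])
    mag = np.take_along_axis(mags, winner[None], axis=0)[0]
    if as_printed:
        theta = np.degrees(np.arctan2(gx, gy)) % 180.0
    else:
        theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    theta[mag == 0] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, orientation=theta)


def cell_grid_shape(shape: tuple[int, int], params: HogParams) -> tuple[int, int]:
    """(cells_y, cells_x): full cells only, partial edge cells dropped."""
    h, w = shape[:2]
    return h // params.cell_size, w // params.cell_size


def cell_histograms(field: GradientField, params: HogParams) -> np.ndarray:
    """Per-cell 9-bin orientation histograms, shape (cells_y, cells_x, bins).

    Each pixel votes its gradient magnitude, split linearly between the two
    nearest bin centres (circular over 180°); votes therefore conserve total
    gradient magnitude within the retained cells.
    """
    cy, cx = cell_grid_shape(field.magnitude.shape, params)
    if cy < 1 or cx < 1:
        raise InvalidParameterError(
            f"image {field.magnitude.shape} is smaller than one {params.cell_size}px cell"
        )
    c = params.cell_size
    mag = field.magnitude[: cy * c, : cx * c]
    theta = field.orientation[: cy * c, : cx * c]

    t = theta / params.bin_width
    lower = np.floor(t).astype(int) % params.bins
    frac = t - np.floor(t)
    upper = (lower + 1) % params.bins
    if params.hard_assignment:
        lower = np.rint(t).astype(int) % params.bins
        w_lower, w_upper = mag, np.zeros_like(mag)
        upper = lower
    else:
        w_lower = mag * (1.0 - frac)
        w_upper = mag * frac

    hists = np.zeros((cy, cx, params.bins))
    for b in range(params.bins):
        contrib = np.where(lower == b, w_lower, 0.0) + np.where(upper == b, w_upper, 0.0)
        hists[:, :, b] = contrib.reshape(cy, c, cx, c).sum(axis=(1, 3))
    return hists


def block_descriptor(hists: np.ndarray, params: HogParams) -> np.ndarray:
    """Slide block windows over the cell grid and concatenate the
    L2-normalised block vectors (zero blocks stay zero)."""
    cy, cx, bins = hists.shape
    bs, stride = params.block_size, params.block_stride
    if cy < bs or cx < bs:
        raise InvalidParameterError(
            f"cell grid {cy}x{cx} is smaller than a {bs}x{bs} block"
        )
    blocks = []
    for by in range(0, cy - bs + 1, stride):
        for bx in range(0, cx - bs + 1, stride):
            vec = hists[by : by + bs, bx : bx + bs].reshape(-1)
            norm = np.linalg.norm(vec)
            blocks.append(vec / norm if norm > 0 else vec)
    return np.concatenate(blocks)


def descriptor_length(shape: tuple[int, int], params: HogParams) -> int:
    """Closed-form descriptor length for an image of the given (H, W)."""
    cy, cx = cell_grid_shape(shape, params)
    bs, stride = params.block_size, params.block_stride
    ny = (cy - bs) // stride + 1
    nx = (cx - bs) // stride + 1
    return ny * nx * bs * bs * params.bins


def hog_descriptor(gray: np.ndarray, params: HogParams = HogParams()) -> np.ndarray:
    """Grey HOG descriptor of a 2-D image (108 values at the study geometry)."""
    field = gradients(gray, params.as_printed_orientation)
    hists = cell_histograms(field, params)
    return block_descriptor(hists, params)


def colour_hog_descriptor(img: np.ndarray, params: HogParams = HogParams()) -> np.ndarray:
    """Colour HOG: dominant-channel gradients, otherwise identical geometry,
    hence the same descriptor length as the grey variant."""
    field = _colour_gradients(img, params.as_printed_orientation)
    hists = cell_histograms(field, params)
    return block_descriptor(hists, params)
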
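"""Photograph preprocessing and beak segmentation.

The study pipeline downscales each photograph to 10% of its native size,
lightly Gaussian-smooths it, converts to luma grey via the ITU-R BT.601
weights Y = 0.299 R + 0.587 G + 0.114 B, thresholds at grey level 240 to
separate beak from lightbox, and traces the region-of-interest contour.

Both threshold polarities are provided: ``dark`` (object below the
threshold — a dark beak on a bright lightbox, the physically sensible
orientation and the default) and ``bright`` (object at or above the
threshold).
"""

from __future__ import annotations

import math

import numpy as np
from PIL import Image, ImageOps
from scipy import ndimage
from skimage import measure
from skimage.transform import resize as _sk_resize

from .errors import InvalidParameterError, NoRoiFoundError

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def load_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/JPEG), honouring EXIF orientation."""
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        return np.asarray(im.convert("RGB"))


def rescale(img: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear rescale by ``factor``; each dimension rounds half-up, min 1."""
    if not 0 < factor <= 1:
        raise InvalidParameterError(f"rescale factor must lie in (0, 1], got {factor}")
    if factor == 1.0:
        return img.copy()
    h, w = img.shape[:2]
    new_h = max(1, math.floor(h * factor + 0.5))
    new_w = max(1, math.floor(w * factor + 0.5))
    out = _sk_resize(
        img.astype(float), (new_h, new_w), order=1, anti_aliasing=False, preserve_range=True
    )
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).clip(0, 255).astype(img.dtype)
    return out


def gaussian_smooth(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Convolve with a normalised Gaussian (radius 3·sigma), per channel.

    ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img.copy()
    out = np.empty(img.shape, dtype=float)
    src = img.astype(float)
    if img.ndim == 2:
        ndimage.gaussian_filter(src, sigma, truncate=3.0, mode="nearest", output=out)
    else:
        for ch in range(img.shape[2]):
            ndimage.gaussian_filter(
                src[..., ch], sigma, truncate=3.0, mode="nearest", output=out[..., ch]
            )
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).clip(0, 255).astype(img.dtype)
    return out


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grey Y = 0.299 R + 0.587 G + 0.114 B, kept in floating point."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img.astype(float) @ np.asarray(GRAY_WEIGHTS)


def binarize(gray: np.ndarray, threshold: float = 240, object_polarity: str = "dark") -> np.ndarray:
    """Threshold a grey image into a boolean object mask.

    ``bright``: pixels with Y >= threshold are object (the orientation as
    printed for a lightbox protocol); ``dark``: pixels with Y < threshold
    are object (a dark beak on a bright background, the default).
    """
    if not 0 <= threshold <= 255:
        raise InvalidParameterError(f"threshold must lie in [0, 255], got {threshold}")
    gray = np.asarray(gray)
    if object_polarity == "bright":
        return gray >= threshold
    if object_polarity == "dark":
        return gray < threshold
    raise InvalidParameterError(
        f"object_polarity must be 'bright' or 'dark', got {object_polarity!r}"
    )


def extract_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Trace one closed outer contour per 8-connected object component.

    Each contour is an (N, 2) float array of (x, y) points, 0-based, x
    rightward and y downward, oriented clockwise in image coordinates and
    closed (first point == last point).  Contours are sub-pixel: they run
    through the half-level crossings around each component, so the traced
    polygon of a filled component rasterises back to that component.
    Holes inside a component are ignored (outer boundary only).
    An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    contours = []
    for lab in range(1, n + 1):
        comp = ndimage.binary_fill_holes(labels == lab)
        padded = np.pad(comp.astype(float), 1)
        traced = measure.find_contours(padded, 0.5, fully_connected="high")
        # fill_holes leaves a single outer boundary; keep the longest trace
        # defensively in case of sub-pixel slivers.
        rc = max(traced, key=len) - 1.0  # undo padding offset; (row, col)
        contours.append(rc[:, ::-1])  # -> (x, y)
    return contours


def smooth_contour(contour: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Regularise a raster-traced contour for metric measurements.

    A marching-squares trace of a digitised smooth boundary carries a
    staircase ripple that inflates its arc length by several percent (a
    digitised disc reads ~6% long), which biases every perimeter-derived
    shape descriptor.  This resamples the closed polygon at ~1 px arc
    spacing and applies a periodic Gaussian (sigma in samples ~ pixels) to
    the coordinate sequences, removing the pixelation ripple while leaving
    shape-scale geometry intact.  Contours shorter than 16 px are returned
    unchanged (nothing to regularise at that scale).  Returns a closed
    polygon (first point == last point).
    """
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    contour = np.asarray(contour, dtype=float)
    closed = (
        contour
        if np.allclose(contour[0], contour[-1])
        else np.vstack([contour, contour[:1]])
    )
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if sigma == 0 or length < 16:
        return contour
    n = max(int(round(length)), 8)
    t = np.linspace(0.0, length, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    xs = ndimage.gaussian_filter1d(x, sigma, mode="wrap")
    ys = ndimage.gaussian_filter1d(y, sigma, mode="wrap")
    out = np.column_stack([xs, ys])
    return np.vstack([out, out[:1]])


def contour_area(contour: np.ndarray) -> float:
    """Enclosed area of a closed contour by the surveyor's (shoelace) formula."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_perimeter(contour: np.ndarray) -> float:
    """Arc length of the closed contour polygon."""
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def fill_contour(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a closed contour back to a boolean mask of ``shape`` (H, W)."""
    from skimage.draw import polygon as draw_polygon

    rr, cc = draw_polygon(contour[:, 1], contour[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def select_roi(contours: list[np.ndarray], min_area: float = 100.0) -> np.ndarray:
    """Largest-area contour among those with area >= ``min_area``.

    Raises :class:`NoRoiFoundError` when nothing passes the filter — the
    segmentation picked up only noise specks.
    """
    best = None
    best_area = -np.inf
    for contour in contours:
        area = contour_area(contour)
        if area >= min_area and area > best_area:
            best, best_area = contour, area
    if best is None:
        raise NoRoiFoundError(f"no contour with area >= {min_area} px^2")
    return best


def segment_image(
    img: np.ndarray,
    *,
    rescale_factor: float = 0.1,
    sigma: float = 1.0,
    threshold: float = 240,
    object_polarity: str = "dark",
    min_area: float = 100.0,
):
    """Run the full preprocessing chain on one photograph.

    rescale -> Gaussian smooth -> grey conversion -> threshold -> contour
    trace -> largest-ROI selection.  Returns ``(working_rgb, gray, mask,
    roi_contour)`` where ``working_rgb`` is the rescaled, smoothed image the
    feature extractors consume.
    """
    small = rescale(img, rescale_factor)
    smooth = gaussian_smooth(small, sigma)
    gray = rgb_to_gray(smooth)
    mask = binarize(gray, threshold, object_polarity)
    roi = select_roi(extract_contours(mask), min_area)
    return smooth, gray, mask, roi
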
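"""Image preprocessing and threshold-based segmentation.

Images are reduced to the working representation the optimizers see: an
8-bit grayscale grid at a fixed size (default 256x256).  An optimized
threshold set is then applied per pixel, producing a label map and a
class-mean reconstruction — each pixel replaced by the mean intensity of
its threshold class.  Class-mean replacement is the standard "segmented
image" convention for thresholding quality metrics and is the unique rule
under which maximizing the between-class variance also maximizes the PSNR
of the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from .otsu import Histogram, ThresholdSet, compute_histogram

__all__ = [
    "SegmentationResult",
    "preprocess",
    "apply_thresholds",
    "mask_from_labels",
    "save_label_map",
    "colorize_labels",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class SegmentationResult:
    """Label map plus class-mean reconstruction for one threshold set.

    ``class_means`` holds the unrounded class representative intensities;
    ``reconstruction`` is the 8-bit image using means rounded
    half-to-even (empty classes get the midpoint of their bin range).
    """

    label_map: np.ndarray  # int labels 0..k
    reconstruction: np.ndarray  # uint8
    thresholds: ThresholdSet
    class_means: np.ndarray  # float, length k+1


def preprocess(
    image, target_size: tuple[int, int] = (256, 256)
) -> np.ndarray:
    """Load and normalize a raster image to an 8-bit grayscale grid.

    RGB inputs are converted to luminance (0.299 R + 0.587 G + 0.114 B),
    resized to ``target_size`` by bilinear interpolation, rescaled to
    [0, 1] and quantized back to 0..255 with round-half-to-even.
    Accepts a path or an ndarray (2-D gray or HxWx3 RGB).
    """
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "I;16") else im)
    else:
        arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("zero-size image")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError("expected 1 or 3 channels")
        r, g, b = (arr[..., c].astype(float) for c in range(3))
        gray = LUMINANCE_WEIGHTS[0] * r + LUMINANCE_WEIGHTS[1] * g + LUMINANCE_WEIGHTS[2] * b
    elif arr.ndim == 2:
        gray = arr.astype(float)
    else:
        raise ValueError("expected a 2-D or 3-channel image")
    if gray.shape != tuple(target_size):
        gray = resize(
            gray, target_size, order=1, preserve_range=True, anti_aliasing=False
        )
    # normalize to [0, 1], then quantize back to the 8-bit grid
    unit = np.clip(gray / 255.0, 0.0, 1.0)
    return np.rint(unit * 255.0).astype(np.uint8)


def apply_thresholds(
    image: np.ndarray, thresholds: ThresholdSet, hist: Histogram | None = None
) -> SegmentationResult:
    """Segment an 8-bit grid with a canonical threshold set.

    A pixel of value v gets label i when ``floor(t_i) < v <= floor(t_{i+1})``
    (labels 0..k, non-decreasing in intensity).  Class representatives are
    the class means computed from the image's own histogram.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D intensity grid")
    if hist is None:
        hist = compute_histogram(arr, n_levels=thresholds.n_levels)
    floors = thresholds.floors
    labels = np.searchsorted(floors, arr, side="left")

    L = hist.n_levels
    edges = np.concatenate(([-1], floors, [L - 1]))
    P = np.concatenate(([0.0], np.cumsum(hist.probs)))
    j = np.arange(L, dtype=float)
    M = np.concatenate(([0.0], np.cumsum(j * hist.probs)))
    lo, hi = edges[:-1] + 1, edges[1:] + 1
    w = P[hi] - P[lo]
    m = M[hi] - M[lo]
    occupied = w > 0.0
    midpoints = (edges[:-1] + 1 + edges[1:]) / 2.0  # fallback for empty classes
    class_means = np.where(occupied, m / np.where(occupied, w, 1.0), midpoints)

    levels = np.rint(class_means).astype(np.uint8)  # numpy rint = half-to-even
    reconstruction = levels[labels]
    return SegmentationResult(
        label_map=labels,
        reconstruction=reconstruction,
        thresholds=thresholds,
        class_means=class_means,
    )


def mask_from_labels(
    result: SegmentationResult, foreground_classes
) -> np.ndarray:
    """Binarize a multilevel segmentation by a chosen class subset.

    Overlap metrics against a ground-truth mask need a binary output; which
    classes count as foreground is application-dependent (e.g. the darkest
    class for nuclei on a bright background), so the subset is explicit.
    """
    fg = np.asarray(list(foreground_classes))
    return np.isin(result.label_map, fg)


def save_label_map(result: SegmentationResult, path, colorize: bool = False) -> None:
    """Write the label map (or a colorized version) as PNG."""
    if colorize:
        Image.fromarray(colorize_labels(result.label_map)).save(path)
    else:
        k = int(result.label_map.max()) if result.label_map.size else 0
        scale = 255 // max(k, 1)
        Image.fromarray((result.label_map * scale).astype(np.uint8)).save(path)


def colorize_labels(label_map: np.ndarray) -> np.ndarray:
    """Map class indices to distinct RGB colors for figures."""
    palette = np.array(
        [
            (68, 1, 84), (59, 82, 139), (33, 145, 140), (94, 201, 98),
            (253, 231, 37), (220, 50, 32), (0, 114, 178), (230, 159, 0),
            (204, 121, 167), (86, 180, 233), (0, 158, 115), (240, 228, 66),
            (120, 120, 120),
        ],
        dtype=np.uint8,
    )
    return palette[np.asarray(label_map) % len(palette)]
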
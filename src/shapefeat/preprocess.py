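"""RGB image to single-component plant mask.

Pipeline: 3x3 Gaussian smoothing -> excess-green (ExG) colour transform on
chromatic coordinates -> masking of underexposed (colour-unreliable)
pixels -> thresholding (Otsu on the reliable pixels, or a fixed
threshold) -> component rejoining, which bridges disconnected silhouette
fragments with minimal strips until a single connected component remains.

The segmentation here is a documented threshold segmenter (ExG + Otsu by
default, fixed-threshold fallback); plants on a dark soil background have
strongly positive ExG while soil is near zero or negative, so a global
threshold separates them cleanly under controlled lighting.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage import draw as skdraw
from skimage import filters, measure, morphology

from .errors import EmptyMaskError, ParameterError, SizeError

__all__ = [
    "GAUSSIAN_3X3",
    "smooth",
    "excess_green",
    "mask_underexposed",
    "segment",
    "connected_components",
    "rejoin_components",
    "binarize_image",
]

#: Normalized 3x3 binomial kernel, the standard discrete 3x3 Gaussian.
GAUSSIAN_3X3 = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0

DEFAULT_INTENSITY_FLOOR = 45  # R+G+B below this is colour-unreliable


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ParameterError("expected an H x W x 3 RGB array")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise SizeError("image must be at least 3 x 3 to admit the filter window")
    return image


def smooth(image: np.ndarray) -> np.ndarray:
    """Convolve each channel with the normalized 3x3 Gaussian kernel.

    Reflective border padding avoids darkening edges (which would bias ExG
    near the image border).  Constant images are fixed points.
    """
    image = _check_rgb(image).astype(float)
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = ndi.convolve(image[..., c], GAUSSIAN_3X3, mode="reflect")
    return out


def excess_green(image: np.ndarray) -> np.ndarray:
    """ExG = 2g - r - b on chromatic coordinates r,g,b = R,G,B / (R+G+B).

    Pixels with R+G+B = 0 map to 0.  The chromatic normalization cancels
    uniform intensity gain, so ExG depends on colour only.
    """
    image = _check_rgb(image).astype(float)
    total = image.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = image / total[..., None]
    exg = 2 * chrom[..., 1] - chrom[..., 0] - chrom[..., 2]
    return np.where(total > 0, exg, 0.0)


def mask_underexposed(image: np.ndarray, intensity_floor: int = DEFAULT_INTENSITY_FLOOR) -> np.ndarray:
    """Boolean grid of colour-unreliable pixels: R+G+B < intensity_floor."""
    if intensity_floor < 0:
        raise ParameterError("intensity_floor must be >= 0")
    image = _check_rgb(image).astype(float)
    return image.sum(axis=2) < intensity_floor


def segment(
    exg: np.ndarray,
    unreliable: np.ndarray | None = None,
    method: str = "otsu",
    fixed_threshold: float = 0.1,
) -> np.ndarray:
    """Threshold the ExG grid into a binary plant mask.

    Object pixels have ExG above the threshold and are colour-reliable.
    With ``method="otsu"`` the threshold is computed on reliable pixels
    only; ``method="fixed"`` uses ``fixed_threshold`` directly.
    """
    exg = np.asarray(exg, dtype=float)
    if unreliable is None:
        unreliable = np.zeros(exg.shape, dtype=bool)
    unreliable = np.asarray(unreliable, dtype=bool)
    if unreliable.shape != exg.shape:
        raise ParameterError("exg and unreliable grids must share shape")
    reliable = ~unreliable
    if not reliable.any():
        raise EmptyMaskError("all pixels are marked unreliable")
    if method == "otsu":
        threshold = filters.threshold_otsu(exg[reliable])
    elif method == "fixed":
        threshold = fixed_threshold
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")
    mask = (exg > threshold) & reliable
    if not mask.any():
        raise EmptyMaskError("segmentation produced an empty mask")
    return mask


def connected_components(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label object pixels 1..K (background 0); 4- or 8-connectivity."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    labels, count = measure.label(
        np.asarray(mask, dtype=bool),
        connectivity=1 if connectivity == 4 else 2,
        return_num=True,
    )
    return labels, count


def _contour_pixels(component: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of component pixels adjacent to background,
    sorted lexicographically so argmin tie-breaks deterministically."""
    boundary = component & ~ndi.binary_erosion(component)
    coords = np.argwhere(boundary)
    return coords  # np.argwhere is already in row-major (lexicographic) order


def rejoin_components(
    mask: np.ndarray,
    strip_width_px: int = 2,
    connectivity: int = 8,
    max_joins: int | None = None,
) -> np.ndarray:
    """Bridge disconnected fragments until one component remains.

    Iteratively the pair of components with the smallest contour-to-contour
    Euclidean distance is joined by a filled strip along the segment
    between their closest contour points (Bresenham line dilated to
    ``strip_width_px``).  Ties are broken by the lexicographically smallest
    (row, col) point pair.  Original object pixels are never removed.

    ``max_joins`` limits the number of joins (useful for inspecting the
    join order); by default the process runs to a single component.
    """
    if strip_width_px < 1:
        raise ParameterError("strip_width_px must be >= 1")
    mask = np.asarray(mask, dtype=bool).copy()
    if not mask.any():
        raise EmptyMaskError("cannot rejoin an empty mask")
    joins = 0
    while True:
        labels, count = connected_components(mask, connectivity)
        if count <= 1 or (max_joins is not None and joins >= max_joins):
            return mask
        contours = {k: _contour_pixels(labels == k) for k in range(1, count + 1)}
        best: tuple[float, tuple, tuple] | None = None
        for i in range(1, count + 1):
            for j in range(i + 1, count + 1):
                d = cdist(contours[i], contours[j])
                flat = np.argmin(d)  # first minimum = lexicographic smallest pair
                pi, pj = np.unravel_index(flat, d.shape)
                cand = (
                    float(d[pi, pj]),
                    tuple(contours[i][pi]),
                    tuple(contours[j][pj]),
                )
                if best is None or cand < best:
                    best = cand
        _, pa, pb = best
        rr, cc = skdraw.line(pa[0], pa[1], pb[0], pb[1])
        strip = np.zeros_like(mask)
        strip[rr, cc] = True
        if strip_width_px > 1:
            strip = morphology.dilation(strip, morphology.footprint_rectangle((strip_width_px, strip_width_px)))
        mask |= strip
        joins += 1


def binarize_image(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float = 0.1,
    intensity_floor: int = DEFAULT_INTENSITY_FLOOR,
    strip_width_px: int = 2,
) -> np.ndarray:
    """Full preprocessing chain: RGB image -> single-component plant mask."""
    smoothed = smooth(image)
    exg = excess_green(smoothed)
    unreliable = mask_underexposed(smoothed, intensity_floor)
    mask = segment(exg, unreliable, method=method, fixed_threshold=fixed_threshold)
    return rejoin_components(mask, strip_width_px=strip_width_px)
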
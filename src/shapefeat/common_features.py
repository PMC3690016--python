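"""The 21-feature common shape-feature set (CFS).

A literature baseline against which the distance-distribution features are
compared: the seven Hu moment invariants, region and contour measures
(area, perimeter, convex hull area/perimeter, solidity, perimeter ratio,
compactness, eccentricity), the Peura-Iivarinen circular and elliptic
variances of the contour, and four skeleton statistics.

Conventions
-----------
* The contour is the 0.5-level isoline of the mask (sub-pixel, marching
  squares) with collinear points pruned; perimeter is its arc length.
  Measuring the perimeter on this polygon rather than counting pixel
  edges stabilizes compactness and perimeter ratio across rotations.
* ``area`` is the object pixel count and ``convex_area`` the pixel count
  of the filled convex hull, so solidity is guaranteed to be <= 1.
* Compactness is normalized to (0, 1]: 4*pi*area / perimeter**2.
* Skeleton features: skeleton length / perimeter, endpoint count,
  branch-point count, and mean medial distance along the skeleton divided
  by the maximum distance (a width ratio).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from skimage import measure, morphology

from .distance_features import DistanceMap, FeatureVector, distance_transform
from .errors import EmptyMaskError, MultiComponentError, ParameterError

__all__ = [
    "CFS_FEATURE_NAMES",
    "ContourPolygon",
    "trace_contour",
    "hu_moments",
    "region_features",
    "variance_features",
    "skeleton_features",
    "cfs",
]

CFS_FEATURE_NAMES = (
    "hu_1",
    "hu_2",
    "hu_3",
    "hu_4",
    "hu_5",
    "hu_6",
    "hu_7",
    "area",
    "perimeter",
    "convex_area",
    "eccentricity",
    "solidity",
    "convex_perimeter",
    "perimeter_ratio",
    "compactness",
    "circular_variance",
    "elliptic_variance",
    "skel_length_ratio",
    "skel_endpoints",
    "skel_branchpoints",
    "skel_mean_width",
)

#: CFS features invariant under translation, lattice rotation and flips
#: (everything except the size-dependent area/perimeter/hull measures).
CFS_INVARIANT_NAMES = tuple(
    n
    for n in CFS_FEATURE_NAMES
    if n not in ("area", "perimeter", "convex_area", "convex_perimeter")
)


@dataclass(frozen=True)
class ContourPolygon:
    """Outer boundary as ordered (row, col) vertices; closure implicit."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ParameterError("contour needs >= 3 (row, col) vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def smoothed(self, iterations: int = 1) -> "ContourPolygon":
        """Closed-polyline moving average (window 3), one pass by default.

        The raw marching-squares isoline staircases along the lattice and
        overestimates arc length by ~5%; a single smoothing pass removes
        that bias (a disk's smoothed perimeter is within 0.3% of 2*pi*R)
        without eroding genuine shape detail.
        """
        v = self.vertices
        for _ in range(iterations):
            v = (np.roll(v, 1, axis=0) + v + np.roll(v, -1, axis=0)) / 3.0
        return ContourPolygon(v)

    @property
    def signed_area(self) -> float:
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * np.sum(r * np.roll(c, -1) - c * np.roll(r, -1)))

    @property
    def area(self) -> float:
        return abs(self.signed_area)


def _check_single_component(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no object pixels")
    if measure.label(mask, connectivity=2).max() > 1:
        raise MultiComponentError("multi-component mask; run rejoin_components first")
    return mask


def _prune_collinear(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    prev = np.roll(points, 1, axis=0)
    nxt = np.roll(points, -1, axis=0)
    cross = (points[:, 0] - prev[:, 0]) * (nxt[:, 1] - prev[:, 1]) - (
        points[:, 1] - prev[:, 1]
    ) * (nxt[:, 0] - prev[:, 0])
    return points[np.abs(cross) > tol]


def trace_contour(mask: np.ndarray) -> ContourPolygon:
    """Sub-pixel outer boundary in consistent (counter-clockwise) order.

    The 0.5-level marching-squares isoline of the padded mask, with
    duplicate endpoint and collinear vertices removed.  For convex shapes
    its shoelace area is within one cell count of the pixel area.
    """
    mask = _check_single_component(mask)
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=len)
    points = outer[:-1] - 1.0  # drop duplicated endpoint, undo padding
    points = _prune_collinear(points)
    poly = ContourPolygon(points)
    if poly.signed_area < 0:
        poly = ContourPolygon(points[::-1])
    return poly


def hu_moments(mask: np.ndarray) -> np.ndarray:
    """The seven Hu invariants of the filled region (normalized central
    moments), invariant to translation, scale and rotation."""
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        raise EmptyMaskError("mask has no object pixels")
    mu = measure.moments_central(mask)
    nu = measure.moments_normalized(mu)
    return measure.moments_hu(nu)


def region_features(mask: np.ndarray, contour: ContourPolygon | None = None) -> dict[str, float]:
    """Area, perimeter, hull measures, solidity, compactness, eccentricity."""
    mask = _check_single_component(mask)
    if contour is None:
        contour = trace_contour(mask)
    area = float(mask.sum())
    perimeter = contour.smoothed().perimeter
    hull = ConvexHull(contour.vertices)
    convex_perimeter = float(hull.area)  # in 2-D, .area is the perimeter
    convex_area = float(morphology.convex_hull_image(mask).sum())

    mu = measure.moments_central(mask.astype(float))
    m00 = mu[0, 0]
    cov = np.array([[mu[2, 0], mu[1, 1]], [mu[1, 1], mu[0, 2]]]) / m00
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam1, lam2 = max(eigvals[0], 1e-12), max(eigvals[1], 0.0)
    eccentricity = float(np.sqrt(1.0 - lam2 / lam1))

    return {
        "area": area,
        "perimeter": perimeter,
        "convex_area": convex_area,
        "eccentricity": eccentricity,
        "solidity": area / convex_area,
        "convex_perimeter": convex_perimeter,
        "perimeter_ratio": min(1.0, convex_perimeter / perimeter),
        "compactness": min(1.0, 4.0 * np.pi * area / perimeter**2),
    }


def variance_features(contour: ContourPolygon) -> tuple[float, float]:
    """Circular and elliptic variance of the contour (Peura-Iivarinen).

    Circular variance measures the normalized spread of vertex radii about
    the centroid; elliptic variance is the analogue with the Mahalanobis
    radius under the contour covariance, so ellipses score near zero.
    Both are invariant to similarity transforms.
    """
    v = contour.vertices
    centroid = v.mean(axis=0)
    d = v - centroid
    radii = np.linalg.norm(d, axis=1)
    mu_r = radii.mean()
    circular = float(np.mean((radii - mu_r) ** 2) / mu_r**2)

    cov = np.cov(d.T)
    inv = np.linalg.pinv(cov)
    mahal = np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))
    mu_m = mahal.mean()
    elliptic = float(np.mean((mahal - mu_m) ** 2) / mu_m**2)
    return circular, elliptic


def _canonical_orientation(mask: np.ndarray) -> np.ndarray:
    """Crop to the bounding box and pick a canonical dihedral orientation.

    Lattice thinning is anisotropic, so a skeleton computed on a rotated
    mask is not the rotated skeleton.  Statistics computed on the
    canonical orientation (the lexicographically smallest of the eight
    rotations/flips) are exactly invariant under translations, 90-degree
    rotations and axis flips.
    """
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    cropped = mask[np.ix_(rows, cols)]
    variants = []
    for k in range(4):
        rot = np.rot90(cropped, k)
        for var in (rot, rot[:, ::-1]):
            variants.append((var.shape, np.packbits(var).tobytes(), var))
    variants.sort(key=lambda t: (t[0], t[1]))
    return variants[0][2]


def skeleton_features(
    mask: np.ndarray,
    dmap: DistanceMap | None = None,
    perimeter: float | None = None,
) -> dict[str, float]:
    """Four skeleton statistics of a single-component mask.

    Length counts unit steps between 8-adjacent skeleton pixels (sqrt(2)
    for diagonals); endpoints have one skeleton neighbour, branch points
    three or more.  Mean width is the mean distance-map value along the
    skeleton relative to the object's maximum distance.  The skeleton is
    thinned on a canonical orientation of the mask (see
    ``_canonical_orientation``), so all four values are invariant under
    lattice rotations and flips; distance values are unaffected because
    the transform pads with background.
    """
    mask = _check_single_component(mask)
    if perimeter is None:
        perimeter = trace_contour(mask).smoothed().perimeter
    mask = _canonical_orientation(mask)
    # distances must align with the canonical orientation; the multiset of
    # distances (hence the max) is unchanged, so a caller-provided dmap is
    # only consulted for the normalizer
    max_from_caller = float(np.max(dmap)) if dmap is not None else None
    dmap = distance_transform(mask)
    skel = morphology.skeletonize(mask)
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    neighbours = ndi.convolve(skel.astype(int), kernel, mode="constant")
    endpoints = int(np.sum(skel & (neighbours == 1)))
    branchpoints = int(np.sum(skel & (neighbours >= 3)))

    # length: each adjacent pixel pair contributes its step length once
    orth = (skel[:, 1:] & skel[:, :-1]).sum() + (skel[1:, :] & skel[:-1, :]).sum()
    diag = (skel[1:, 1:] & skel[:-1, :-1]).sum() + (skel[1:, :-1] & skel[:-1, 1:]).sum()
    length = float(orth + np.sqrt(2.0) * diag)

    on_skel = dmap[skel]
    max_d = max_from_caller if max_from_caller is not None else float(dmap.max())
    mean_width = float(on_skel.mean() / max_d) if on_skel.size else 0.0
    return {
        "skel_length_ratio": length / perimeter,
        "skel_endpoints": float(endpoints),
        "skel_branchpoints": float(branchpoints),
        "skel_mean_width": mean_width,
    }


def cfs(mask: np.ndarray, sample_id: str = "") -> FeatureVector:
    """Compute the full 21-value common feature set for one mask."""
    mask = _check_single_component(mask)
    contour = trace_contour(mask)
    hu = hu_moments(mask)
    region = region_features(mask, contour)
    circ, ellip = variance_features(contour)
    skel = skeleton_features(mask, perimeter=contour.smoothed().perimeter)
    values = {f"hu_{i + 1}": float(h) for i, h in enumerate(hu)}
    values.update(region)
    values["circular_variance"] = circ
    values["elliptic_variance"] = ellip
    values.update(skel)
    ordered = np.array([values[name] for name in CFS_FEATURE_NAMES])
    return FeatureVector("CFS", CFS_FEATURE_NAMES, ordered, None, sample_id)
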
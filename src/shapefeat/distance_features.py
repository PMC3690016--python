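"""Distance-transform shape descriptors: RSFS and LPFS feature sets.

The descriptor of a silhouette is the distribution of Euclidean distances
from each object pixel to the nearest background pixel.  Collecting all
distances and sorting them ascending yields a monotone series that is
exactly invariant to translation and to lattice rotations (sorting discards
pixel order).  Four *data mappings* of that series are supported:

==============  ======================================================
``sort``        the sorted distances themselves
``scaled``      sorted distances divided by the maximum distance
``accu``        prefix sums of the sorted distances
``accuScaled``  prefix sums divided by the final (total) sum
==============  ======================================================

The ``scaled`` and ``accuScaled`` mappings end at exactly 1 and are
approximately scale invariant; ``sort`` and ``accu`` deliberately are not.

Two feature families parametrize a mapped series of length N:

* RSFS — eleven equidistant rank positions spanning the series; the first
  (always the minimum distance, carrying no information) is discarded,
  leaving ten sampled values ``s_1..s_10``.
* LPFS — the ten coefficients ``a_1..a_10`` of a degree-9 expansion in
  Legendre polynomials ``p_1(x)=1, p_2(x)=x, ...`` fitted to the series
  over abscissae rescaled to [-1, 1].  Legendre coefficients are mutually
  (near-)uncorrelated, so individual coefficients can be dropped without
  refitting the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import EmptyMaskError, MultiComponentError, ParameterError, TooFewPixelsError

__all__ = [
    "MAPPING_KINDS",
    "DistanceMap",
    "MappedDistribution",
    "LegendreBasisCache",
    "FeatureVector",
    "distance_transform",
    "extract_sorted",
    "apply_mapping",
    "rsfs",
    "rescale_abscissae",
    "legendre_basis",
    "fit_legendre",
    "reconstruct",
    "featurize",
]

MAPPING_KINDS = ("sort", "scaled", "accu", "accuScaled")

N_FEATURES = 10  # both feature families emit ten values


@dataclass(frozen=True)
class MappedDistribution:
    """A 1-D nondecreasing distance series tagged with its mapping kind."""

    y: np.ndarray
    mapping_kind: str

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class LegendreBasisCache:
    """Rows ``basis[n-1, i] = p_n(x_i)`` for n = 1..order."""

    order: int
    x: np.ndarray
    basis: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class FeatureVector:
    set_kind: str  # RSFS | LPFS | CFS
    names: tuple[str, ...]
    values: np.ndarray
    mapping_kind: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ParameterError("names and values must align")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# distance map values: d > 0 on object pixels, -1 sentinel elsewhere
DistanceMap = np.ndarray


def distance_transform(mask: np.ndarray) -> DistanceMap:
    """Exact Euclidean distance of every object pixel to the nearest
    background pixel center; ``-1`` off the object.

    The mask is padded with one background pixel so objects touching the
    border still have finite distances; a boundary object pixel therefore
    maps to exactly 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no object pixels")
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return np.where(mask, dist, -1.0)


def extract_sorted(dmap: DistanceMap) -> MappedDistribution:
    """Collect all distances != -1 and sort ascending (``sort`` mapping)."""
    values = np.asarray(dmap, dtype=float)
    dists = values[values != -1.0]
    if dists.size == 0:
        raise EmptyMaskError("distance map holds no object distances")
    return MappedDistribution(np.sort(dists, kind="stable"), "sort")


def apply_mapping(sorted_dist: MappedDistribution, kind: str) -> MappedDistribution:
    """Map a sorted distance series to one of the four representations."""
    if sorted_dist.mapping_kind != "sort":
        raise ParameterError("apply_mapping expects a 'sort' series")
    if kind not in MAPPING_KINDS:
        raise ParameterError(f"unknown mapping kind {kind!r}")
    y = sorted_dist.y
    if kind == "sort":
        return sorted_dist
    if kind == "scaled":
        return MappedDistribution(y / y[-1], "scaled")
    accu = np.cumsum(y)
    if kind == "accu":
        return MappedDistribution(accu, "accu")
    return MappedDistribution(accu / accu[-1], "accuScaled")


def rsfs(mapped: MappedDistribution) -> FeatureVector:
    """Resampled feature set: the series read at ten equidistant ranks.

    Eleven equidistant indices cover the whole vector; the first (rank 0,
    always the minimum distance) is discarded.  Indices are rounded
    half-up for determinism.
    """
    n = mapped.n
    if n < N_FEATURES + 1:
        raise TooFewPixelsError(f"RSFS needs >= {N_FEATURES + 1} pixels, got {n}")
    j = np.arange(1, N_FEATURES + 1)
    idx = np.floor(j * (n - 1) / N_FEATURES + 0.5).astype(int)
    names = tuple(f"s_{k}" for k in j)
    return FeatureVector("RSFS", names, mapped.y[idx].copy(), mapped.mapping_kind)


def rescale_abscissae(n: int) -> np.ndarray:
    """Equidistant abscissae spanning [-1, 1]: x_i = 2(i-1)/(N-1) - 1."""
    if n < 2:
        raise ParameterError("need at least 2 points to span [-1, 1]")
    return np.linspace(-1.0, 1.0, n)


def legendre_basis(order: int, x: np.ndarray) -> LegendreBasisCache:
    """Evaluate p_1..p_order on ``x`` via the three-term recursion

    p_{n+2}(x) = [(2n+1) x p_{n+1}(x) - n p_n(x)] / (n+1),
    with p_1 = 1 and p_2 = x.
    """
    if order < 1:
        raise ParameterError("order must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ParameterError("abscissae must lie in [-1, 1]")
    basis = np.empty((order, len(x)))
    basis[0] = 1.0
    if order > 1:
        basis[1] = x
    for n in range(1, order - 1):  # fills row n+1, i.e. p_{n+2}
        basis[n + 1] = ((2 * n + 1) * x * basis[n] - n * basis[n - 1]) / (n + 1)
    return LegendreBasisCache(order, x, basis)


def fit_legendre(
    mapped: MappedDistribution,
    order: int = N_FEATURES,
    method: str = "lstsq",
) -> FeatureVector:
    """Estimate the Legendre coefficients a_1..a_order of a mapped series.

    ``method="lstsq"`` (default) solves the discrete least-squares problem
    min ||B^T a - y||, which recovers exactly representable series to
    machine precision.  ``method="projection"`` uses the orthogonal-basis
    ratio a_n = <p_n, y> / <p_n, p_n> with plain discrete sums; on a finite
    equidistant grid the basis is only approximately orthogonal, so the
    two estimators differ by O(1/N).
    """
    n = mapped.n
    if n < order:
        raise TooFewPixelsError(f"need N >= order ({order}), got N = {n}")
    x = rescale_abscissae(n)
    cache = legendre_basis(order, x)
    b = cache.basis
    if method == "lstsq":
        coeffs, *_ = np.linalg.lstsq(b.T, mapped.y, rcond=None)
    elif method == "projection":
        coeffs = (b @ mapped.y) / np.einsum("ij,ij->i", b, b)
    else:
        raise ParameterError(f"unknown fit method {method!r}")
    names = tuple(f"a_{k}" for k in range(1, order + 1))
    return FeatureVector("LPFS", names, coeffs, mapped.mapping_kind)


def reconstruct(coeffs: FeatureVector | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate P(x_i) = sum_n a_n p_n(x_i) at the given abscissae."""
    a = coeffs.values if isinstance(coeffs, FeatureVector) else np.asarray(coeffs, float)
    cache = legendre_basis(len(a), x)
    return a @ cache.basis


def featurize(
    mask: np.ndarray,
    set_kind: str,
    mapping_kind: str = "scaled",
    order: int = N_FEATURES,
    sample_id: str = "",
) -> FeatureVector:
    """Full descriptor pipeline for a single-component mask.

    Composition: distance transform -> sorted series -> data mapping ->
    RSFS resampling or LPFS Legendre fit.
    """
    mask = np.asarray(mask, dtype=bool)
    if measure.label(mask, connectivity=2).max() > 1:
        raise MultiComponentError("mask has multiple components; rejoin first")
    mapped = apply_mapping(extract_sorted(distance_transform(mask)), mapping_kind)
    if set_kind == "RSFS":
        fv = rsfs(mapped)
    elif set_kind == "LPFS":
        fv = fit_legendre(mapped, order=order)
    else:
        raise ParameterError(f"set_kind must be RSFS or LPFS, got {set_kind!r}")
    return FeatureVector(fv.set_kind, fv.names, fv.values, mapping_kind, sample_id)
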
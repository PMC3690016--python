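"""Synthetic two-class seedling silhouettes and analytic geometric fixtures.

Real cotyledon-stage seedlings of the two target species differ mainly in
leaflet shape: one species carries elongated, strap-like leaflets, the
other rounded ones.  The generator emulates exactly that contrast: each
sample is a union of 2-3 filled ellipses ("leaflets") attached to a common
centre by thin stems, with random pose, size and leaflet aspect ratio.
Optionally a leaflet is disconnected by erasing a band across its stem so
that the component-rejoining stage of the preprocessing pipeline can be
exercised.

Analytic fixtures (disks, rectangles) use a pixel-center-inside membership
rule so lattice-count oracles are unambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage import draw as skdraw
from skimage import measure, morphology

from .errors import ParameterError, SizeError

__all__ = [
    "ShapeClassSpec",
    "SyntheticSample",
    "ELONGATED_SPEC",
    "ROUNDED_SPEC",
    "make_disk",
    "make_rectangle",
    "generate_samples",
    "write_samples",
    "load_specs",
]

DEFAULT_IMAGE_SIZE = (256, 256)


@dataclass(frozen=True)
class ShapeClassSpec:
    """Parameters of one synthetic seedling class.

    Leaflet aspect is the major/minor axis ratio of each elliptical
    leaflet, drawn from Normal(mean, sd) and clipped at 1.05 so a leaflet
    can never invert.  Lengths are in pixels; ``fragment_prob`` is the
    probability that one leaflet is disconnected from the plant body.
    """

    class_label: str
    leaflet_aspect_mean: float
    leaflet_aspect_sd: float
    n_leaflets_range: tuple[int, int] = (2, 3)
    leaflet_length_px_range: tuple[int, int] = (40, 80)
    petiole_length_px_range: tuple[int, int] = (2, 8)
    fragment_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.leaflet_aspect_mean <= 1:
            raise ParameterError("leaflet_aspect_mean must exceed 1")
        if self.leaflet_aspect_sd < 0:
            raise ParameterError("leaflet_aspect_sd must be >= 0")
        if not 0 <= self.fragment_prob <= 1:
            raise ParameterError("fragment_prob must lie in [0, 1]")
        lo, hi = self.n_leaflets_range
        if not (1 <= lo <= hi):
            raise ParameterError("n_leaflets_range must satisfy 1 <= lo <= hi")
        llo, lhi = self.leaflet_length_px_range
        if not (0 < llo <= lhi):
            raise ParameterError("leaflet lengths must be positive")
        plo, phi = self.petiole_length_px_range
        if not (0 <= plo <= phi):
            raise ParameterError("petiole lengths must be >= 0")


#: Default class specifications: the elongated-leaflet class emulates the
#: strap-leaved species, the rounded class the round-leaved one.
ELONGATED_SPEC = ShapeClassSpec("elongated", leaflet_aspect_mean=5.0, leaflet_aspect_sd=0.3)
ROUNDED_SPEC = ShapeClassSpec("rounded", leaflet_aspect_mean=1.6, leaflet_aspect_sd=0.3)


@dataclass(frozen=True)
class SyntheticSample:
    mask: np.ndarray
    class_label: str
    sample_id: str
    seed: int
    params_used: ShapeClassSpec = field(repr=False)


def make_disk(radius_px: int, image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Filled disk: pixels whose center lies within ``radius_px`` of the image center."""
    if radius_px < 1:
        raise SizeError("radius_px must be a positive integer")
    h, w = image_size
    if 2 * radius_px + 2 > min(h, w):
        raise SizeError(f"disk of radius {radius_px} does not fit in {image_size}")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def make_ellipse(
    semi_major_px: float,
    semi_minor_px: float,
    angle_rad: float = 0.0,
    image_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Filled rotated ellipse under the pixel-center-inside rule.

    A single-leaflet analytic fixture: semi-axes in pixels, major axis
    rotated by ``angle_rad`` from the column axis.
    """
    if semi_major_px < semi_minor_px or semi_minor_px <= 0:
        raise SizeError("need semi_major >= semi_minor > 0")
    if image_size is None:
        side = int(2 * semi_major_px + 10)
        image_size = (side, side)
    h, w = image_size
    if 2 * semi_major_px + 2 > min(h, w):
        raise SizeError(f"ellipse does not fit in {image_size}")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * np.cos(angle_rad) + (yy - cy) * np.sin(angle_rad)
    v = -(xx - cx) * np.sin(angle_rad) + (yy - cy) * np.cos(angle_rad)
    return (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0


def make_rectangle(
    width_px: int, height_px: int, image_size: tuple[int, int]
) -> np.ndarray:
    """Axis-aligned filled rectangle centered in the image, >=1 px margin."""
    if width_px < 1 or height_px < 1:
        raise SizeError("rectangle sides must be positive")
    h, w = image_size
    if height_px + 2 > h or width_px + 2 > w:
        raise SizeError(f"{width_px}x{height_px} rectangle does not fit in {image_size}")
    r0 = (h - height_px) // 2
    c0 = (w - width_px) // 2
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r0 + height_px, c0 : c0 + width_px] = True
    return mask


def _thick_line(mask: np.ndarray, p0: tuple[int, int], p1: tuple[int, int]) -> None:
    """Draw a ~3 px wide stem segment into ``mask`` in place."""
    rr, cc = skdraw.line(p0[0], p0[1], p1[0], p1[1])
    stem = np.zeros_like(mask)
    stem[rr.clip(0, mask.shape[0] - 1), cc.clip(0, mask.shape[1] - 1)] = True
    mask |= morphology.dilation(stem, morphology.disk(1))


def _draw_plant(rng: np.random.Generator, spec: ShapeClassSpec, image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    center = np.array([h / 2.0, w / 2.0]) + rng.uniform(-5, 5, size=2)

    n_lo, n_hi = spec.n_leaflets_range
    n = int(rng.integers(n_lo, n_hi + 1))
    base = rng.uniform(0, 2 * np.pi)
    leaflets = []
    for i in range(n):
        # cotyledon-stage morphology: the first two leaflets are opposite
        # cotyledons; any further leaflet is a smaller emerging true leaf
        # placed perpendicular to the cotyledon axis
        if i < 2:
            angle = base + np.pi * i + rng.normal(0, 0.12)
            length_scale = 1.0
        else:
            angle = base + np.pi / 2 + np.pi * (i - 2) + rng.normal(0, 0.12)
            length_scale = 0.45
        length = int(round(length_scale * rng.integers(*_incl(spec.leaflet_length_px_range))))
        aspect = max(1.05, rng.normal(spec.leaflet_aspect_mean, spec.leaflet_aspect_sd))
        petiole = int(rng.integers(*_incl(spec.petiole_length_px_range)))
        direction = np.array([np.sin(angle), np.cos(angle)])
        ell_center = center + (petiole + length / 2.0) * direction
        rr, cc = skdraw.ellipse(
            ell_center[0],
            ell_center[1],
            r_radius=length / 2.0,
            c_radius=length / (2.0 * aspect),
            rotation=-(angle - np.pi / 2),
            shape=(h, w),
        )
        mask[rr, cc] = True
        _thick_line(
            mask,
            tuple(np.round(center).astype(int)),
            tuple(np.round(ell_center).astype(int)),
        )
        leaflets.append((angle, petiole, length, direction))

    if rng.random() < spec.fragment_prob:
        _fragment(mask, rng, center, leaflets)
    return mask


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _fragment(
    mask: np.ndarray,
    rng: np.random.Generator,
    center: np.ndarray,
    leaflets: list[tuple[float, int, int, np.ndarray]],
) -> None:
    """Disconnect one leaflet tip by erasing a band across it, in place.

    The band is perpendicular to the leaflet axis, placed ~35% along the
    leaflet, and confined to the leaflet's neighbourhood so other leaflets
    are untouched.  It widens, and falls back to other leaflets, until the
    mask has at least two 8-connected components; with the default
    geometry the first attempt almost always suffices.
    """
    order = rng.permutation(len(leaflets))
    original = mask.copy()
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for idx in order:
        _, petiole, length, direction = leaflets[idx]
        along = (yy - center[0]) * direction[0] + (xx - center[1]) * direction[1]
        perp = -(yy - center[0]) * direction[1] + (xx - center[1]) * direction[0]
        cut_s = petiole + 0.35 * length
        for thickness in (2.0, 3.0, 5.0):
            mask[:] = original
            band = (np.abs(along - cut_s) <= thickness) & (np.abs(perp) <= length)
            mask[band] = False
            if mask.any() and measure.label(mask, connectivity=2).max() >= 2:
                return
    mask[:] = original  # could not fragment without destroying the object


def generate_samples(
    spec_a: ShapeClassSpec,
    spec_b: ShapeClassSpec,
    n_per_class: int,
    seed: int,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> list[SyntheticSample]:
    """Generate ``2 * n_per_class`` silhouettes, deterministic in ``seed``.

    Each sample draws from its own random stream derived from
    ``(seed, class_index, sample_index)`` so samples are individually
    reproducible and order-independent.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be positive")
    for spec in (spec_a, spec_b):
        max_extent = spec.petiole_length_px_range[1] + spec.leaflet_length_px_range[1]
        if max_extent + 10 > min(image_size) / 2:
            raise SizeError(
                f"class '{spec.class_label}' leaflets (extent {max_extent} px) "
                f"do not fit in {image_size}"
            )
    samples: list[SyntheticSample] = []
    for class_idx, spec in enumerate((spec_a, spec_b)):
        for i in range(n_per_class):
            rng = np.random.default_rng([seed, class_idx, i])
            mask = _draw_plant(rng, spec, image_size)
            if not mask.any():
                raise ParameterError("degenerate spec produced an empty mask")
            samples.append(
                SyntheticSample(
                    mask=mask,
                    class_label=spec.class_label,
                    sample_id=f"{spec.class_label}_{i:04d}",
                    seed=seed,
                    params_used=spec,
                )
            )
    return samples


def write_samples(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write 8-bit PNG masks (0/255) plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class_label", "seed"])
        for s in samples:
            fname = f"{s.sample_id}.png"
            iio.imwrite(out / fname, (s.mask.astype(np.uint8) * 255))
            writer.writerow([fname, s.class_label, s.seed])
    return manifest


def save_specs(spec_a: ShapeClassSpec, spec_b: ShapeClassSpec, path: str | Path) -> None:
    """Persist both class specs as a flat YAML config."""
    payload = {
        "class_a": _spec_dict(spec_a),
        "class_b": _spec_dict(spec_b),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_specs(path: str | Path) -> tuple[ShapeClassSpec, ShapeClassSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _spec_from_dict(payload["class_a"]), _spec_from_dict(payload["class_b"])


def _spec_dict(spec: ShapeClassSpec) -> dict:
    return {
        "class_label": spec.class_label,
        "leaflet_aspect_mean": spec.leaflet_aspect_mean,
        "leaflet_aspect_sd": spec.leaflet_aspect_sd,
        "n_leaflets_range": list(spec.n_leaflets_range),
        "leaflet_length_px_range": list(spec.leaflet_length_px_range),
        "petiole_length_px_range": list(spec.petiole_length_px_range),
        "fragment_prob": spec.fragment_prob,
    }


def _spec_from_dict(d: dict) -> ShapeClassSpec:
    return ShapeClassSpec(
        class_label=d["class_label"],
        leaflet_aspect_mean=float(d["leaflet_aspect_mean"]),
        leaflet_aspect_sd=float(d["leaflet_aspect_sd"]),
        n_leaflets_range=tuple(d.get("n_leaflets_range", (2, 3))),
        leaflet_length_px_range=tuple(d.get("leaflet_length_px_range", (40, 80))),
        petiole_length_px_range=tuple(d.get("petiole_length_px_range", (2, 8))),
        fragment_prob=float(d.get("fragment_prob", 0.0)),
    )


def fragmented(spec: ShapeClassSpec) -> ShapeClassSpec:
    """Copy of ``spec`` with fragmentation always on."""
    return replace(spec, fragment_prob=1.0)
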
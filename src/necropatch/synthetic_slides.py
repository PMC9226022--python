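"""Seeded generator of synthetic histology slides with planted necrotic regions.

Emulates the geometry a necrosis-detection pipeline sees at one working
magnification: textured tissue on a bright background (so Otsu separates
them), contiguous necrotic regions whose texture differs from viable tissue
(paler, less saturated, higher intensity variance), and two simulated
annotators whose contours agree on the core of each region but disagree in a
controllable boundary band.

Every region is authored as a star-convex polygon (centre plus a smooth
radius-vs-angle profile), so the planted truth, the annotator contours and
the rasterised masks all share one polygon representation: with a zero
disagreement band both annotators reproduce the truth mask exactly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .raster import rasterise_polygons

__all__ = [
    "TextureParams",
    "SlideSpec",
    "SlideBundle",
    "generate_slide",
    "write_asap_xml",
]

_N_VERTICES = 48  # vertices per region contour


@dataclass(frozen=True)
class TextureParams:
    """Colour and noise parameters for the three synthetic texture classes.

    ``contrast`` in [0, 1] scales how far the necrotic texture sits from the
    viable-tissue texture (0 = indistinguishable, 1 = the full separation
    below); class separability of the generated tiles is monotone in it.
    ``confuser_fraction`` plants additional necrosis-look-alike blobs in
    viable tissue (not in the truth mask, not annotated) to exercise
    hard-negative mining.
    """

    viable_rgb: tuple[float, float, float] = (0.78, 0.45, 0.66)  # eosin pink/purple
    necrosis_rgb: tuple[float, float, float] = (0.74, 0.68, 0.64)  # pale, desaturated
    background_rgb: tuple[float, float, float] = (0.96, 0.96, 0.96)
    viable_noise: float = 0.06
    necrosis_noise: float = 0.14  # necrosis is the high-variance class
    background_noise: float = 0.01
    noise_scale: float = 2.0  # gaussian correlation length, px
    blob_smoothness: float = 0.25  # low-freq radius jitter of region contours
    contrast: float = 1.0
    confuser_fraction: float = 0.0
    confuser_contrast: float = 0.75


@dataclass(frozen=True)
class SlideSpec:
    """Parameters for one synthetic slide at the working magnification."""

    slide_id: str
    width: int = 1024
    height: int = 1024
    n_necrosis_regions: int = 2
    region_area_range: tuple[float, float] = (20_000.0, 60_000.0)
    annotator_disagreement_band: float = 0.0
    texture_params: TextureParams = field(default_factory=TextureParams)
    background_fraction: float = 0.3
    tile_size: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.width < 2 * self.tile_size or self.height < 2 * self.tile_size:
            raise ValueError(
                f"slide {self.width}x{self.height} smaller than twice the "
                f"tile size {self.tile_size}"
            )
        if self.n_necrosis_regions < 0:
            raise ValueError("n_necrosis_regions must be >= 0")
        if self.annotator_disagreement_band < 0:
            raise ValueError("disagreement band must be >= 0")
        lo, hi = self.region_area_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad region_area_range {self.region_area_range}")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")


@dataclass
class SlideBundle:
    """A generated slide: image, planted truth and two simulated annotators."""

    spec: SlideSpec
    image: np.ndarray  # (H, W, 3) uint8
    annotator_contours: tuple[list[np.ndarray], list[np.ndarray]]
    truth_necrosis_mask: np.ndarray  # (H, W) bool
    tissue_truth_mask: np.ndarray  # (H, W) bool — generator's own tissue map
    confuser_mask: np.ndarray  # (H, W) bool — planted look-alike blobs


def _correlated_noise(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Zero-mean unit-std gaussian field with correlation length ``scale``.

    Long-wavelength fields are synthesised on a coarse grid and upsampled,
    which is equivalent up to interpolation and far cheaper than filtering
    at full resolution.
    """
    if scale <= 4:
        z = rng.standard_normal(shape)
        if scale > 0:
            z = ndimage.gaussian_filter(z, sigma=scale)
    else:
        f = int(scale // 4)
        coarse = (int(np.ceil(shape[0] / f)) + 1, int(np.ceil(shape[1] / f)) + 1)
        z = ndimage.gaussian_filter(rng.standard_normal(coarse), sigma=scale / f)
        z = ndimage.zoom(z, f, order=1)[: shape[0], : shape[1]]
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z - z.mean()


def _tissue_blob(rng: np.random.Generator, h: int, w: int, frac: float) -> np.ndarray:
    """Large smooth blob covering ``frac`` of the slide."""
    field_ = _correlated_noise(rng, (h, w), scale=min(h, w) / 8.0)
    # bias toward the centre so the blob is contiguous rather than banded
    yy = ((np.arange(h) - h / 2) / (h / 2)) ** 2
    xx = ((np.arange(w) - w / 2) / (w / 2)) ** 2
    r2 = yy[:, None] + xx[None, :]
    field_ = field_ - 1.5 * r2
    thr = np.quantile(field_, 1.0 - frac)
    return field_ >= thr


def _region_polygon(
    rng: np.random.Generator, cx: float, cy: float, area: float, smoothness: float
) -> np.ndarray:
    """Star-convex polygon of roughly the requested area, centred at (cx, cy)."""
    theta = np.linspace(0.0, 2 * np.pi, _N_VERTICES, endpoint=False)
    base_r = np.sqrt(area / np.pi)
    # smooth periodic radius profile from a few low-order harmonics
    r = np.ones(_N_VERTICES)
    for k in (2, 3, 5):
        amp = smoothness * rng.uniform(0.2, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.3, None)
    # renormalise so the polygon area matches the request
    r *= base_r / np.sqrt(np.mean(r**2))
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return np.column_stack([xs, ys])


def _perturb_polygon(
    rng: np.random.Generator, poly: np.ndarray, band: float
) -> np.ndarray:
    """One annotator's version of a truth contour.

    Radial offset (systematic over/under-call) plus low-frequency boundary
    jitter, both bounded so every vertex stays within ``band`` pixels of the
    truth contour.
    """
    if band <= 0:
        return poly.copy()
    n = len(poly)
    centre = poly.mean(axis=0)
    rel = poly - centre
    radii = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    offset = rng.uniform(-0.5, 0.5) * band
    jitter = np.zeros(n)
    for k in (1, 2, 4):
        jitter += rng.uniform(-1, 1) / k * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    jitter *= 0.5 * band / max(np.abs(jitter).max(), 1e-9)
    new_r = np.clip(radii + offset + jitter, 1.0, None)
    return np.column_stack(
        [centre[0] + new_r * np.cos(theta), centre[1] + new_r * np.sin(theta)]
    )


def _place_regions(
    rng: np.random.Generator, spec: SlideSpec, tissue: np.ndarray
) -> list[np.ndarray]:
    """Sample non-overlapping region polygons that fit inside the tissue blob."""
    dt = ndimage.distance_transform_edt(tissue)
    polys: list[np.ndarray] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, r)
    for _ in range(spec.n_necrosis_regions):
        area = rng.uniform(*spec.region_area_range)
        r = np.sqrt(area / np.pi)
        ok = dt >= 1.05 * r
        yy = np.arange(spec.height)[:, None]
        xx = np.arange(spec.width)[None, :]
        for other in placed:
            ok &= (xx - other[0]) ** 2 + (yy - other[1]) ** 2 >= (1.1 * (r + other[2])) ** 2
        coords = np.argwhere(ok)
        if len(coords) == 0:
            # no room at this size: fall back to the deepest remaining point
            cy, cx = np.unravel_index(np.argmax(dt), dt.shape)
            r = max(min(r, 0.9 * dt[cy, cx]), 4.0)
            area = np.pi * r**2
        else:
            cy, cx = coords[rng.integers(len(coords))]
        polys.append(
            _region_polygon(
                rng, float(cx), float(cy), area, spec.texture_params.blob_smoothness
            )
        )
        placed.append((float(cx), float(cy), r))
    return polys


def _paint(
    img: np.ndarray,
    mask: np.ndarray,
    rgb: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
    scale: float,
) -> None:
    h, w = mask.shape
    for c in range(3):
        layer = rgb[c] + noise_sd * _correlated_noise(rng, (h, w), scale)
        img[..., c] = np.where(mask, layer, img[..., c])


def generate_slide(spec: SlideSpec) -> SlideBundle:
    """Generate one synthetic slide; byte-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    tp = spec.texture_params

    tissue = _tissue_blob(rng, h, w, 1.0 - spec.background_fraction)

    truth_polys = _place_regions(rng, spec, tissue) if spec.n_necrosis_regions else []
    truth = rasterise_polygons(truth_polys, (h, w)) & tissue

    # two annotators perturb the same truth contours independently
    annot_a = [_perturb_polygon(rng, p, spec.annotator_disagreement_band) for p in truth_polys]
    annot_b = [_perturb_polygon(rng, p, spec.annotator_disagreement_band) for p in truth_polys]

    # confuser blobs: necrosis-look-alike texture inside viable tissue only
    confuser = np.zeros((h, w), dtype=bool)
    if tp.confuser_fraction > 0:
        field_ = _correlated_noise(rng, (h, w), scale=min(h, w) / 24.0)
        viable = tissue & ~truth
        if viable.any():
            thr = np.quantile(field_[viable], 1.0 - tp.confuser_fraction)
            confuser = viable & (field_ >= thr)

    # paint textures: background everywhere, then viable tissue, then lesions
    img = np.empty((h, w, 3), dtype=float)
    _paint(img, np.ones((h, w), bool), tp.background_rgb, tp.background_noise, rng, tp.noise_scale)
    _paint(img, tissue, tp.viable_rgb, tp.viable_noise, rng, tp.noise_scale)

    c = tp.contrast
    nec_rgb = tuple(v + c * (n - v) for v, n in zip(tp.viable_rgb, tp.necrosis_rgb))
    nec_noise = tp.viable_noise + c * (tp.necrosis_noise - tp.viable_noise)
    if confuser.any():
        cc = c * tp.confuser_contrast
        conf_rgb = tuple(v + cc * (n - v) for v, n in zip(tp.viable_rgb, tp.necrosis_rgb))
        conf_noise = tp.viable_noise + cc * (tp.necrosis_noise - tp.viable_noise)
        _paint(img, confuser, conf_rgb, conf_noise, rng, tp.noise_scale)
    _paint(img, truth, nec_rgb, nec_noise, rng, tp.noise_scale)

    img8 = (np.clip(img, 0.0, 1.0) * 255 + 0.5).astype(np.uint8)
    return SlideBundle(
        spec=spec,
        image=img8,
        annotator_contours=(annot_a, annot_b),
        truth_necrosis_mask=truth,
        tissue_truth_mask=tissue,
        confuser_mask=confuser,
    )


def write_asap_xml(contours: Sequence[np.ndarray], path) -> None:
    """Write polygons as ASAP-dialect annotation XML.

    One ``Annotation`` element per polygon, each with ordered ``Coordinate``
    children carrying ``X``, ``Y`` and ``Order`` attributes. Round-trips
    losslessly through :func:`necropatch.masks.parse_asap_annotations`.
    """
    root = ET.Element("ASAP_Annotations")
    annots = ET.SubElement(root, "Annotations")
    for i, poly in enumerate(contours):
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError(f"polygon {i} must have >= 3 (x, y) vertices")
        ann = ET.SubElement(
            annots,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup="necrosis",
            Color="#F4FA58",
        )
        coords = ET.SubElement(ann, "Coordinates")
        for order, (x, y) in enumerate(poly):
            ET.SubElement(
                coords, "Coordinate", Order=str(order), X=repr(float(x)), Y=repr(float(y))
            )
    ET.SubElement(root, "AnnotationGroups")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
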
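"""Per-slide label rasters from dual-annotator contours.

Two pathologist annotation sets are reconciled into three disjoint label
masks over the Otsu tissue mask:

* ``necrosis``    — pixels inside *both* annotators' contours (the
  intersection-agreement rule) and inside tissue;
* ``negative``    — tissue pixels inside *neither* annotator's contours;
* ``disagreement``— tissue pixels inside exactly one annotator's contours,
  excluded from both classes downstream.

The three masks partition the tissue mask pixel-wise.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .raster import rasterise_polygons

__all__ = [
    "AnnotationSet",
    "LabelMasks",
    "parse_asap_annotations",
    "otsu_tissue_mask",
    "build_label_masks",
    "write_label_masks",
]


@dataclass
class AnnotationSet:
    """One annotator's closed polygons for one slide, working-level pixels."""

    slide_id: str
    annotator_id: str
    polygons: list[np.ndarray]


@dataclass
class LabelMasks:
    slide_id: str
    downsample_factor: int
    tissue: np.ndarray
    necrosis: np.ndarray
    negative: np.ndarray
    disagreement: np.ndarray

    def validate(self) -> None:
        shapes = {m.shape for m in (self.tissue, self.necrosis, self.negative, self.disagreement)}
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        if (self.necrosis & self.negative).any() or (self.necrosis & self.disagreement).any() \
                or (self.negative & self.disagreement).any():
            raise ValueError("necrosis/negative/disagreement masks overlap")
        if ((self.necrosis | self.negative | self.disagreement) != self.tissue).any():
            raise ValueError("label masks do not partition the tissue mask")


def parse_asap_annotations(path, slide_id: str = "", annotator_id: str = "") -> AnnotationSet:
    """Parse ASAP-dialect annotation XML into ordered polygon vertex lists."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ValueError(f"malformed annotation XML {path}: {e}") from e
    polygons = []
    for ann in tree.getroot().iter("Annotation"):
        name = ann.get("Name", "<unnamed>")
        verts = []
        for coord in ann.iter("Coordinate"):
            x, y, order = coord.get("X"), coord.get("Y"), coord.get("Order")
            if x is None or y is None:
                raise ValueError(
                    f"Coordinate in Annotation {name!r} missing X or Y attribute"
                )
            verts.append((int(order) if order is not None else len(verts), float(x), float(y)))
        verts.sort(key=lambda t: t[0])
        polygons.append(np.array([(x, y) for _, x, y in verts], dtype=float))
    return AnnotationSet(slide_id=slide_id, annotator_id=annotator_id, polygons=polygons)


def _block_reduce_mean(arr: np.ndarray, f: int) -> np.ndarray:
    h, w = arr.shape[:2]
    arr = arr[: h - h % f, : w - w % f]
    if arr.ndim == 2:
        return arr.reshape(h // f, f, w // f, f).mean(axis=(1, 3))
    return arr.reshape(h // f, f, w // f, f, -1).mean(axis=(1, 3))


def otsu_tissue_mask(image: np.ndarray, downsample_factor: int = 1) -> np.ndarray:
    """Foreground (tissue) mask: Otsu threshold on grayscale, dark side kept.

    Histology tissue is darker than the bright slide background, so the
    below-threshold side is foreground. A constant-intensity image has no
    Otsu split; it is returned as all-background with a warning.
    """
    gray = rgb2gray(image) if image.ndim == 3 else np.asarray(image, dtype=float)
    if downsample_factor > 1:
        gray = _block_reduce_mean(gray, downsample_factor)
    if np.ptp(gray) == 0:
        warnings.warn("constant-intensity image: returning all-background tissue mask")
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    return gray < t


def build_label_masks(
    annot_a: AnnotationSet,
    annot_b: AnnotationSet,
    tissue: np.ndarray,
    downsample_factor: int = 1,
) -> LabelMasks:
    """Combine two annotation sets and a tissue mask into the label partition."""
    if annot_a.slide_id != annot_b.slide_id:
        raise ValueError(
            f"annotation sets are for different slides: "
            f"{annot_a.slide_id!r} vs {annot_b.slide_id!r}"
        )
    shape = tissue.shape
    scale = 1.0 / downsample_factor

    def _raster(annots: AnnotationSet) -> np.ndarray:
        polys = [p * scale for p in annots.polygons] if downsample_factor != 1 else annots.polygons
        return rasterise_polygons(polys, shape)

    a, b = _raster(annot_a), _raster(annot_b)
    necrosis = a & b & tissue
    disagreement = (a ^ b) & tissue
    negative = tissue & ~(a | b)
    lm = LabelMasks(
        slide_id=annot_a.slide_id,
        downsample_factor=downsample_factor,
        tissue=tissue,
        necrosis=necrosis,
        negative=negative,
        disagreement=disagreement,
    )
    lm.validate()
    return lm


def write_label_masks(lm: LabelMasks, out_dir) -> None:
    """Write masks as 0/255 PNGs plus a JSON sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("tissue", "necrosis", "negative", "disagreement"):
        arr = getattr(lm, name).astype(np.uint8) * 255
        Image.fromarray(arr).save(out / f"{lm.slide_id}_{name}.png")
    sidecar = {
        "slide_id": lm.slide_id,
        "downsample_factor": lm.downsample_factor,
        "shape": list(lm.tissue.shape),
    }
    (out / f"{lm.slide_id}_masks.json").write_text(json.dumps(sidecar, indent=2))
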
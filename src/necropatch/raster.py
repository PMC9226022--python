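"""Shared polygon rasterisation.

One convention used everywhere: pixel-centre coordinates, 0-based, x
rightward, y downward; interiors filled with the contour itself counted as
inside; the union is taken over polygons. Keeping a single implementation
guarantees that a truth polygon and its unperturbed annotator copy rasterise
to identical masks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

__all__ = ["rasterise_polygons"]


def rasterise_polygons(
    polygons: Sequence[np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise closed polygons into a boolean mask of ``shape`` (H, W)."""
    h, w = shape
    img = Image.new("1", (w, h), 0)
    draw = ImageDraw.Draw(img)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        if len(poly) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        draw.polygon([(float(x), float(y)) for x, y in poly], fill=1, outline=1)
    return np.asarray(img, dtype=bool)
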
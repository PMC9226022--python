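import numpy as np
import pytest

from necropatch import (
    AnnotationSet,
    SlideSpec,
    TilePatch,
    build_label_masks,
    generate_slide,
    otsu_tissue_mask,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One seeded 1024px slide with three necrotic regions and mild disagreement."""
    spec = SlideSpec(
        slide_id="fix0",
        width=1024,
        height=1024,
        n_necrosis_regions=3,
        region_area_range=(30_000.0, 60_000.0),
        annotator_disagreement_band=8.0,
        background_fraction=0.35,
        seed=42,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def small_label_masks(small_bundle):
    tissue = otsu_tissue_mask(small_bundle.image)
    a, b = small_bundle.annotator_contours
    return build_label_masks(
        AnnotationSet("fix0", "A", list(a)),
        AnnotationSet("fix0", "B", list(b)),
        tissue,
    )


def texture_patches(bundle, n_per_class=100, size=64, seed=0):
    """Crop labelled square patches centred well inside each texture class."""
    rng = np.random.default_rng(seed)
    h, w = bundle.truth_necrosis_mask.shape
    out = []
    for label, mask in (
        ("necrosis", bundle.truth_necrosis_mask),
        ("negative", bundle.tissue_truth_mask & ~bundle.truth_necrosis_mask),
    ):
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, iterations=size // 2)
        ys, xs = np.where(interior)
        assert len(ys) >= n_per_class, "fixture slide too small for patch sampling"
        pick = rng.choice(len(ys), size=n_per_class, replace=False)
        for j, i in enumerate(pick):
            y = min(max(ys[i] - size // 2, 0), h - size)
            x = min(max(xs[i] - size // 2, 0), w - size)
            out.append(
                TilePatch(
                    slide_id=bundle.spec.slide_id,
                    grid_row=j if label == "necrosis" else j + n_per_class,
                    grid_col=0,
                    origin_x=x,
                    origin_y=y,
                    size=size,
                    label=label,
                    image=bundle.image[y : y + size, x : x + size].copy(),
                )
            )
    return out


@pytest.fixture(scope="session")
def separable_patches(small_bundle):
    """200 necrosis + 200 viable texture patches from the fixture slide."""
    return texture_patches(small_bundle, n_per_class=200, size=64, seed=7)
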
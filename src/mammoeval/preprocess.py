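"""Image standardisation for mammogram-like frames.

The pipeline mirrors what high-resolution mammography classifiers expect:
segment the breast from the dark background (threshold, morphological
closing, hole filling, largest connected component), crop tightly to the
breast, flip right-side views so every breast faces the same way, and
bilinearly resize to a fixed portrait working size (2944 x 1920 by default).

Annotation boxes ride along: every geometric step has a corresponding box
transform so reader annotations stay aligned with the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .concordance import AnnotationBox

__all__ = [
    "PreprocessedImage",
    "EmptyForegroundError",
    "RIGHT_VIEWS",
    "DEFAULT_TARGET_SHAPE",
    "segment_breast",
    "crop_to_breast",
    "standardize_orientation",
    "resize_bilinear",
    "shift_box",
    "flip_box",
    "scale_box",
    "preprocess_image",
    "transform_box",
]

#: Views acquired on the right breast; these get flipped horizontally.
RIGHT_VIEWS = frozenset({"RCC", "RMLO"})

#: Working resolution (rows, cols) — portrait, taller than wide.
DEFAULT_TARGET_SHAPE = (2944, 1920)


class EmptyForegroundError(ValueError):
    """Raised when an image contains no detectable breast foreground."""


@dataclass(frozen=True)
class PreprocessedImage:
    """A standardised view image plus the geometry needed to map back."""

    pixels: np.ndarray
    crop_offset: tuple[int, int]
    crop_shape: tuple[int, int]
    flipped: bool
    target_shape: tuple[int, int]
    view: str = ""


def segment_breast(
    image: np.ndarray,
    threshold_rule: str | float = "otsu",
    closing_radius: int = 5,
) -> np.ndarray:
    """Binary breast mask via thresholding + morphology + largest component.

    ``threshold_rule`` is either a fixed intensity or ``"otsu"``, in which
    case Otsu's threshold is computed on the nonzero pixels only (the
    background of a mammogram is a near-constant dark band that would
    otherwise dominate the histogram). The thresholded mask is closed with
    a disc, holes are filled, and only the largest connected component is
    kept, so small off-breast artifacts (labels, dust) are discarded.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not (img > 0).any():
        raise EmptyForegroundError("image is entirely background (all zeros)")
    if threshold_rule == "otsu":
        # Otsu over the full image separates the dark background band from
        # tissue; restricting it to bright pixels would instead split the
        # breast from any brighter artifact and segment the artifact.
        if np.ptp(img) == 0:
            thr = img.min() / 2.0  # constant foreground: keep it all
        else:
            thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold_rule)
    mask = img > thr
    if not mask.any():
        raise EmptyForegroundError(
            f"no pixels above threshold {thr:.4g}; cannot segment breast"
        )
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise EmptyForegroundError("morphology removed all foreground")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def crop_to_breast(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, tuple[int, int]]:
    """Tight bounding-box crop of the mask; returns (crop, crop_offset).

    Every true mask pixel is retained. Annotation boxes move into crop
    coordinates by subtracting ``crop_offset``.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyForegroundError("mask is empty; nothing to crop")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return image[r0:r1, c0:c1], (r0, c0)


def standardize_orientation(image: np.ndarray, view: str) -> np.ndarray:
    """Horizontally flip right-breast views (RCC, RMLO) only.

    After this step every breast sits against the left image edge. The
    operation is an involution on right views and the identity elsewhere.
    """
    if view in RIGHT_VIEWS:
        return np.asarray(image)[:, ::-1].copy()
    return np.asarray(image)


def resize_bilinear(
    image: np.ndarray, target_shape: tuple[int, int]
) -> np.ndarray:
    """Bilinear resize with corner-aligned sampling.

    Output pixel (i, j) samples the input at
    ``(i * (H-1)/(h-1), j * (W-1)/(w-1))``, so the four image corners map
    exactly onto each other. Constant images stay exactly constant, and the
    output range never exceeds the input range (no overshoot). A target
    axis of length 1 samples the centre of that input axis.
    """
    img = np.asarray(image, float)
    tr, tc = int(target_shape[0]), int(target_shape[1])
    if tr < 1 or tc < 1:
        raise ValueError(f"target dims must be >= 1, got {(tr, tc)}")
    sr, sc = img.shape
    if (tr, tc) == (sr, sc):
        return img.copy()
    if tr > 1:
        rows = np.arange(tr) * (sr - 1) / (tr - 1)
    else:
        rows = np.array([(sr - 1) / 2.0])
    if tc > 1:
        cols = np.arange(tc) * (sc - 1) / (tc - 1)
    else:
        cols = np.array([(sc - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        img, [rr, cc], order=1, mode="nearest"
    )


# ---------------------------------------------------------------------------
# Box transforms that mirror the pixel operations


def shift_box(box: AnnotationBox, d_row: float, d_col: float) -> AnnotationBox:
    return replace(
        box,
        row_min=box.row_min + d_row,
        row_max=box.row_max + d_row,
        col_min=box.col_min + d_col,
        col_max=box.col_max + d_col,
    )


def flip_box(box: AnnotationBox, width: float) -> AnnotationBox:
    """Reflect a half-open box horizontally on an image of given width.

    Column endpoints map via c -> width - c and swap roles, so
    [c0, c1) becomes [width - c1, width - c0).
    """
    return replace(box, col_min=width - box.col_max, col_max=width - box.col_min)


def scale_box(
    box: AnnotationBox,
    src_shape: tuple[int, int],
    dst_shape: tuple[int, int],
) -> AnnotationBox:
    """Rescale a box by the per-axis size ratio dst/src.

    A plain ratio map keeps containment relations (a point inside the box
    stays inside) and is what annotation overlays use after resizing.
    """
    fr = dst_shape[0] / src_shape[0]
    fc = dst_shape[1] / src_shape[1]
    return replace(
        box,
        row_min=box.row_min * fr,
        row_max=box.row_max * fr,
        col_min=box.col_min * fc,
        col_max=box.col_max * fc,
    )


def preprocess_image(
    image: np.ndarray,
    view: str,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
    threshold_rule: str | float = "otsu",
    closing_radius: int = 5,
) -> PreprocessedImage:
    """Full standardisation: segment -> crop -> flip -> resize."""
    mask = segment_breast(image, threshold_rule, closing_radius)
    crop, offset = crop_to_breast(image, mask)
    crop_shape = crop.shape
    flipped = view in RIGHT_VIEWS
    oriented = standardize_orientation(crop, view)
    pixels = resize_bilinear(oriented, target_shape)
    return PreprocessedImage(
        pixels=pixels,
        crop_offset=offset,
        crop_shape=(int(crop_shape[0]), int(crop_shape[1])),
        flipped=flipped,
        target_shape=(int(target_shape[0]), int(target_shape[1])),
        view=view,
    )


def transform_box(box: AnnotationBox, pre: PreprocessedImage) -> AnnotationBox:
    """Map an original-coordinates box through a preprocessing result."""
    out = shift_box(box, -pre.crop_offset[0], -pre.crop_offset[1])
    if pre.flipped:
        out = flip_box(out, pre.crop_shape[1])
    return scale_box(out, pre.crop_shape, pre.target_shape)
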
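"""Saliency-agreement metrics: histogram intersection (SIM) and
regularised Kullback-Leibler divergence (KLD).

Two comparison pathways are supported, mirroring how the metrics are used
when benchmarking lesion-localising models against each other and against
radiologists' annotations:

* value histograms — pixel values of two saliency maps binned into a
  common normalised histogram (SIM's natural habitat);
* spatial distributions — maps (or rasterised annotation-box masks)
  resampled onto a common grid and normalised to unit mass (KLD's natural
  habitat).

Both metrics accept either representation. SIM(H1, H2) = sum_i min(H1_i,
H2_i) lies in [0, 1] with 1 for identical inputs. KLD is evaluated in the
regularised form sum_i D1_i * log(eps + D1_i / (eps + D2_i)) with
eps = 1e-10; it is asymmetric and, because of eps, not exactly zero even
at D1 = D2 (bounded by roughly n_cells * eps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .concordance import AnnotationBox
from .preprocess import resize_bilinear

__all__ = [
    "NormalizedHistogram",
    "DEFAULT_EPSILON",
    "DEFAULT_N_BINS",
    "to_histogram",
    "boxes_to_mask",
    "to_distribution",
    "sim",
    "kld",
]

DEFAULT_EPSILON = 1e-10
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class NormalizedHistogram:
    """Equal-width value histogram with masses summing to 1."""

    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "masses", np.asarray(self.masses, float))
        if (self.masses < 0).any():
            raise ValueError("histogram masses must be non-negative")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"histogram masses must sum to 1, got {self.masses.sum()!r}"
            )


def to_histogram(
    grid: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> NormalizedHistogram:
    """Normalised histogram of a grid's pixel values.

    Values are clipped into ``value_range`` before binning so that the
    masses always sum to exactly the pixel count / pixel count = 1.
    """
    g = np.asarray(grid, float).ravel()
    if g.size == 0:
        raise ValueError("cannot histogram an empty grid")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    lo, hi = value_range
    if not hi > lo:
        raise ValueError(f"degenerate value range {value_range}")
    counts, edges = np.histogram(np.clip(g, lo, hi), bins=n_bins, range=(lo, hi))
    return NormalizedHistogram(edges, counts / g.size)


def boxes_to_mask(
    boxes: Sequence[AnnotationBox], image_shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise a set of half-open boxes to a binary mask (1 inside any box)."""
    mask = np.zeros(image_shape, float)
    rows, cols = image_shape
    for b in boxes:
        r0 = max(0, int(np.floor(b.row_min)))
        c0 = max(0, int(np.floor(b.col_min)))
        r1 = min(rows, int(np.ceil(b.row_max)))
        c1 = min(cols, int(np.ceil(b.col_max)))
        if r1 > r0 and c1 > c0:
            mask[r0:r1, c0:c1] = 1.0
    return mask


Source = Union[np.ndarray, Sequence[AnnotationBox]]


def to_distribution(
    source: Source,
    common_grid_shape: tuple[int, int],
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Unit-mass spatial distribution on a common grid.

    A saliency grid is bilinearly resampled to ``common_grid_shape``
    (clipping any interpolation negatives at 0) and divided by its total.
    A sequence of annotation boxes is rasterised on ``image_shape``,
    resampled the same way, and normalised, giving uniform mass inside the
    annotated union. An all-zero source has no distribution and raises.
    """
    if isinstance(source, np.ndarray):
        grid = np.asarray(source, float)
    else:
        if image_shape is None:
            raise ValueError("image_shape is required to rasterise boxes")
        grid = boxes_to_mask(source, image_shape)
    if grid.shape != tuple(common_grid_shape):
        grid = resize_bilinear(grid, common_grid_shape)
    grid = np.clip(grid, 0.0, None)
    total = grid.sum()
    if total <= 0.0:
        raise ValueError("source has zero total mass; no distribution exists")
    return grid / total


def _as_mass_pair(
    a: NormalizedHistogram | np.ndarray, b: NormalizedHistogram | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, NormalizedHistogram) and isinstance(b, NormalizedHistogram):
        if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(
            a.bin_edges, b.bin_edges
        ):
            raise ValueError("histograms have different binning")
        return a.masses, b.masses
    if isinstance(a, NormalizedHistogram) or isinstance(b, NormalizedHistogram):
        raise ValueError("cannot mix a histogram with a raw distribution")
    ga, gb = np.asarray(a, float), np.asarray(b, float)
    if ga.shape != gb.shape:
        raise ValueError(f"grid shapes differ: {ga.shape} vs {gb.shape}")
    return ga, gb


def sim(
    h1: NormalizedHistogram | np.ndarray, h2: NormalizedHistogram | np.ndarray
) -> float:
    """Histogram intersection of two normalised mass vectors/grids.

    SIM = sum_i min(H1_i, H2_i); symmetric, 1 iff identical, 0 iff the
    supports are disjoint.
    """
    m1, m2 = _as_mass_pair(h1, h2)
    return float(np.minimum(m1, m2).sum())


def kld(
    d1: NormalizedHistogram | np.ndarray,
    d2: NormalizedHistogram | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Regularised Kullback-Leibler divergence of d1 from d2.

    KLD = sum_i D1_i * log(eps + D1_i / (eps + D2_i)), natural log.
    Asymmetric; small values mean the distributions are close. At
    D1 = D2 the value is not exactly 0 but of order n_cells * eps, and it
    tends to 0 as eps shrinks.
    """
    m1, m2 = _as_mass_pair(d1, d2)
    ratio = np.zeros_like(m1)
    np.divide(m1, epsilon + m2, out=ratio)
    terms = m1 * np.log(epsilon + ratio)
    return float(terms.sum())
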
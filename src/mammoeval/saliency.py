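"""Deterministic saliency-map operators used by weakly supervised detectors.

Globally-aware mammography classifiers in the GMIC/GLAM family turn a
coarse saliency grid into a case score and a set of regions of interest
through a handful of purely mechanical steps: top-t% pooling of the grid
(t = 6 by default), greedy selection of the K patches with the largest
average intensity (K = 3 for the compact model, 6 for the diffuse one),
re-placement of patch-level maps on the full canvas, and fusion of the
multi-scale grids (184x120, 92x60, 46x30) into a single map. Those steps
are reimplemented here as standalone, trained-weight-free operators so the
evaluation pipeline can be exercised without the networks themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import DEFAULT_TARGET_SHAPE, resize_bilinear

__all__ = [
    "SaliencyMap",
    "Patch",
    "GLAM_SCALES",
    "top_t_percent_pool",
    "default_patch_shape",
    "select_patches",
    "aggregate_patch_maps",
    "fuse_multiscale",
]

#: GLAM-style multi-scale saliency grid shapes, finest first.
GLAM_SCALES = ((184, 120), (92, 60), (46, 30))

#: Default top-t% pooling percentage.
DEFAULT_T_PERCENT = 6.0

#: Patch counts of the two model styles.
GMIC_NUM_PATCHES = 3
GLAM_NUM_PATCHES = 6

#: Reference patch / image geometry from which default patch shapes derive:
#: a 256 x 256 patch on a 2944 x 1920 image.
_REFERENCE_PATCH_AREA_FRACTION = (256 * 256) / (
    DEFAULT_TARGET_SHAPE[0] * DEFAULT_TARGET_SHAPE[1]
)


@dataclass
class SaliencyMap:
    """A model's non-negative saliency grid for one view plus its score."""

    model_id: str
    view: str
    grid: np.ndarray
    malignancy_score: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        if self.grid.ndim != 2:
            raise ValueError(f"saliency grid must be 2-D, got {self.grid.shape}")
        if (self.grid < 0).any():
            raise ValueError("saliency grid must be non-negative")
        if not (0.0 <= self.malignancy_score <= 1.0):
            raise ValueError(
                f"malignancy score must be in [0, 1], got {self.malignancy_score}"
            )

    @property
    def native_shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Patch:
    """A selected patch: top-left corner, shape, and its selection-time mean."""

    top_left: tuple[int, int]
    shape: tuple[int, int]
    mean_intensity: float


def top_t_percent_pool(grid: np.ndarray, t_percent: float = DEFAULT_T_PERCENT) -> float:
    """Mean of the largest ceil(t% * n_pixels) values of a grid.

    The pooled value always lies within [min(grid), max(grid)]; t = 100
    reduces to the global mean. The pixel count is rounded up, so the pool
    is never empty.
    """
    g = np.asarray(grid, float).ravel()
    if g.size == 0:
        raise ValueError("cannot pool an empty grid")
    if not (0.0 < t_percent <= 100.0):
        raise ValueError(f"t_percent must be in (0, 100], got {t_percent}")
    k = math.ceil(t_percent / 100.0 * g.size)
    top = np.partition(g, g.size - k)[g.size - k:]
    return float(top.mean())


def default_patch_shape(grid_shape: tuple[int, int]) -> tuple[int, int]:
    """Square patch covering the same area fraction of the grid as a
    256 x 256 patch does of a 2944 x 1920 image."""
    rows, cols = grid_shape
    side = max(1, round(math.sqrt(_REFERENCE_PATCH_AREA_FRACTION * rows * cols)))
    side = min(side, rows, cols)
    return (side, side)


def _window_means(grid: np.ndarray, patch_shape: tuple[int, int]) -> np.ndarray:
    """Mean intensity of every valid patch position.

    Direct per-window summation (not an integral image): identical windows
    then yield bit-identical means, which keeps the documented
    lexicographic tie-break exact.
    """
    windows = np.lib.stride_tricks.sliding_window_view(grid, patch_shape)
    return windows.mean(axis=(2, 3))


def select_patches(
    grid: np.ndarray,
    k: int = GMIC_NUM_PATCHES,
    patch_shape: tuple[int, int] | None = None,
) -> list[Patch]:
    """Greedy selection of the K patches with largest average intensity.

    At each step the valid position maximising the patch mean under the
    current grid is chosen; its footprint is then zeroed out (suppression
    by erasure) before the next step, so later patches avoid already
    claimed mass while overlap remains possible at footprint edges.
    Reported means are selection-time values and hence non-increasing.

    Ties break on the smallest (row, col) in lexicographic order; a
    top-left position can be selected at most once, which keeps the
    degenerate all-constant grid from returning K identical patches.
    """
    g = np.array(grid, float)
    if g.ndim != 2 or g.size == 0:
        raise ValueError(f"grid must be a nonempty 2-D array, got {g.shape}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if patch_shape is None:
        patch_shape = default_patch_shape(g.shape)
    pr, pc = int(patch_shape[0]), int(patch_shape[1])
    if pr > g.shape[0] or pc > g.shape[1] or pr < 1 or pc < 1:
        raise ValueError(
            f"patch shape {patch_shape} does not fit grid {g.shape}"
        )
    n_positions = (g.shape[0] - pr + 1) * (g.shape[1] - pc + 1)
    patches: list[Patch] = []
    taken = np.zeros((g.shape[0] - pr + 1, g.shape[1] - pc + 1), bool)
    for _ in range(min(k, n_positions)):
        means = _window_means(g, (pr, pc))
        means[taken] = -np.inf
        flat = int(np.argmax(means))  # first max in C order = lexicographic min
        r, c = divmod(flat, means.shape[1])
        patches.append(Patch((r, c), (pr, pc), float(means[r, c])))
        taken[r, c] = True
        g[r:r + pr, c:c + pc] = 0.0
    return patches


def aggregate_patch_maps(
    patches_with_maps: Sequence[tuple[tuple[int, int], np.ndarray]],
    canvas_shape: tuple[int, int],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Weighted sum of patch-level maps placed at their canvas positions.

    ``patches_with_maps`` pairs each patch's top-left corner with its 2-D
    map. Weights must be non-negative and sum to 1 (uniform by default);
    overlapping footprints add. Total canvas mass equals
    sum_i weight_i * mass(map_i) exactly.
    """
    canvas = np.zeros(canvas_shape, float)
    n = len(patches_with_maps)
    if n == 0:
        return canvas
    if weights is None:
        weights = [1.0 / n] * n
    w = np.asarray(weights, float)
    if w.shape != (n,) or (w < 0).any():
        raise ValueError("weights must be non-negative, one per patch")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    for weight, (top_left, patch_map) in zip(w, patches_with_maps):
        pm = np.asarray(patch_map, float)
        r, c = int(top_left[0]), int(top_left[1])
        if r < 0 or c < 0 or r + pm.shape[0] > canvas_shape[0] \
                or c + pm.shape[1] > canvas_shape[1]:
            raise ValueError(
                f"patch at {top_left} with shape {pm.shape} exceeds canvas "
                f"{canvas_shape}"
            )
        canvas[r:r + pm.shape[0], c:c + pm.shape[1]] += weight * pm
    return canvas


def _is_double(fine: tuple[int, int], coarse: tuple[int, int]) -> bool:
    return fine[0] == 2 * coarse[0] and fine[1] == 2 * coarse[1]


def fuse_multiscale(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Average multi-scale saliency grids on the finest grid.

    Inputs must form a strict 2x pyramid (the GLAM defaults are 184x120,
    92x60 and 46x30); any order is accepted. Coarser grids are upsampled
    with corner-aligned bilinear interpolation, so fusing identical
    constants is exact and the output never exceeds the largest input
    value.
    """
    if not maps:
        raise ValueError("need at least one map to fuse")
    arrays = sorted(
        (np.asarray(m, float) for m in maps),
        key=lambda a: a.shape[0],
        reverse=True,
    )
    finest = arrays[0].shape
    for coarse, fine in zip(arrays[1:], arrays[:-1]):
        if not _is_double(fine.shape, coarse.shape):
            raise ValueError(
                f"map shapes {[a.shape for a in arrays]} do not form a "
                f"strict 2x pyramid"
            )
    upsampled = [arrays[0]] + [
        resize_bilinear(a, finest) for a in arrays[1:]
    ]
    return np.mean(upsampled, axis=0)
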
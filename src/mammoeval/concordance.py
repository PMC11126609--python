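"""Inter-reader concordance of lesion annotations.

In double-read screening mammography two radiologists independently draw
tight axis-aligned boxes around suspicious regions. This module quantifies
their per-case agreement: overlap detection and IoU between boxes, greedy
one-to-one matching, Lin's concordance correlation coefficient (CCC) over
the corner coordinates of matched boxes, assignment of McBride's four
interpretation levels, and flagging of challenging-to-localise cases.

Boxes use a 0-based, half-open pixel convention
``[row_min, row_max) x [col_min, col_max)`` so that areas and IoU are
integer-exact on rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationBox",
    "MatchedPair",
    "ConcordanceRecord",
    "ConcordanceInputError",
    "LEVELS",
    "iou",
    "iou_matrix",
    "match_boxes",
    "lin_ccc",
    "case_concordance",
    "mcbride_level",
    "is_challenging",
    "evaluate_case",
    "concordance_table",
]

#: McBride interpretation levels, best agreement first.
LEVELS = ("almost_perfect", "substantial", "moderate", "poor")

#: CCC band edges between successive levels (almost_perfect > 0.99, ...).
DEFAULT_BAND_EDGES = (0.99, 0.95, 0.90)


class ConcordanceInputError(ValueError):
    """Invalid input to a concordance computation.

    ``code`` distinguishes failure modes programmatically:
    ``length_mismatch``, ``constant_input``, ``too_short``, ``view_mismatch``,
    ``out_of_range``, ``empty``.
    """

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class AnnotationBox:
    """One reader's rectangular annotation on one view.

    Coordinates are 0-based and half-open: the box covers pixel rows
    ``row_min .. row_max - 1`` and likewise for columns.
    """

    case_id: str
    reader: str
    view: str
    row_min: float
    col_min: float
    row_max: float
    col_max: float

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ConcordanceInputError(
                f"box must have positive area, got rows [{self.row_min}, "
                f"{self.row_max}) cols [{self.col_min}, {self.col_max})",
                code="empty",
            )

    @property
    def area(self) -> float:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    def corners(self) -> tuple[float, ...]:
        """The four corners, row-major: each corner contributes (row, col).

        Order: (row_min, col_min), (row_min, col_max),
        (row_max, col_min), (row_max, col_max).
        """
        return (
            self.row_min, self.col_min,
            self.row_min, self.col_max,
            self.row_max, self.col_min,
            self.row_max, self.col_max,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.row_min, self.col_min, self.row_max, self.col_max], float
        )


@dataclass(frozen=True)
class MatchedPair:
    box_a: AnnotationBox
    box_b: AnnotationBox
    iou: float


@dataclass
class ConcordanceRecord:
    """Per-case agreement summary between two readers."""

    case_id: str
    matched_pairs: list[MatchedPair]
    unmatched: list[AnnotationBox]
    ccc: float  # NaN when no pair overlaps
    level: str
    challenging: bool

    @property
    def mean_iou(self) -> float:
        if not self.matched_pairs:
            return float("nan")
        return float(np.mean([p.iou for p in self.matched_pairs]))


def _intersection_area(a: AnnotationBox, b: AnnotationBox) -> float:
    dr = min(a.row_max, b.row_max) - max(a.row_min, b.row_min)
    dc = min(a.col_max, b.col_max) - max(a.col_min, b.col_min)
    return max(0.0, dr) * max(0.0, dc)


def iou(box_a: AnnotationBox, box_b: AnnotationBox) -> float:
    """Intersection over union of two boxes on the same view.

    Symmetric, in [0, 1]; 1 iff the boxes coincide, 0 iff they are disjoint.
    Raises if the boxes are on different views (IoU across projections is
    meaningless).
    """
    if box_a.view != box_b.view:
        raise ConcordanceInputError(
            f"cannot compare boxes across views ({box_a.view} vs {box_b.view})",
            code="view_mismatch",
        )
    inter = _intersection_area(box_a, box_b)
    union = box_a.area + box_b.area - inter
    return inter / union


def iou_matrix(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two box sets given as (n, 4) arrays.

    Rows are ``(row_min, col_min, row_max, col_max)``. This vectorised path
    is what :func:`match_boxes` uses; the scalar :func:`iou` is its
    element-wise equivalent.
    """
    a = np.atleast_2d(np.asarray(coords_a, float))
    b = np.atleast_2d(np.asarray(coords_b, float))
    dr = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0]))
    dc = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = np.clip(dr, 0.0, None) * np.clip(dc, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union


def match_boxes(
    boxes_a: Sequence[AnnotationBox], boxes_b: Sequence[AnnotationBox]
) -> tuple[list[MatchedPair], list[AnnotationBox]]:
    """Greedy one-to-one matching of two readers' boxes by descending IoU.

    Only pairs on the same view with overlap area strictly greater than zero
    are eligible (the study's definition of overlapping annotations). Each
    box joins at most one pair; leftovers are returned unmatched. Ties in
    IoU break deterministically on the input order of the A then B box.
    """
    pairs: list[MatchedPair] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    candidates = []
    for i, ba in enumerate(boxes_a):
        for j, bb in enumerate(boxes_b):
            if ba.view != bb.view:
                continue
            if _intersection_area(ba, bb) > 0.0:
                candidates.append((-iou(ba, bb), i, j))
    candidates.sort()
    for neg_iou, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(MatchedPair(boxes_a[i], boxes_b[j], -neg_iou))
    unmatched = [b for i, b in enumerate(boxes_a) if i not in used_a]
    unmatched += [b for j, b in enumerate(boxes_b) if j not in used_b]
    return pairs, unmatched


def lin_ccc(x_values: Iterable[float], y_values: Iterable[float]) -> float:
    """Lin's concordance correlation coefficient of two paired sequences.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (divide-by-n) moments. Equals 1 iff y is identical to x; penalises both
    loss of correlation and location/scale shift, so |CCC| <= |Pearson r|.
    """
    x = np.asarray(list(x_values) if not isinstance(x_values, np.ndarray)
                   else x_values, float)
    y = np.asarray(list(y_values) if not isinstance(y_values, np.ndarray)
                   else y_values, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConcordanceInputError(
            f"paired sequences must be 1-D and equal length, got shapes "
            f"{x.shape} and {y.shape}",
            code="length_mismatch",
        )
    if x.size < 2:
        raise ConcordanceInputError(
            "need at least two paired values", code="too_short"
        )
    if np.array_equal(x, y):
        return 1.0
    xm, ym = x.mean(), y.mean()
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0.0 and sy2 == 0.0:
        raise ConcordanceInputError(
            "both sequences are constant; CCC undefined", code="constant_input"
        )
    sxy = ((x - xm) * (y - ym)).mean()
    return float(2.0 * sxy / (sx2 + sy2 + (xm - ym) ** 2))


def case_concordance(matched_pairs: Sequence[MatchedPair]) -> float:
    """Case-level CCC over the four corner points of all matched pairs.

    For each matched pair the 8 corner coordinates of reader A's box form
    the x sequence and the corresponding coordinates of reader B's box the
    y sequence; pairs from all views of the case are pooled into one CCC.
    """
    if not matched_pairs:
        raise ConcordanceInputError(
            "case concordance needs at least one matched pair", code="empty"
        )
    x: list[float] = []
    y: list[float] = []
    for pair in matched_pairs:
        x.extend(pair.box_a.corners())
        y.extend(pair.box_b.corners())
    return lin_ccc(x, y)


def mcbride_level(
    ccc: float, band_edges: tuple[float, float, float] = DEFAULT_BAND_EDGES
) -> str:
    """McBride interpretation level for a CCC value.

    almost_perfect: ccc > 0.99; substantial: 0.95 < ccc <= 0.99;
    moderate: 0.90 < ccc <= 0.95; poor: ccc <= 0.90. The quoted bands fix
    only the outer bounds ("greater than 0.99", "less than 0.9"); boundary
    values are assigned to the lower category, and the edges are exposed
    for alternative conventions.
    """
    if not (-1.0 - 1e-12 <= ccc <= 1.0 + 1e-12):
        raise ConcordanceInputError(
            f"CCC must lie in [-1, 1], got {ccc}", code="out_of_range"
        )
    hi, mid, lo = band_edges
    if ccc > hi:
        return "almost_perfect"
    if ccc > mid:
        return "substantial"
    if ccc > lo:
        return "moderate"
    return "poor"


def is_challenging(
    matched_pairs: Sequence[MatchedPair], iou_threshold: float = 0.95
) -> bool:
    """Whether a case is challenging to localise.

    Readers "significantly overlap" when some matched pair attains
    IoU > 0.95; a case is challenging iff that never happens — including
    total disagreement (no overlapping pair at all).
    """
    return not any(p.iou > iou_threshold for p in matched_pairs)


def evaluate_case(
    boxes: Sequence[AnnotationBox],
    band_edges: tuple[float, float, float] = DEFAULT_BAND_EDGES,
) -> ConcordanceRecord:
    """Full concordance record for one case's annotations from two readers.

    Cases where no pair of boxes overlaps (total reader disagreement) get
    ccc = NaN, level ``poor`` and ``challenging = True`` — the worst
    possible agreement.
    """
    if not boxes:
        raise ConcordanceInputError("no annotations supplied", code="empty")
    case_ids = {b.case_id for b in boxes}
    if len(case_ids) != 1:
        raise ConcordanceInputError(
            f"boxes span multiple cases: {sorted(case_ids)}", code="empty"
        )
    case_id = boxes[0].case_id
    readers = sorted({b.reader for b in boxes})
    boxes_a = [b for b in boxes if b.reader == readers[0]]
    boxes_b = [b for b in boxes if len(readers) > 1 and b.reader == readers[1]]
    pairs, unmatched = match_boxes(boxes_a, boxes_b)
    if pairs:
        ccc = case_concordance(pairs)
        level = mcbride_level(ccc, band_edges)
    else:
        ccc = float("nan")
        level = "poor"
    return ConcordanceRecord(
        case_id=case_id,
        matched_pairs=pairs,
        unmatched=unmatched,
        ccc=ccc,
        level=level,
        challenging=is_challenging(pairs),
    )


def concordance_table(boxes: Sequence[AnnotationBox]) -> pd.DataFrame:
    """Concordance records for every case present in ``boxes`` as a table.

    Columns: case_id, n_pairs, mean_iou, ccc, level, challenging.
    """
    by_case: dict[str, list[AnnotationBox]] = {}
    for b in boxes:
        by_case.setdefault(b.case_id, []).append(b)
    rows = []
    for case_id in sorted(by_case):
        rec = evaluate_case(by_case[case_id])
        rows.append(
            {
                "case_id": case_id,
                "n_pairs": len(rec.matched_pairs),
                "mean_iou": rec.mean_iou,
                "ccc": rec.ccc,
                "level": rec.level,
                "challenging": rec.challenging,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["case_id", "n_pairs", "mean_iou", "ccc", "level", "challenging"],
    )
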
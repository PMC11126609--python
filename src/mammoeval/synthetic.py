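"""Seeded synthetic screening cohorts.

The study this toolkit evaluates — lesion-localising AI inside a
double-read screening programme — rests on private data: screening
mammograms, paired radiologist annotations, and saliency maps from two
trained networks. This module generates a stand-in cohort with the same
observable structure so every downstream stage (preprocessing,
concordance, saliency agreement, stratified reporting) runs end to end:

* breast-shaped half-elliptical foregrounds on dark backgrounds, with
  elliptical lesions rendered as additive Gaussian bumps;
* truth boxes per lesion, and two readers' boxes derived from each truth
  box by independent Gaussian corner jitter (the concordance dial);
* per-model saliency grids — a compact "gmic_like" style and a diffuse
  "glam_like" style with more false-positive blobs — whose blob offsets
  and per-case malignancy scores are the localisation/detection dials;
* case metadata: cancer category (missed / prior_vis / prior_invis /
  normal), T1/T2/T3 size group, laterality.

Everything is reproducible bit-for-bit from ``SynthConfig.seed``. The
generator is calibratable: :func:`calibrate_band_sigmas` finds, by pilot
simulation, jitter levels whose realised case CCCs land in each McBride
band, and the ``tie_to_concordance`` mode couples detection quality and
saliency offsets to the realised reader agreement, emulating the study's
central observation that lesions hard for radiologists to pin down are
hard for the models too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .concordance import AnnotationBox, evaluate_case
from .saliency import SaliencyMap

__all__ = [
    "VIEWS",
    "CATEGORIES",
    "SIZE_GROUPS",
    "TruthLesion",
    "SynthConfig",
    "Case",
    "Cohort",
    "LesionPlacementError",
    "DegenerateBoxError",
    "size_group_of",
    "allocate_counts",
    "breast_mask",
    "generate_image",
    "jitter_box",
    "generate_saliency",
    "generate_cohort",
    "calibrate_band_sigmas",
    "quality_from_ccc",
]

VIEWS = ("LCC", "LMLO", "RCC", "RMLO")
LEFT_VIEWS = ("LCC", "LMLO")
RIGHT_VIEWS_T = ("RCC", "RMLO")
CATEGORIES = ("missed", "prior_vis", "prior_invis")
SIZE_GROUPS = ("T1", "T2", "T3")

#: Tumour size thresholds in cm (T1 <= 2 cm; 2 < T2 < 5; T3 >= 5).
T1_MAX_CM = 2.0
T3_MIN_CM = 5.0

#: Diameter ranges (cm) sampled per size group.
_SIZE_RANGES_CM = {"T1": (0.9, 2.0), "T2": (2.05, 4.95), "T3": (5.0, 6.2)}

#: Style profiles of the two emulated models. The diffuse style spreads its
#: blobs wider, produces more off-lesion blobs and scores slightly lower,
#: matching the qualitative contrast between the two networks.
MODEL_PROFILES: Mapping[str, Mapping[str, float]] = {
    "gmic_like": {"spread_mult": 1.0, "fp_rate_mult": 1.0, "quality_mult": 1.0},
    "glam_like": {"spread_mult": 1.8, "fp_rate_mult": 3.0, "quality_mult": 0.95},
}

#: Lesion-blob amplitude range: the peak saliency height drawn per lesion.
#: Deliberately narrow so the case score q * amplitude maps category/band
#: quality differences onto well-separated sensitivities.
AMP_RANGE = (0.6, 0.9)

#: False-positive blob amplitude range; the small tail above the 0.5
#: decision threshold gives cancer-free cases a realistic false-positive
#: rate (specificity well below 1 but high).
FP_AMP_RANGE = (0.05, 0.52)


class LesionPlacementError(ValueError):
    """A lesion ellipse does not fit inside the breast foreground."""


class DegenerateBoxError(ValueError):
    """Corner jitter kept producing a zero-area box after clipping."""


def size_group_of(diameter_cm: float) -> str:
    """T1 (<= 2 cm), T2 (2-5 cm) or T3 (>= 5 cm) for a lesion diameter."""
    if diameter_cm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_cm}")
    if diameter_cm <= T1_MAX_CM:
        return "T1"
    if diameter_cm < T3_MIN_CM:
        return "T2"
    return "T3"


@dataclass(frozen=True)
class TruthLesion:
    """Ground-truth elliptical lesion on one view."""

    view: str
    center: tuple[float, float]  # (row, col) pixels
    semi_axes: tuple[float, float]  # (a, b) pixels, rows/cols
    diameter_cm: float
    intensity_gain: float = 0.5

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.diameter_cm <= 0:
            raise ValueError("diameter_cm must be positive")

    @property
    def size_group(self) -> str:
        return size_group_of(self.diameter_cm)

    def truth_box(self, case_id: str, reader: str = "truth") -> AnnotationBox:
        r, c = self.center
        a, b = self.semi_axes
        return AnnotationBox(
            case_id=case_id,
            reader=reader,
            view=self.view,
            row_min=math.floor(r - a),
            col_min=math.floor(c - b),
            row_max=math.ceil(r + a),
            col_max=math.ceil(c + b),
        )


@dataclass(frozen=True)
class SynthConfig:
    """All dials of the synthetic cohort generator.

    ``n_cases`` counts cancer cases; ``n_normals`` cancer-free cases are
    appended for specificity estimation (defaults to ``n_cases``). Mixes
    are allocated exactly by largest remainder. ``jitter_sigma`` (pixels)
    governs reader concordance; ``saliency_offset_sigma`` and
    ``saliency_spread`` (image pixels) govern localisation quality;
    ``detect_quality`` maps cancer category to a detection-probability
    scale; ``quality_uplift`` emulates transfer learning by scaling every
    case score up. ``tie_to_concordance`` couples quality and offset to the
    realised per-case reader CCC via :func:`quality_from_ccc`.
    """

    n_cases: int = 100
    category_mix: tuple[float, float, float] = (0.25, 0.35, 0.40)
    size_mix: tuple[float, float, float] = (0.68, 0.24, 0.08)
    jitter_sigma: float = 2.0
    saliency_offset_sigma: float = 4.0
    saliency_spread: float = 12.0
    fp_blob_rate: float = 0.4
    detect_quality: Mapping[str, float] = field(
        default_factory=lambda: {
            "missed": 0.80,
            "prior_vis": 0.95,
            "prior_invis": 0.88,
        }
    )
    pixel_spacing_cm: float = 0.08
    seed: int = 0
    image_shape: tuple[int, int] = (368, 240)
    saliency_shape: tuple[int, int] = (184, 120)
    n_normals: int | None = None
    models: tuple[str, ...] = ("gmic_like", "glam_like")
    single_reader_rate: float = 0.05
    noise_level: float = 0.02
    quality_uplift: float = 0.0
    tie_to_concordance: bool = False
    band_jitter_sigmas: tuple[float, float, float, float] | None = None
    lesions_per_view: tuple[int, int] = (6, 6)
    render_images: bool = False
    render_saliency: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        for name, mix in (("category_mix", self.category_mix),
                          ("size_mix", self.size_mix)):
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise ValueError(f"{name} must be 3 non-negative proportions")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(mix)!r}")
        for name, sigma in (
            ("jitter_sigma", self.jitter_sigma),
            ("saliency_offset_sigma", self.saliency_offset_sigma),
            ("noise_level", self.noise_level),
        ):
            if sigma < 0:
                raise ValueError(f"{name} must be >= 0, got {sigma}")
        if self.saliency_spread <= 0:
            raise ValueError("saliency_spread must be > 0")
        if self.fp_blob_rate < 0:
            raise ValueError("fp_blob_rate must be >= 0")
        for cat, q in self.detect_quality.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"detect_quality[{cat!r}] must be in [0, 1]")
        if not (0.0 <= self.single_reader_rate <= 1.0):
            raise ValueError("single_reader_rate must be a probability")
        for model in self.models:
            if model not in MODEL_PROFILES:
                raise ValueError(f"unknown model style {model!r}")

    @property
    def effective_n_normals(self) -> int:
        return self.n_cases if self.n_normals is None else self.n_normals


@dataclass
class Case:
    """One screening examination of four views."""

    case_id: str
    images: dict[str, np.ndarray]
    laterality_of_cancer: str  # left / right / none
    category: str  # missed / prior_vis / prior_invis / normal
    size_group: str  # T1 / T2 / T3 / none
    truth_lesions: list[TruthLesion]
    reader_boxes: list[AnnotationBox]
    jitter_sigma: float = 0.0

    @property
    def is_cancer(self) -> bool:
        return self.category != "normal"


@dataclass
class Cohort:
    """Generated cases plus their per-model, per-view saliency maps."""

    cases: list[Case]
    saliency_maps: list[SaliencyMap]
    config: SynthConfig

    def saliency_for(self, case_id: str, model_id: str) -> list[SaliencyMap]:
        return [
            s for s in self.saliency_maps
            if s.case_id == case_id and s.model_id == model_id
        ]


def allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to the given proportions.

    Exact: counts sum to n; ties in the fractional part go to the lower
    index for determinism.
    """
    raw = [n * p for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Geometry


def breast_mask(view: str, shape: tuple[int, int]) -> np.ndarray:
    """Half-elliptical breast foreground touching the chest-wall edge.

    Left-breast views rest on the left image edge, right-breast views on
    the right edge; all other borders keep a clear background band.
    """
    rows, cols = shape
    ry, rx = 0.46 * rows, 0.80 * cols
    r0 = rows / 2.0
    rr = (np.arange(rows) + 0.5 - r0) / ry
    if view in LEFT_VIEWS:
        cc = (np.arange(cols) + 0.5) / rx
    elif view in RIGHT_VIEWS_T:
        cc = (cols - np.arange(cols) - 0.5) / rx
    else:
        raise ValueError(f"unknown view {view!r}")
    return (rr[:, None] ** 2 + cc[None, :] ** 2) <= 1.0


def _inside_breast(view: str, shape: tuple[int, int],
                   row: float, col: float) -> bool:
    rows, cols = shape
    ry, rx = 0.46 * rows, 0.80 * cols
    if view in LEFT_VIEWS:
        u = col / rx
    else:
        u = (cols - col) / rx
    v = (row - rows / 2.0) / ry
    return u >= 0 and v * v + u * u <= 1.0


def _lesion_fits(lesion: TruthLesion, shape: tuple[int, int]) -> bool:
    r, c = lesion.center
    a, b = lesion.semi_axes
    extremes = [(r - a, c), (r + a, c), (r, c - b), (r, c + b), (r, c)]
    return all(_inside_breast(lesion.view, shape, er, ec) for er, ec in extremes)


def generate_image(
    view: str,
    lesions: Sequence[TruthLesion],
    noise_level: float,
    seed: int | np.random.Generator,
    shape: tuple[int, int] = (368, 240),
    base_intensity: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale view: breast foreground + additive lesions.

    Returns (image, foreground_mask). The background stays exactly zero
    (a near-zero border band by construction); foreground texture is
    Gaussian noise at ``noise_level``; each lesion adds an elliptical
    Gaussian bump of height ``intensity_gain`` whose sigma is half the
    semi-axis, so most of the bump lies inside the stated ellipse.
    Deterministic for a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mask = breast_mask(view, shape)
    img = np.where(mask, base_intensity, 0.0)
    if noise_level > 0:
        img += rng.normal(0.0, noise_level, shape) * mask
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for lesion in lesions:
        if lesion.view != view:
            raise ValueError(
                f"lesion on view {lesion.view} passed to {view} image"
            )
        if not _lesion_fits(lesion, shape):
            raise LesionPlacementError(
                f"lesion at {lesion.center} with semi-axes "
                f"{lesion.semi_axes} exceeds the breast foreground"
            )
        r, c = lesion.center
        sa, sb = lesion.semi_axes[0] / 2.0, lesion.semi_axes[1] / 2.0
        bump = lesion.intensity_gain * np.exp(
            -0.5 * (((rr - r) / sa) ** 2 + ((cc - c) / sb) ** 2)
        )
        img += bump * mask
    return np.clip(img, 0.0, None), mask


def jitter_box(
    truth_box: AnnotationBox,
    jitter_sigma: float,
    seed: int | np.random.Generator,
    image_shape: tuple[int, int] = (368, 240),
    max_retries: int = 10,
) -> AnnotationBox:
    """Perturb each of the four corner coordinates with N(0, sigma^2).

    The perturbed coordinates are re-ordered (min < max per axis) and
    clipped to the image; degenerate zero-area results are re-drawn up to
    ``max_retries`` times before raising.
    """
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = truth_box.as_array()
    if jitter_sigma == 0:
        return truth_box
    rows, cols = image_shape
    for _ in range(max_retries):
        r0, c0, r1, c1 = base + rng.normal(0.0, jitter_sigma, 4)
        rlo, rhi = sorted((r0, r1))
        clo, chi = sorted((c0, c1))
        rlo, rhi = np.clip(rlo, 0, rows), np.clip(rhi, 0, rows)
        clo, chi = np.clip(clo, 0, cols), np.clip(chi, 0, cols)
        if rhi - rlo > 0 and chi - clo > 0:
            return replace(
                truth_box, row_min=float(rlo), row_max=float(rhi),
                col_min=float(clo), col_max=float(chi),
            )
    raise DegenerateBoxError(
        f"could not draw a non-degenerate jittered box after "
        f"{max_retries} tries (sigma={jitter_sigma})"
    )


# ---------------------------------------------------------------------------
# Saliency


def _add_blob(grid: np.ndarray, center: tuple[float, float],
              sigmas: tuple[float, float], amplitude: float) -> None:
    rr = np.arange(grid.shape[0])[:, None]
    cc = np.arange(grid.shape[1])[None, :]
    grid += amplitude * np.exp(
        -0.5 * (((rr - center[0]) / sigmas[0]) ** 2
                + ((cc - center[1]) / sigmas[1]) ** 2)
    )


def generate_saliency(
    truth_lesions: Sequence[TruthLesion],
    offset_sigma: float,
    spread: float,
    fp_blob_rate: float,
    seed: int | np.random.Generator,
    *,
    view: str,
    image_shape: tuple[int, int] = (368, 240),
    grid_shape: tuple[int, int] = (184, 120),
    model_id: str = "gmic_like",
    detect_quality: float = 1.0,
    quality_uplift: float = 0.0,
    case_id: str = "",
) -> SaliencyMap:
    """Model-like saliency grid for one view.

    One Gaussian blob per lesion, its centre displaced by N(0,
    offset_sigma^2) in image pixels, plus Poisson(fp_blob_rate) off-lesion
    blobs of sub-threshold amplitude. The view's malignancy score is a
    monotone function of the peak lesion-blob height times
    ``detect_quality`` (scaled up by ``quality_uplift``); views without a
    lesion score by their largest false-positive blob.
    """
    if spread <= 0:
        raise ValueError("spread must be > 0")
    if offset_sigma < 0:
        raise ValueError("offset_sigma must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    profile = MODEL_PROFILES[model_id]
    scale_r = grid_shape[0] / image_shape[0]
    scale_c = grid_shape[1] / image_shape[1]
    view_lesions = [l for l in truth_lesions if l.view == view]
    grid = np.zeros(grid_shape, float)
    peak_lesion = 0.0
    if view_lesions:
        # one conspicuity draw per view: the signs of one cancer share it
        amp = rng.uniform(*AMP_RANGE)
        peak_lesion = amp
        for lesion in view_lesions:
            dr, dc = (rng.normal(0.0, offset_sigma, 2) if offset_sigma > 0
                      else (0.0, 0.0))
            center = (
                (lesion.center[0] + dr) * scale_r,
                (lesion.center[1] + dc) * scale_c,
            )
            blob_spread = spread * profile["spread_mult"]
            spread_g = (
                max(0.8, blob_spread * scale_r),
                max(0.8, blob_spread * scale_c),
            )
            _add_blob(grid, center, spread_g, amp)
    n_fp = rng.poisson(fp_blob_rate * profile["fp_rate_mult"])
    fp_spread = max(spread, 8.0) * profile["spread_mult"]
    fp_spread_g = (
        max(0.8, fp_spread * scale_r),
        max(0.8, fp_spread * scale_c),
    )
    peak_fp = 0.0
    for _ in range(n_fp):
        amp = rng.uniform(*FP_AMP_RANGE)
        center = (
            rng.uniform(0.1, 0.9) * grid_shape[0],
            rng.uniform(0.05, 0.6) * grid_shape[1],
        )
        _add_blob(grid, center, fp_spread_g, amp)
        peak_fp = max(peak_fp, amp)
    q = detect_quality * profile["quality_mult"] * (1.0 + quality_uplift)
    score = min(1.0, max(peak_lesion * q, peak_fp))
    return SaliencyMap(
        model_id=model_id, view=view, grid=grid,
        malignancy_score=score, case_id=case_id,
    )


# ---------------------------------------------------------------------------
# Concordance-coupled quality


def quality_from_ccc(ccc: float) -> float:
    """Detection-quality multiplier as a function of realised reader CCC.

    Piecewise-linear and increasing, with knots at the McBride band edges,
    so cases that readers localise discordantly are also harder for the
    emulated models — the coupling the tied-cohort mode uses. NaN CCC
    (total disagreement) maps to the minimum.
    """
    if math.isnan(ccc):
        return 0.60
    return float(np.interp(
        ccc,
        [-1.0, 0.0, 0.90, 0.95, 0.99, 1.0],
        [0.60, 0.60, 0.70, 0.80, 0.90, 1.00],
    ))


def _sample_lesion(
    rng: np.random.Generator,
    view: str,
    anchor: tuple[float, float],
    diameter_cm: float,
    pixel_spacing_cm: float,
    shape: tuple[int, int],
    gain: float,
) -> TruthLesion:
    """One lesion near the case anchor; retries keep it inside the breast."""
    r_px = diameter_cm / 2.0 / pixel_spacing_cm
    for _ in range(50):
        u = rng.uniform(0.75, 1.0)
        a, b = r_px, r_px * u
        dr, dc = rng.uniform(-4, 4, 2)
        center = (anchor[0] + dr, anchor[1] + dc)
        lesion = TruthLesion(
            view=view, center=center, semi_axes=(a, b),
            diameter_cm=diameter_cm, intensity_gain=gain,
        )
        if _lesion_fits(lesion, shape):
            return lesion
    raise LesionPlacementError(
        f"could not place a {diameter_cm:.1f} cm lesion inside the breast "
        f"on a {shape} frame at {pixel_spacing_cm} cm/px"
    )


#: Reference corner variance (px^2) at which ``jitter_sigma`` applies
#: literally; cases with larger/smaller truth-corner spread scale their
#: reader noise proportionally (see _make_cancer_case).
_REFERENCE_CORNER_VAR = 3000.0


def _lesion_anchors(
    rng: np.random.Generator,
    view: str,
    shape: tuple[int, int],
    n_lesions: int,
    size_group: str,
    pixel_spacing_cm: float,
) -> list[tuple[float, float]]:
    """Anchors of a case's lesion signs on one view.

    Lesions fan out over deterministic row sub-anchors centred on
    ``cols / 2`` — centring there makes the row-column separation term of
    the truth boxes' corner variance identical for left- and right-breast
    cases (mirrored columns sit symmetrically about cols / 2). The fan
    half-span scales with the size group's lesion radius (shrunk until
    every extreme fits inside the breast), so small-lesion cases form
    compact clusters: their corner variance — and with it the
    variance-normalised reader jitter — stays proportionally small, which
    keeps jittered boxes of small lesions overlapping their counterparts.
    Columns sit in a narrow mid-breast band, mirrored for right views.
    """
    rows, cols = shape
    mid_row = cols / 2.0
    a_max = _SIZE_RANGES_CM[size_group][1] / 2.0 / pixel_spacing_cm
    base_col = rng.uniform(0.40, 0.45)
    margin = 6.0

    def fits(span: float) -> bool:
        for r in (mid_row - span, mid_row + span):
            for cf in (base_col - 0.02, base_col + 0.02):
                c = cf * cols
                ext = a_max + margin
                pts = [(r - ext, c), (r + ext, c), (r, c - ext), (r, c + ext)]
                if not all(
                    _inside_breast("LCC", shape, pr, pc) for pr, pc in pts
                ):
                    return False
        return True

    span = 2.0 * a_max
    while span > 4.0 and not fits(span):
        span *= 0.85
    if n_lesions > 1:
        offsets = np.linspace(-span, span, n_lesions)
    else:
        offsets = np.array([0.0])
    anchors = []
    for off in offsets:
        row = mid_row + off + rng.uniform(-4, 4)
        col_frac = np.clip(base_col + rng.uniform(-0.015, 0.015), 0.05, 0.95)
        if view in LEFT_VIEWS:
            col = col_frac * cols
        else:
            col = (1 - col_frac) * cols
        anchors.append((row, col))
    return anchors


def _make_cancer_case(
    rng: np.random.Generator,
    config: SynthConfig,
    case_id: str,
    category: str,
    size_group: str,
    jitter_sigma: float,
) -> Case:
    shape = config.image_shape
    laterality = "left" if rng.random() < 0.5 else "right"
    views = LEFT_VIEWS if laterality == "left" else RIGHT_VIEWS_T
    lo, hi = _SIZE_RANGES_CM[size_group]
    n_lesions = int(rng.integers(config.lesions_per_view[0],
                                 config.lesions_per_view[1] + 1))
    lesions: list[TruthLesion] = []
    truth_boxes: list[AnnotationBox] = []
    for view in views:
        anchors = _lesion_anchors(
            rng, view, shape, n_lesions, size_group, config.pixel_spacing_cm
        )
        for anchor in anchors:
            diameter = float(rng.uniform(lo, hi))
            lesion = _sample_lesion(
                rng, view, anchor, diameter, config.pixel_spacing_cm,
                shape, gain=0.5,
            )
            lesions.append(lesion)
            truth_boxes.append(lesion.truth_box(case_id))
    # Reader imprecision scales with the case's own corner-coordinate
    # spread: CCC is scale-free, so this makes the expected per-case CCC
    # equal to 1 / (1 + jitter_sigma^2 / V_REF) for *every* case, turning
    # jitter_sigma into a clean, size- and placement-independent
    # concordance dial.
    corner_values = np.array([b.corners() for b in truth_boxes]).ravel()
    v_case = float(corner_values.var()) if corner_values.size else 0.0
    sigma_case = jitter_sigma * math.sqrt(v_case / _REFERENCE_CORNER_VAR)
    boxes: list[AnnotationBox] = []
    for truth in truth_boxes:
        for reader in ("A", "B"):
            boxes.append(replace(
                jitter_box(truth, sigma_case, rng, shape),
                reader=reader,
            ))
    if boxes and rng.random() < config.single_reader_rate:
        # emulate a single-reader-only finding: drop one reader's box
        drop = int(rng.integers(0, len(boxes)))
        boxes = boxes[:drop] + boxes[drop + 1:]
    images: dict[str, np.ndarray] = {}
    if config.render_images:
        for view in VIEWS:
            view_lesions = [l for l in lesions if l.view == view]
            img, _ = generate_image(
                view, view_lesions, config.noise_level, rng, shape
            )
            images[view] = img
    return Case(
        case_id=case_id,
        images=images,
        laterality_of_cancer=laterality,
        category=category,
        size_group=size_group,
        truth_lesions=lesions,
        reader_boxes=boxes,
        jitter_sigma=jitter_sigma,
    )


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a full cohort of cancer and cancer-free cases.

    Category and size mixes are honoured exactly by largest-remainder
    allocation. When ``tie_to_concordance`` is set, each cancer case draws
    its jitter from one of four band-calibrated sigmas and its detection
    quality / saliency offset are modulated by the realised reader CCC.
    """
    n = config.n_cases
    cat_counts = allocate_counts(n, config.category_mix)
    size_counts = allocate_counts(n, config.size_mix)
    categories = [c for c, k in zip(CATEGORIES, cat_counts) for _ in range(k)]
    sizes = [s for s, k in zip(SIZE_GROUPS, size_counts) for _ in range(k)]
    master = np.random.default_rng(config.seed)
    sizes = [sizes[i] for i in master.permutation(n)]

    band_sigmas: tuple[float, ...] | None = None
    if config.tie_to_concordance:
        band_sigmas = config.band_jitter_sigmas or calibrate_band_sigmas(config)

    n_total = n + config.effective_n_normals
    seeds = np.random.SeedSequence(config.seed).spawn(n_total)
    cases: list[Case] = []
    maps: list[SaliencyMap] = []
    for i in range(n_total):
        rng = np.random.default_rng(seeds[i])
        case_id = f"case_{i:04d}"
        if i < n:
            if band_sigmas is not None:
                sigma = float(band_sigmas[int(rng.integers(0, len(band_sigmas)))])
            else:
                sigma = config.jitter_sigma
            case = _make_cancer_case(
                rng, config, case_id, categories[i], sizes[i], sigma
            )
        else:
            images = {}
            if config.render_images:
                for view in VIEWS:
                    img, _ = generate_image(
                        view, [], config.noise_level, rng, config.image_shape
                    )
                    images[view] = img
            case = Case(
                case_id=case_id, images=images, laterality_of_cancer="none",
                category="normal", size_group="none", truth_lesions=[],
                reader_boxes=[],
            )
        cases.append(case)
        if not config.render_saliency:
            continue
        # saliency offset and spread scale with the case's lesion size, so
        # the localisation dials act on the scale the lesions live on
        if case.truth_lesions:
            r_mean = float(np.mean([
                (l.semi_axes[0] + l.semi_axes[1]) / 2.0
                for l in case.truth_lesions
            ]))
            size_scale = r_mean / 20.0
        else:
            size_scale = 1.0
        q_mult = 1.0
        offset = config.saliency_offset_sigma * size_scale
        if config.tie_to_concordance and case.is_cancer and case.reader_boxes:
            rec = evaluate_case(case.reader_boxes)
            f = quality_from_ccc(rec.ccc)
            q_mult = f
            # blob displacement grows from ~0.1 to ~0.9 mean lesion radii
            # as realised reader agreement falls from perfect to poor
            r_mean = size_scale * 20.0
            offset = (config.saliency_offset_sigma / 6.0) * r_mean * (
                0.1 + 1.8 * (1.0 - f)
            )
        base_q = config.detect_quality.get(case.category, 0.0)
        for model_id in config.models:
            for view in VIEWS:
                maps.append(generate_saliency(
                    case.truth_lesions,
                    offset,
                    config.saliency_spread * size_scale,
                    config.fp_blob_rate,
                    rng,
                    view=view,
                    image_shape=config.image_shape,
                    grid_shape=config.saliency_shape,
                    model_id=model_id,
                    detect_quality=base_q * q_mult,
                    quality_uplift=config.quality_uplift,
                    case_id=case_id,
                ))
    return Cohort(cases=cases, saliency_maps=maps, config=config)


def _pilot_mean_ccc(
    config: SynthConfig, sigma: float, n_pilot: int, seed: int
) -> float:
    """Mean case CCC at one jitter level (boxes only, no saliency)."""
    pilot = replace(
        config, n_cases=n_pilot, n_normals=0, jitter_sigma=sigma,
        tie_to_concordance=False, render_images=False, render_saliency=False,
        single_reader_rate=0.0, seed=seed,
    )
    cohort = generate_cohort(pilot)
    cccs = [
        evaluate_case(case.reader_boxes).ccc
        for case in cohort.cases
        if case.reader_boxes
    ]
    return float(np.nanmean(cccs))


#: Mean-CCC targets per McBride band used by calibration. The two narrow
#: interior bands aim at their centres; the open-ended outer bands aim
#: comfortably inside their edge.
_BAND_CCC_TARGETS = {
    "almost_perfect": 0.997,
    "substantial": 0.970,
    "moderate": 0.9275,
    "poor": 0.80,
}


def calibrate_band_sigmas(
    config: SynthConfig,
    n_pilot: int = 60,
    sigma_grid: Sequence[float] | None = None,
) -> tuple[float, float, float, float]:
    """Pilot-calibrated jitter sigmas for the four McBride bands.

    Simulates small box-only cohorts over a sigma grid, interpolates the
    (monotone decreasing) mean-CCC-versus-sigma curve, and returns, per
    band (almost_perfect, substantial, moderate, poor order), the sigma
    at which the mean case CCC crosses that band's target value. The mean
    is a far less noisy pilot statistic than an in-band fraction, so small
    pilots calibrate reliably. Deterministic given ``config.seed``.
    """
    if sigma_grid is None:
        sigma_grid = [
            0.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 19.0, 23.0,
            28.0, 34.0, 42.0,
        ]
    means = np.array([
        _pilot_mean_ccc(config, sigma, n_pilot, seed=config.seed + 104729)
        for sigma in sigma_grid
    ])
    # enforce monotone decrease so interpolation is well posed
    means = np.minimum.accumulate(means)
    out = []
    for band in ("almost_perfect", "substantial", "moderate", "poor"):
        target = _BAND_CCC_TARGETS[band]
        sigma = float(np.interp(-target, -means, sigma_grid))
        out.append(sigma)
    return tuple(out)  # type: ignore[return-value]
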
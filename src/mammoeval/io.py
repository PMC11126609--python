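"""File formats, run configuration and the end-to-end pipeline.

Interchange formats are chosen for desk-scale inspectability: annotations
as CSV (case_id, reader, view, row_min, col_min, row_max, col_max),
images as PNG, saliency maps as compressed ``.npz`` archives, the cohort
manifest and report summary as JSON, and run configuration as YAML. A run
directory always contains the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .concordance import AnnotationBox, concordance_table
from .evaluate import (
    agreement_by_level,
    compare_groups,
    evaluate_cohort,
    format_stratified,
    sensitivity_specificity,
    stratify,
)
from .saliency import SaliencyMap
from .synthetic import CATEGORIES, Cohort, SynthConfig, generate_cohort

log = logging.getLogger("mammoeval")

ANNOTATION_COLUMNS = [
    "case_id", "reader", "view", "row_min", "col_min", "row_max", "col_max",
]

__all__ = [
    "ANNOTATION_COLUMNS",
    "AnnotationFormatError",
    "read_annotations",
    "write_annotations",
    "write_image_png",
    "read_image_png",
    "write_saliency_archive",
    "read_saliency_archive",
    "load_config",
    "save_config",
    "write_cohort",
    "read_cohort",
    "run_pipeline",
]


class AnnotationFormatError(ValueError):
    """Malformed annotation rows; carries per-row diagnostics."""

    def __init__(self, problems: list[str]):
        super().__init__(
            "invalid annotation file:\n  " + "\n  ".join(problems)
        )
        self.problems = problems


def write_annotations(boxes: Sequence[AnnotationBox], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "case_id": b.case_id, "reader": b.reader, "view": b.view,
                "row_min": b.row_min, "col_min": b.col_min,
                "row_max": b.row_max, "col_max": b.col_max,
            }
            for b in boxes
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationBox]:
    """Read and validate an annotations CSV.

    Any malformed row (missing column, non-numeric coordinate, min >= max)
    is rejected with a diagnostic naming the 1-based data row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError([f"missing columns: {missing}"])
    problems: list[str] = []
    boxes: list[AnnotationBox] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            coords = [
                float(getattr(row, c))
                for c in ("row_min", "col_min", "row_max", "col_max")
            ]
        except (TypeError, ValueError):
            problems.append(f"row {i}: non-numeric coordinates")
            continue
        if not np.all(np.isfinite(coords)):
            problems.append(f"row {i}: non-finite coordinates")
            continue
        if not (coords[0] < coords[2] and coords[1] < coords[3]):
            problems.append(
                f"row {i}: box has non-positive extent "
                f"(row [{coords[0]}, {coords[2]}), col [{coords[1]}, {coords[3]}))"
            )
            continue
        boxes.append(AnnotationBox(
            case_id=str(row.case_id), reader=str(row.reader),
            view=str(row.view), row_min=coords[0], col_min=coords[1],
            row_max=coords[2], col_max=coords[3],
        ))
    if problems:
        raise AnnotationFormatError(problems)
    return boxes


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Save a float image as 16-bit grayscale PNG (values clipped to [0, 2])."""
    arr = np.clip(np.asarray(image, float), 0.0, 2.0)
    Image.fromarray((arr / 2.0 * 65535).astype(np.uint16)).save(path)

def read_image_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path), float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr / 65535.0 * 2.0


def write_saliency_archive(
    maps: Sequence[SaliencyMap], path: str | Path
) -> None:
    """All saliency grids in one compressed archive.

    Keys are ``<case_id>/<model_id>/<view>``; scores travel in a parallel
    JSON-encoded array under ``__scores__``.
    """
    arrays = {
        f"{m.case_id}/{m.model_id}/{m.view}": m.grid.astype(np.float32)
        for m in maps
    }
    scores = {
        f"{m.case_id}/{m.model_id}/{m.view}": m.malignancy_score for m in maps
    }
    arrays["__scores__"] = np.frombuffer(
        json.dumps(scores, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def read_saliency_archive(path: str | Path) -> list[SaliencyMap]:
    with np.load(path) as data:
        scores = json.loads(bytes(data["__scores__"]).decode())
        out = []
        for key in data.files:
            if key == "__scores__":
                continue
            case_id, model_id, view = key.split("/")
            out.append(SaliencyMap(
                model_id=model_id, view=view,
                grid=np.asarray(data[key], float),
                malignancy_score=float(scores[key]), case_id=case_id,
            ))
    out.sort(key=lambda m: (m.case_id, m.model_id, m.view))
    return out


def _config_to_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["detect_quality"] = dict(d["detect_quality"])
    return d


def save_config(config: SynthConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> SynthConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("category_mix", "size_mix", "image_shape", "saliency_shape",
                "models", "lesions_per_view", "band_jitter_sigmas"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SynthConfig(**raw)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_cohort(cohort: Cohort, run_dir: str | Path) -> Path:
    """Persist a cohort under a run directory: config, annotations,
    saliency archive, per-case PNGs (when rendered), and a manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_config(cohort.config, run_dir / "config.yaml")
    boxes = [b for case in cohort.cases for b in case.reader_boxes]
    write_annotations(boxes, run_dir / "annotations.csv")
    if cohort.saliency_maps:
        write_saliency_archive(cohort.saliency_maps, run_dir / "saliency.npz")
    image_dir = run_dir / "images"
    n_png = 0
    for case in cohort.cases:
        for view, img in case.images.items():
            image_dir.mkdir(exist_ok=True)
            write_image_png(img, image_dir / f"{case.case_id}_{view}.png")
            n_png += 1
    cases_meta = [
        {
            "case_id": c.case_id,
            "category": c.category,
            "size_group": c.size_group,
            "laterality_of_cancer": c.laterality_of_cancer,
            "jitter_sigma": c.jitter_sigma,
            "truth_lesions": [
                {
                    "view": l.view,
                    "center": list(l.center),
                    "semi_axes": list(l.semi_axes),
                    "diameter_cm": l.diameter_cm,
                    "intensity_gain": l.intensity_gain,
                }
                for l in c.truth_lesions
            ],
        }
        for c in cohort.cases
    ]
    manifest = {
        "mammoeval_version": __version__,
        "seed": cohort.config.seed,
        "n_cases": len(cohort.cases),
        "n_saliency_maps": len(cohort.saliency_maps),
        "n_images": n_png,
        "cases": cases_meta,
        "file_hashes": {
            p.name: _file_hash(p)
            for p in sorted(run_dir.glob("*"))
            if p.is_file() and p.suffix in {".csv", ".yaml", ".npz"}
        },
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir


def read_cohort(run_dir: str | Path) -> Cohort:
    """Reconstruct a cohort from a persisted run directory.

    Rebuilds cases (metadata, truth lesions, reader boxes — images are not
    reloaded) and saliency maps, so every downstream table can be
    regenerated without re-simulation.
    """
    from .synthetic import Case, TruthLesion

    run_dir = Path(run_dir)
    config = load_config(run_dir / "config.yaml")
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    boxes_by_case: dict[str, list[AnnotationBox]] = {}
    for b in read_annotations(run_dir / "annotations.csv"):
        boxes_by_case.setdefault(b.case_id, []).append(b)
    cases = []
    for meta in manifest["cases"]:
        lesions = [
            TruthLesion(
                view=l["view"],
                center=tuple(l["center"]),
                semi_axes=tuple(l["semi_axes"]),
                diameter_cm=l["diameter_cm"],
                intensity_gain=l["intensity_gain"],
            )
            for l in meta["truth_lesions"]
        ]
        cases.append(Case(
            case_id=meta["case_id"],
            images={},
            laterality_of_cancer=meta["laterality_of_cancer"],
            category=meta["category"],
            size_group=meta["size_group"],
            truth_lesions=lesions,
            reader_boxes=boxes_by_case.get(meta["case_id"], []),
            jitter_sigma=meta["jitter_sigma"],
        ))
    archive = run_dir / "saliency.npz"
    maps = read_saliency_archive(archive) if archive.exists() else []
    return Cohort(cases=cases, saliency_maps=maps, config=config)


def run_pipeline(config: SynthConfig, run_dir: str | Path) -> Path:
    """simulate -> concord -> agree -> evaluate -> report, persisted.

    Each stage writes its table under ``run_dir``; any failure aborts with
    the stage name while earlier outputs stay on disk for debugging.
    Idempotent given the seed: re-running reproduces every CSV bit for bit.
    """
    run_dir = Path(run_dir)
    stage = "simulate"
    try:
        cohort = generate_cohort(config)
        write_cohort(cohort, run_dir)
        log.info("simulate: %d cases, %d saliency maps (seed=%d)",
                 len(cohort.cases), len(cohort.saliency_maps), config.seed)

        stage = "concord"
        boxes = [b for case in cohort.cases for b in case.reader_boxes]
        conc = concordance_table(boxes)
        conc.to_csv(run_dir / "concordance.csv", index=False)

        stage = "agree"
        agree_frames = []
        for model_id in config.models:
            df = agreement_by_level(cohort, model_id, concordance=conc)
            df.insert(0, "model_id", model_id)
            df["mode"] = "map_vs_annotation"
            agree_frames.append(df)
        if len(config.models) >= 2:
            df = agreement_by_level(
                cohort, config.models[0], other_model_id=config.models[1],
                concordance=conc,
            )
            df.insert(0, "model_id", f"{config.models[0]}_vs_{config.models[1]}")
            df["mode"] = "map_vs_map"
            agree_frames.append(df)
        agree = pd.concat(agree_frames, ignore_index=True)
        agree.to_csv(run_dir / "agreement.csv", index=False)

        stage = "evaluate"
        result_frames = {}
        for model_id in config.models:
            res = evaluate_cohort(cohort, model_id, concordance=conc)
            res.insert(0, "model_id", model_id)
            result_frames[model_id] = res
        results = pd.concat(result_frames.values(), ignore_index=True)
        results.to_csv(run_dir / "results.csv", index=False)

        stage = "report"
        summary: dict = {"models": {}}
        level_order = ["almost_perfect", "substantial", "moderate", "poor"]
        for model_id, res in result_frames.items():
            table1 = stratify(
                res, rows="level", cols="category",
                row_order=level_order, col_order=list(CATEGORIES),
            )
            format_stratified(table1).to_csv(
                run_dir / f"table1_{model_id}.csv"
            )
            rates = sensitivity_specificity(res)
            tests = {
                "category_chi2": compare_groups(res, "category", "chi2"),
                "level_anova": compare_groups(
                    res, "level", "anova", seed=config.seed
                ),
            }
            summary["models"][model_id] = {"rates": rates, "tests": tests}
        t2 = (
            agree.groupby(["model_id", "mode", "level"])[["sim", "kld"]]
            .mean()
            .reset_index()
        )
        t2.to_csv(run_dir / "table2_agreement.csv", index=False)
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return run_dir
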
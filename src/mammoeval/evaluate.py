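"""Case-level evaluation and stratified accuracy reporting.

Turns a cohort, its saliency maps and its concordance records into the
study's result surfaces: per-case classification at a score threshold,
localisation hit scoring, sensitivity/specificity with exact counts and
Wilson intervals, tables stratified by cancer category x concordance
level x size group, and group-difference tests (chi-square for
proportions; one-way ANOVA on subsample sensitivities with Holm-corrected
pairwise post-hocs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .agreement import boxes_to_mask, kld, sim, to_distribution
from .concordance import AnnotationBox, ConcordanceRecord, concordance_table
from .saliency import SaliencyMap
from .synthetic import Cohort

__all__ = [
    "classify_case",
    "localization_hit",
    "sensitivity_specificity",
    "stratify",
    "format_stratified",
    "compare_groups",
    "evaluate_cohort",
    "agreement_by_level",
]

DEFAULT_THRESHOLD = 0.5


def classify_case(
    malignancy_scores: Sequence[float], threshold: float = DEFAULT_THRESHOLD
) -> tuple[str, float]:
    """Case-level decision from per-view scores: max rule.

    Returns ("positive"/"negative", case_score) with
    case_score = max over views and positive iff score >= threshold.
    """
    if len(malignancy_scores) == 0:
        raise ValueError("need at least one view score")
    score = float(max(malignancy_scores))
    return ("positive" if score >= threshold else "negative", score)


def localization_hit(
    saliency: SaliencyMap,
    reference_boxes: Sequence[AnnotationBox],
    image_shape: tuple[int, int],
    criterion: str = "argmax",
    tau: float = 0.5,
) -> bool | None:
    """Whether a saliency map localises the lesion.

    ``argmax`` (default): the grid argmax, mapped to image coordinates by
    the per-axis size ratio, lies inside the union of reference boxes.
    ``mass_fraction``: at least ``tau`` of the map's mass falls inside the
    box union. Returns None (not applicable) when there is no reference
    box on this view — never a silent False.
    """
    boxes = [b for b in reference_boxes if b.view == saliency.view]
    if not boxes:
        return None
    grid = saliency.grid
    if criterion == "argmax":
        if grid.sum() == 0:
            return False
        r, c = np.unravel_index(int(np.argmax(grid)), grid.shape)
        row = (r + 0.5) * image_shape[0] / grid.shape[0]
        col = (c + 0.5) * image_shape[1] / grid.shape[1]
        return any(
            b.row_min <= row < b.row_max and b.col_min <= col < b.col_max
            for b in boxes
        )
    if criterion == "mass_fraction":
        total = grid.sum()
        if total == 0:
            return False
        mask = boxes_to_mask(boxes, image_shape)
        from .preprocess import resize_bilinear

        mask_g = resize_bilinear(mask, grid.shape) > 0.5
        return float(grid[mask_g].sum() / total) >= tau
    raise ValueError(f"unknown criterion {criterion!r}")


def _wilson(correct: int, total: int) -> tuple[float, float]:
    lo, hi = proportion_confint(correct, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def sensitivity_specificity(results: pd.DataFrame) -> dict:
    """Sensitivity and specificity with exact counts and 95% Wilson CIs.

    ``results`` needs boolean columns ``truth`` (cancer present) and
    ``predicted_positive``. Rates without any eligible case are reported
    as None, never as 0.
    """
    truth = results["truth"].to_numpy(bool)
    pred = results["predicted_positive"].to_numpy(bool)
    tp = int((truth & pred).sum())
    fn = int((truth & ~pred).sum())
    tn = int((~truth & ~pred).sum())
    fp = int((~truth & pred).sum())
    out: dict = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
    if tp + fn > 0:
        out["sensitivity"] = tp / (tp + fn)
        out["sensitivity_ci"] = _wilson(tp, tp + fn)
    else:
        out["sensitivity"] = None
        out["sensitivity_ci"] = None
    if tn + fp > 0:
        out["specificity"] = tn / (tn + fp)
        out["specificity_ci"] = _wilson(tn, tn + fp)
    else:
        out["specificity"] = None
        out["specificity_ci"] = None
    return out


def stratify(
    results: pd.DataFrame,
    rows: str = "level",
    cols: str = "category",
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sensitivity per stratum with exact numerator/denominator counts.

    Only truth-positive cases enter. The output has a MultiIndex column
    per stratum column with (sensitivity, correct, total); empty strata
    hold NaN sensitivity and zero counts (rendered as em dashes by
    :func:`format_stratified`, never as 0%).
    """
    for axis in (rows, cols):
        if axis not in results.columns:
            raise ValueError(f"results lack a {axis!r} column")
    pos = results[results["truth"]]
    if row_order is not None:
        unknown = set(pos[rows].dropna()) - set(row_order)
        if unknown:
            raise ValueError(f"unknown {rows} labels: {sorted(unknown)}")
    if col_order is not None:
        unknown = set(pos[cols].dropna()) - set(col_order)
        if unknown:
            raise ValueError(f"unknown {cols} labels: {sorted(unknown)}")
    row_vals = row_order or sorted(pos[rows].dropna().unique())
    col_vals = col_order or sorted(pos[cols].dropna().unique())
    data = {}
    for cv in col_vals:
        col_cells = []
        for rv in row_vals:
            cell = pos[(pos[rows] == rv) & (pos[cols] == cv)]
            total = len(cell)
            correct = int(cell["predicted_positive"].sum())
            sens = correct / total if total else float("nan")
            col_cells.append((sens, correct, total))
        data[cv] = col_cells
    frames = {}
    for cv, cells in data.items():
        frames[(cv, "sensitivity")] = [c[0] for c in cells]
        frames[(cv, "correct")] = [c[1] for c in cells]
        frames[(cv, "total")] = [c[2] for c in cells]
    table = pd.DataFrame(frames, index=pd.Index(row_vals, name=rows))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=[cols, None])
    return table


def format_stratified(table: pd.DataFrame) -> pd.DataFrame:
    """Render a stratified table as "82.98% (78/94)" strings ("—" if empty)."""
    cols = table.columns.get_level_values(0).unique()
    out = {}
    for cv in cols:
        cells = []
        for rv in table.index:
            sens = table.loc[rv, (cv, "sensitivity")]
            correct = table.loc[rv, (cv, "correct")]
            total = table.loc[rv, (cv, "total")]
            if total == 0 or pd.isna(sens):
                cells.append("—")
            else:
                cells.append(f"{100 * sens:.2f}% ({int(correct)}/{int(total)})")
        out[cv] = cells
    return pd.DataFrame(out, index=table.index)


def compare_groups(
    results: pd.DataFrame,
    group_col: str = "category",
    method: str = "chi2",
    n_subsamples: int = 10,
    seed: int = 0,
) -> dict:
    """Test whether detection rates differ across groups.

    ``chi2``: chi-square test of independence on the detected/missed
    confusion counts across groups. ``anova``: each group's truth-positive
    cases are split into ``n_subsamples`` seeded folds, per-fold
    sensitivities feed a one-way ANOVA, and pairwise Welch t-tests are
    Holm-corrected. Returns the p-value(s) and the test actually used, or
    ``testable = False`` when fewer than two groups have cases.
    """
    pos = results[results["truth"]]
    groups = [g for g in sorted(pos[group_col].dropna().unique())]
    counts = {
        g: (
            int(pos[pos[group_col] == g]["predicted_positive"].sum()),
            int((pos[group_col] == g).sum()),
        )
        for g in groups
    }
    usable = [g for g in groups if counts[g][1] > 0]
    if len(usable) < 2:
        return {"testable": False, "method": method, "groups": groups}
    if method == "chi2":
        table = np.array(
            [[counts[g][0], counts[g][1] - counts[g][0]] for g in usable]
        )
        if (table.sum(axis=0) == 0).any():
            # all detected or all missed everywhere: no variation to test
            return {"testable": False, "method": method, "groups": usable}
        chi2, p, dof, _ = stats.chi2_contingency(table)
        return {
            "testable": True, "method": "chi2", "groups": usable,
            "statistic": float(chi2), "p_value": float(p), "dof": int(dof),
            "counts": counts,
        }
    if method == "anova":
        rng = np.random.default_rng(seed)
        fold_sens: dict[str, list[float]] = {}
        for g in usable:
            sub = pos[pos[group_col] == g]
            hits = sub["predicted_positive"].to_numpy(float)
            order = rng.permutation(len(hits))
            folds = np.array_split(hits[order], n_subsamples)
            fold_sens[g] = [float(f.mean()) for f in folds if len(f) > 0]
        samples = [fold_sens[g] for g in usable]
        if any(len(s) < 2 for s in samples):
            return {"testable": False, "method": method, "groups": usable}
        import warnings

        with warnings.catch_warnings():
            # near-constant fold sensitivities trip scipy's precision
            # warning; the degenerate case is handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            f_stat, p = stats.f_oneway(*samples)
            if not np.isfinite(p):
                # zero variance everywhere: identical rates, no evidence
                f_stat, p = 0.0, 1.0
            pairs = list(combinations(usable, 2))
            raw_p = []
            for ga, gb in pairs:
                _, pp = stats.ttest_ind(
                    fold_sens[ga], fold_sens[gb], equal_var=False
                )
                raw_p.append(float(pp) if np.isfinite(pp) else 1.0)
        if raw_p:
            _, adj, _, _ = multipletests(raw_p, method="holm")
        else:
            adj = []
        posthoc = {
            f"{ga}_vs_{gb}": float(p_adj)
            for (ga, gb), p_adj in zip(pairs, adj)
        }
        return {
            "testable": True, "method": "anova", "groups": usable,
            "statistic": float(f_stat), "p_value": float(p),
            "posthoc_holm": posthoc, "counts": counts,
        }
    raise ValueError(f"unknown method {method!r}")


def evaluate_cohort(
    cohort: Cohort,
    model_id: str = "gmic_like",
    threshold: float = DEFAULT_THRESHOLD,
    concordance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case results table for one model over a cohort.

    Columns: case_id, truth, category, size_group, level (reader
    concordance; None for cancer-free cases), predicted_positive, score,
    localization_hit (None when not applicable).
    """
    if concordance is None:
        boxes = [b for case in cohort.cases for b in case.reader_boxes]
        concordance = concordance_table(boxes) if boxes else pd.DataFrame(
            columns=["case_id", "level"]
        )
    level_of = dict(zip(concordance["case_id"], concordance["level"]))
    rows = []
    for case in cohort.cases:
        maps = cohort.saliency_for(case.case_id, model_id)
        if not maps:
            continue
        label, score = classify_case(
            [m.malignancy_score for m in maps], threshold
        )
        hit: bool | None = None
        if case.truth_lesions:
            refs = [l.truth_box(case.case_id) for l in case.truth_lesions]
            view_hits = [
                localization_hit(m, refs, cohort.config.image_shape)
                for m in maps
            ]
            view_hits = [h for h in view_hits if h is not None]
            hit = any(view_hits) if view_hits else None
        rows.append({
            "case_id": case.case_id,
            "truth": case.is_cancer,
            "category": case.category,
            "size_group": case.size_group,
            "level": level_of.get(case.case_id),
            "predicted_positive": label == "positive",
            "score": score,
            "localization_hit": hit,
        })
    return pd.DataFrame(rows)


def agreement_by_level(
    cohort: Cohort,
    model_id: str = "gmic_like",
    other_model_id: str | None = None,
    concordance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-view SIM/KLD between saliency and a reference, with case level.

    By default each cancer view's saliency distribution is compared with
    the readers' annotation-box distribution; pass ``other_model_id`` to
    compare two models' maps instead. Returns one row per usable view:
    case_id, view, level, sim, kld.
    """
    if concordance is None:
        boxes = [b for case in cohort.cases for b in case.reader_boxes]
        concordance = concordance_table(boxes) if boxes else pd.DataFrame(
            columns=["case_id", "level"]
        )
    level_of = dict(zip(concordance["case_id"], concordance["level"]))
    shape = cohort.config.saliency_shape
    img_shape = cohort.config.image_shape
    rows = []
    for case in cohort.cases:
        if not case.is_cancer:
            continue
        maps = cohort.saliency_for(case.case_id, model_id)
        other = (
            {m.view: m for m in cohort.saliency_for(case.case_id, other_model_id)}
            if other_model_id else {}
        )
        for m in maps:
            try:
                d1 = to_distribution(m.grid, shape)
            except ValueError:
                continue
            if other_model_id:
                om = other.get(m.view)
                if om is None:
                    continue
                try:
                    d2 = to_distribution(om.grid, shape)
                except ValueError:
                    continue
            else:
                boxes = [b for b in case.reader_boxes if b.view == m.view]
                if not boxes:
                    continue
                d2 = to_distribution(boxes, shape, image_shape=img_shape)
            rows.append({
                "case_id": case.case_id,
                "view": m.view,
                "level": level_of.get(case.case_id),
                "sim": sim(d1, d2),
                "kld": kld(d1, d2),
            })
    return pd.DataFrame(rows)
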
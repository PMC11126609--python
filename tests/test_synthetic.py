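"""Synthetic cohort generator: determinism, mixes, jitter, saliency dials."""

import numpy as np
import pytest

from mammoeval.concordance import AnnotationBox, evaluate_case
from mammoeval.synthetic import (
    LesionPlacementError,
    SynthConfig,
    TruthLesion,
    allocate_counts,
    breast_mask,
    generate_cohort,
    generate_image,
    generate_saliency,
    jitter_box,
    size_group_of,
)


class TestConfigValidation:
    def test_mixes_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SynthConfig(category_mix=(0.5, 0.2, 0.2))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(jitter_sigma=-1)

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_cases=0)

    def test_quality_must_be_probability(self):
        with pytest.raises(ValueError):
            SynthConfig(detect_quality={"missed": 1.2,
                                        "prior_vis": 0.9,
                                        "prior_invis": 0.9})


class TestSizeGroups:
    @pytest.mark.parametrize("d,g", [(0.5, "T1"), (2.0, "T1"), (2.01, "T2"),
                                     (4.99, "T2"), (5.0, "T3"), (8.0, "T3")])
    def test_thresholds(self, d, g):
        assert size_group_of(d) == g

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            size_group_of(0.0)


class TestAllocation:
    def test_exact_example(self):
        assert allocate_counts(100, (0.25, 0.35, 0.40)) == [25, 35, 40]

    def test_largest_remainder_on_awkward_mix(self):
        counts = allocate_counts(10, (1 / 3, 1 / 3, 1 / 3))
        assert sum(counts) == 10 and sorted(counts) == [3, 3, 4]

    def test_always_sums_to_n(self, rng):
        for _ in range(50):
            p = rng.random(4)
            p /= p.sum()
            n = int(rng.integers(1, 500))
            counts = allocate_counts(n, p)
            assert sum(counts) == n
            assert all(abs(c - n * q) <= 1 for c, q in zip(counts, p))


class TestGenerateImage:
    def test_foreground_is_single_component_touching_chest_wall(self):
        img, mask = generate_image("RCC", [], 0.0, seed=1, shape=(96, 64))
        from skimage.measure import label

        assert label(mask).max() == 1
        assert mask[:, -1].any() and not mask[:, 0].any()  # right edge
        # background border band near zero
        assert img[0, :].max() == 0.0 and img[-1, :].max() == 0.0

    def test_lesion_raises_local_intensity(self):
        lesion = TruthLesion("LCC", (48.0, 20.0), (8.0, 6.0), 1.2,
                             intensity_gain=0.5)
        img, mask = generate_image("LCC", [lesion], 0.0, seed=1,
                                   shape=(96, 64))
        rr, cc = np.mgrid[0:96, 0:64]
        inside = ((rr - 48) / 8.0) ** 2 + ((cc - 20) / 6.0) ** 2 <= 1
        outside = mask & ~inside
        assert img[inside].mean() > img[outside].mean()

    def test_seeded_determinism(self):
        a, _ = generate_image("LMLO", [], 0.05, seed=7, shape=(64, 48))
        b, _ = generate_image("LMLO", [], 0.05, seed=7, shape=(64, 48))
        np.testing.assert_array_equal(a, b)

    def test_lesion_outside_breast_rejected(self):
        lesion = TruthLesion("LCC", (5.0, 60.0), (10.0, 10.0), 1.6)
        with pytest.raises(LesionPlacementError):
            generate_image("LCC", [lesion], 0.0, seed=1, shape=(96, 64))


class TestJitterBox:
    def box(self):
        return AnnotationBox("c", "truth", "LCC", 40, 30, 60, 50)

    def test_zero_sigma_is_identity(self):
        assert jitter_box(self.box(), 0.0, seed=3) == self.box()

    def test_seeded_reproducibility(self):
        a = jitter_box(self.box(), 2.0, seed=11)
        b = jitter_box(self.box(), 2.0, seed=11)
        assert a == b and a != self.box()

    def test_mean_absolute_displacement_is_half_normal(self):
        """E|N(0, s)| = s * sqrt(2/pi); Monte-Carlo check at s=5."""
        rng = np.random.default_rng(99)
        disp = []
        truth = AnnotationBox("c", "truth", "LCC", 100, 80, 160, 140)
        for _ in range(1000):
            j = jitter_box(truth, 5.0, rng, image_shape=(368, 240))
            disp.extend(np.abs(j.as_array() - truth.as_array()))
        expected = 5.0 * np.sqrt(2 / np.pi)
        assert np.mean(disp) == pytest.approx(expected, rel=0.10)

    def test_degenerate_draws_eventually_error(self):
        # a 1x1 box fully in the corner with huge jitter cannot always
        # survive clipping; bounded retries then raise
        from mammoeval.synthetic import DegenerateBoxError

        tiny = AnnotationBox("c", "truth", "LCC", 0, 0, 1, 1)
        with pytest.raises(DegenerateBoxError):
            # fixed seed chosen only for determinism of the failure path
            jitter_box(tiny, 500.0, seed=1, image_shape=(4, 4),
                       max_retries=3)


class TestGenerateSaliency:
    def test_no_lesions_no_fp_gives_zero_map(self):
        m = generate_saliency([], 0.0, 10.0, 0.0, seed=1, view="LCC")
        assert not m.grid.any() and m.malignancy_score == 0.0

    def test_centered_blob_argmax_at_lesion(self):
        lesion = TruthLesion("LCC", (184.0, 100.0), (12.0, 12.0), 1.9)
        m = generate_saliency([lesion], 0.0, 12.0, 0.0, seed=1, view="LCC",
                              image_shape=(368, 240), grid_shape=(184, 120))
        r, c = np.unravel_index(np.argmax(m.grid), m.grid.shape)
        assert (r, c) == (92, 50)

    def test_fp_blob_count_matches_poisson_rate(self):
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(500):
            m = generate_saliency([], 0.0, 10.0, 3.0, rng, view="LCC",
                                  grid_shape=(46, 30))
            # blobs are the only mass; count by local maxima is fragile,
            # so recover the Poisson draw from the generator contract:
            counts.append(m.grid.max() > 0)
        # P(N=0) = exp(-3) ~ 0.0498: frequency of empty maps checks the rate
        frac_empty = 1.0 - np.mean(counts)
        assert frac_empty == pytest.approx(np.exp(-3.0), abs=0.03)


class TestGenerateCohort:
    def test_category_mix_allocated_exactly(self):
        cfg = SynthConfig(n_cases=100, n_normals=0, seed=1,
                          render_saliency=False)
        cohort = generate_cohort(cfg)
        cats = [c.category for c in cohort.cases]
        assert cats.count("missed") == 25
        assert cats.count("prior_vis") == 35
        assert cats.count("prior_invis") == 40

    def test_size_mix_allocated_exactly(self):
        cfg = SynthConfig(n_cases=50, n_normals=0, seed=1,
                          size_mix=(0.5, 0.3, 0.2), render_saliency=False)
        cohort = generate_cohort(cfg)
        sizes = [c.size_group for c in cohort.cases]
        assert (sizes.count("T1"), sizes.count("T2"), sizes.count("T3")) \
            == (25, 15, 10)

    def test_zero_jitter_cohort_all_almost_perfect(self):
        cfg = SynthConfig(n_cases=30, n_normals=0, jitter_sigma=0.0, seed=2,
                          render_saliency=False, single_reader_rate=0.0)
        cohort = generate_cohort(cfg)
        for case in cohort.cases:
            rec = evaluate_case(case.reader_boxes)
            assert rec.ccc == 1.0 and rec.level == "almost_perfect"

    def test_bit_identical_under_same_seed(self):
        cfg = SynthConfig(n_cases=12, n_normals=6, seed=77,
                          saliency_shape=(46, 30))
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ca, cb in zip(a.cases, b.cases):
            assert ca.reader_boxes == cb.reader_boxes
            assert ca.category == cb.category
        for ma, mb in zip(a.saliency_maps, b.saliency_maps):
            np.testing.assert_array_equal(ma.grid, mb.grid)
            assert ma.malignancy_score == mb.malignancy_score

    def test_normal_cases_have_no_lesions(self):
        cfg = SynthConfig(n_cases=5, n_normals=4, seed=3,
                          saliency_shape=(46, 30))
        cohort = generate_cohort(cfg)
        normals = [c for c in cohort.cases if c.category == "normal"]
        assert len(normals) == 4
        for c in normals:
            assert c.truth_lesions == [] and c.reader_boxes == []
            assert c.size_group == "none"

    def test_lesions_lie_inside_breast_and_carry_consistent_sizes(self):
        cfg = SynthConfig(n_cases=20, n_normals=0, seed=4,
                          render_saliency=False)
        cohort = generate_cohort(cfg)
        for case in cohort.cases:
            for lesion in case.truth_lesions:
                assert lesion.size_group == case.size_group
                mask = breast_mask(lesion.view, cfg.image_shape)
                r, c = (int(round(v)) for v in lesion.center)
                assert mask[r, c]

    def test_saliency_argmax_accuracy_degrades_with_offset(self):
        fracs = []
        for off in (0.0, 12.0, 60.0):
            cfg = SynthConfig(n_cases=60, n_normals=0, seed=6,
                              saliency_offset_sigma=off,
                              models=("gmic_like",),
                              saliency_shape=(92, 60))
            cohort = generate_cohort(cfg)
            hits = 0
            total = 0
            for case in cohort.cases:
                refs = [l.truth_box(case.case_id) for l in case.truth_lesions]
                for m in cohort.saliency_for(case.case_id, "gmic_like"):
                    vrefs = [b for b in refs if b.view == m.view]
                    if not vrefs or not m.grid.any():
                        continue
                    r, c = np.unravel_index(np.argmax(m.grid), m.grid.shape)
                    row = (r + 0.5) * cfg.image_shape[0] / m.grid.shape[0]
                    col = (c + 0.5) * cfg.image_shape[1] / m.grid.shape[1]
                    total += 1
                    hits += any(b.row_min <= row < b.row_max
                                and b.col_min <= col < b.col_max
                                for b in vrefs)
            fracs.append(hits / total)
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[0] - fracs[2] > 0.2


class TestMonotoneConcordanceDial:
    def test_mean_ccc_strictly_decreasing_in_jitter(self):
        means = []
        for sigma in (0.0, 1.0, 2.0, 5.0, 10.0):
            cfg = SynthConfig(n_cases=200, n_normals=0, jitter_sigma=sigma,
                              seed=8, render_saliency=False,
                              single_reader_rate=0.0)
            cohort = generate_cohort(cfg)
            cccs = [evaluate_case(c.reader_boxes).ccc for c in cohort.cases]
            means.append(np.nanmean(cccs))
        assert all(a > b for a, b in zip(means, means[1:]))
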
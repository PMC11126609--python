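"""Reader-concordance machinery: IoU, matching, Lin's CCC, McBride levels."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mammoeval.concordance import (
    AnnotationBox,
    ConcordanceInputError,
    MatchedPair,
    case_concordance,
    concordance_table,
    evaluate_case,
    iou,
    iou_matrix,
    is_challenging,
    lin_ccc,
    match_boxes,
    mcbride_level,
)


def box(r0, c0, r1, c1, reader="A", view="LCC", case="c1"):
    return AnnotationBox(case, reader, view, r0, c0, r1, c1)


class TestIoU:
    def test_identical_boxes_have_iou_one(self):
        assert iou(box(0, 0, 4, 4), box(0, 0, 4, 4, "B")) == 1.0

    def test_disjoint_boxes_have_iou_zero(self):
        assert iou(box(0, 0, 2, 2), box(5, 5, 7, 7, "B")) == 0.0

    def test_unit_overlap_example(self):
        # [0,2)x[0,2) vs [1,3)x[1,3): intersection 1, union 7
        assert iou(box(0, 0, 2, 2), box(1, 1, 3, 3, "B")) == pytest.approx(1 / 7)

    def test_touching_boxes_do_not_overlap(self):
        # half-open convention: [0,2) and [2,4) share no pixel
        assert iou(box(0, 0, 2, 2), box(2, 0, 4, 2, "B")) == 0.0

    def test_cross_view_comparison_rejected(self):
        with pytest.raises(ConcordanceInputError) as err:
            iou(box(0, 0, 2, 2, view="LCC"), box(0, 0, 2, 2, view="RCC"))
        assert err.value.code == "view_mismatch"

    def test_degenerate_box_rejected(self):
        with pytest.raises(ConcordanceInputError):
            box(3, 0, 3, 2)

    def test_matches_pixel_counting_on_random_boxes(self, rng):
        """Scalar iou equals rasterized pixel counting on random pairs."""
        for _ in range(300):
            r0a, r1a = sorted(rng.choice(21, 2, replace=False))
            c0a, c1a = sorted(rng.choice(21, 2, replace=False))
            r0b, r1b = sorted(rng.choice(21, 2, replace=False))
            c0b, c1b = sorted(rng.choice(21, 2, replace=False))
            ba = box(r0a, c0a, r1a, c1a)
            bb = box(r0b, c0b, r1b, c1b, "B")
            ma = np.zeros((21, 21), bool)
            mb = np.zeros((21, 21), bool)
            ma[r0a:r1a, c0a:c1a] = True
            mb[r0b:r1b, c0b:c1b] = True
            expected = (ma & mb).sum() / (ma | mb).sum()
            assert iou(ba, bb) == pytest.approx(expected, abs=1e-12)

    def test_scalar_matches_vectorised_matrix(self, rng):
        coords = np.sort(rng.integers(0, 15, size=(30, 2, 2)), axis=2)
        boxes = [
            box(c[0, 0], c[1, 0], c[0, 1] + 1, c[1, 1] + 1) for c in coords
        ]
        arr = np.array([b.as_array() for b in boxes])
        mat = iou_matrix(arr, arr)
        for i, bi in enumerate(boxes):
            for j, bj in enumerate(boxes):
                other = box(bj.row_min, bj.col_min, bj.row_max, bj.col_max, "B")
                assert mat[i, j] == pytest.approx(iou(bi, other), abs=1e-12)


class TestMatching:
    def test_single_overlapping_pair(self):
        pairs, unmatched = match_boxes(
            [box(0, 0, 4, 4)], [box(1, 1, 5, 5, "B")]
        )
        assert len(pairs) == 1 and not unmatched

    def test_disjoint_boxes_stay_unmatched(self):
        pairs, unmatched = match_boxes(
            [box(0, 0, 2, 2)], [box(10, 10, 12, 12, "B")]
        )
        assert pairs == [] and len(unmatched) == 2

    def test_greedy_resolves_cross_overlaps_by_descending_iou(self):
        # cross IoUs approximately {(0.8, 0.1), (0.2, 0.7)}
        a1 = box(0, 0, 10, 10)
        a2 = box(20, 20, 30, 30)
        b1 = box(0, 0, 10, 9, "B")       # iou(a1,b1) = 0.9
        b2 = box(20, 20, 30, 27, "B")    # iou(a2,b2) = 0.7
        # also force weak cross overlaps
        pairs, unmatched = match_boxes([a1, a2], [b1, b2])
        matched = {(p.box_a.row_min, p.box_b.row_min) for p in pairs}
        assert matched == {(0, 0), (20, 20)} and not unmatched

    def test_matching_is_maximal(self, rng):
        """No two unmatched boxes from opposite readers still overlap."""
        def mk(reader):
            out = []
            for _ in range(rng.integers(1, 4)):
                r0, r1 = np.sort(rng.integers(0, 12, 2)) + [0, 1]
                c0, c1 = np.sort(rng.integers(0, 12, 2)) + [0, 1]
                out.append(box(r0, c0, r1, c1, reader))
            return out

        for _ in range(100):
            boxes_a, boxes_b = mk("A"), mk("B")
            pairs, unmatched = match_boxes(boxes_a, boxes_b)
            un_a = [b for b in unmatched if b.reader == "A"]
            un_b = [b for b in unmatched if b.reader == "B"]
            for ba in un_a:
                for bb in un_b:
                    assert iou(ba, bb) == 0.0
            # one-to-one
            assert len({id(p.box_a) for p in pairs}) == len(pairs)
            assert len({id(p.box_b) for p in pairs}) == len(pairs)


class TestLinCCC:
    def test_perfect_concordance_is_exactly_one(self):
        assert lin_ccc([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_constant_shift_example(self):
        # 2*1.25 / (1.25 + 1.25 + 1) = 0.714285...
        assert lin_ccc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(
            2 * 1.25 / 3.5, abs=1e-12
        )

    def test_perfect_reversal_is_minus_one(self):
        assert lin_ccc([1, 2], [2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_exact_rational_oracle(self, rng):
        """CCC agrees with exact Fraction arithmetic on random sequences."""
        for _ in range(200):
            n = int(rng.integers(2, 12))
            x = rng.integers(-50, 50, n) / 8.0
            y = rng.integers(-50, 50, n) / 8.0
            if np.array_equal(x, y) or (np.ptp(x) == 0 and np.ptp(y) == 0):
                continue
            fx = [Fraction(v).limit_denominator(10**9) for v in x]
            fy = [Fraction(v).limit_denominator(10**9) for v in y]
            mx, my = sum(fx) / n, sum(fy) / n
            sxx = sum((v - mx) ** 2 for v in fx) / n
            syy = sum((v - my) ** 2 for v in fy) / n
            sxy = sum((a - mx) * (b - my) for a, b in zip(fx, fy)) / n
            expected = 2 * sxy / (sxx + syy + (mx - my) ** 2)
            assert lin_ccc(x, y) == pytest.approx(float(expected), abs=1e-12)

    def test_error_codes_are_distinct(self):
        with pytest.raises(ConcordanceInputError) as e1:
            lin_ccc([1, 2], [1, 2, 3])
        with pytest.raises(ConcordanceInputError) as e2:
            lin_ccc([3, 3, 3], [5, 5, 5])
        assert e1.value.code == "length_mismatch"
        assert e2.value.code == "constant_input"

    @given(
        st.lists(st.integers(-100, 100), min_size=3, max_size=20),
        st.integers(1, 9),
        st.integers(-20, 20),
    )
    def test_invariant_under_shared_positive_affine_map(self, xs, scale, shift):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        x = np.array(xs, float)
        y = x + rng.normal(0, 1.0, len(x))
        base = lin_ccc(x, y)
        mapped = lin_ccc(scale * x + shift, scale * y + shift)
        assert mapped == pytest.approx(base, abs=1e-9)

    @given(st.integers(0, 5000))
    def test_never_exceeds_pearson_in_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.5 * x
        ccc = lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12


class TestCaseConcordance:
    def test_identical_annotations_give_one(self):
        a, b = box(2, 3, 10, 12), box(2, 3, 10, 12, "B")
        assert case_concordance([MatchedPair(a, b, 1.0)]) == 1.0

    def test_location_shift_penalised_below_pearson(self):
        # reader B = reader A shifted: Pearson over corners stays 1,
        # CCC strictly below
        a1, a2 = box(0, 0, 10, 10), box(30, 30, 44, 44)
        b1, b2 = box(5, 5, 15, 15, "B"), box(35, 35, 49, 49, "B")
        ccc = case_concordance(
            [MatchedPair(a1, b1, 0.3), MatchedPair(a2, b2, 0.3)]
        )
        x = np.array(a1.corners() + a2.corners())
        y = np.array(b1.corners() + b2.corners())
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)
        assert ccc < 1.0

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ConcordanceInputError):
            case_concordance([])


class TestMcBride:
    @pytest.mark.parametrize(
        "ccc,level",
        [
            (0.995, "almost_perfect"),
            (0.97, "substantial"),
            (0.92, "moderate"),
            (0.85, "poor"),
            (-0.2, "poor"),
            # boundary convention: edge values go to the lower category
            (0.99, "substantial"),
            (0.95, "moderate"),
            (0.90, "poor"),
        ],
    )
    def test_band_assignment(self, ccc, level):
        assert mcbride_level(ccc) == level

    def test_out_of_range_rejected(self):
        with pytest.raises(ConcordanceInputError):
            mcbride_level(1.5)


class TestChallenging:
    def test_identical_boxes_not_challenging(self):
        a, b = box(0, 0, 5, 5), box(0, 0, 5, 5, "B")
        assert is_challenging([MatchedPair(a, b, 1.0)]) is False

    def test_partial_overlap_is_challenging(self):
        a, b = box(0, 0, 8, 8), box(4, 4, 12, 12, "B")
        assert is_challenging([MatchedPair(a, b, iou(a, b))]) is True

    def test_total_disagreement_is_challenging(self):
        assert is_challenging([]) is True


class TestEvaluateCase:
    def test_total_disagreement_flagged_poor(self):
        rec = evaluate_case([box(0, 0, 2, 2), box(10, 10, 14, 14, "B")])
        assert np.isnan(rec.ccc)
        assert rec.level == "poor" and rec.challenging

    def test_table_has_one_row_per_case(self):
        boxes = [
            box(0, 0, 5, 5, "A", case="x"),
            box(0, 0, 5, 5, "B", case="x"),
            box(2, 2, 8, 8, "A", case="y"),
            box(3, 3, 9, 9, "B", case="y"),
        ]
        table = concordance_table(boxes)
        assert list(table["case_id"]) == ["x", "y"]
        assert table.loc[0, "ccc"] == 1.0
        assert table.loc[0, "level"] == "almost_perfect"
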
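"""Thresholding, co-localization, compartment metrics, and OD grading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cishquant.errors import (
    DegeneracyError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
    ShapeError,
)
from cishquant.quantitation import (
    GRADE_LABELS,
    PRINTED_CUTOFFS,
    PRINTED_OD_MAX,
    PRINTED_OD_MIN,
    colocalize,
    compute_sample_metrics,
    default_grade_scale,
    derive_grade_scale,
    grade_code,
    grade_od,
    threshold_map,
)
from cishquant.unmixing import ConcentrationMaps


def make_maps(nbt, mg=None):
    nbt = np.asarray(nbt, dtype=float)
    mg = np.zeros_like(nbt) if mg is None else np.asarray(mg, dtype=float)
    return ConcentrationMaps(("NBT/BCIP", "methyl_green"),
                             np.stack([nbt, mg]), np.zeros_like(nbt))


class TestThresholding:
    def test_zero_map_yields_empty_mask(self):
        roi = np.ones((4, 4), bool)
        assert not threshold_map(np.zeros((4, 4)), roi, "absolute", 0.1).any()

    def test_absolute_threshold_is_strict(self):
        roi = np.ones((1, 2), bool)
        mask = threshold_map(np.array([[0.05, 0.15]]), roi, "absolute", 0.1)
        np.testing.assert_array_equal(mask, [[False, True]])

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyInputError):
            threshold_map(np.ones((3, 3)), np.zeros((3, 3), bool), "absolute", 0.1)

    def test_otsu_separates_a_bimodal_map(self):
        """Otsu must land between the modes; the oracle is an exhaustive
        sweep maximizing between-class variance over candidate thresholds."""
        rng = np.random.default_rng(0)
        lo = rng.normal(0.1, 0.01, 500)
        hi = rng.normal(0.8, 0.01, 500)
        pixels = np.concatenate([lo, hi]).reshape(20, 50)
        roi = np.ones_like(pixels, bool)
        mask = threshold_map(pixels, roi, "otsu")

        flat = np.sort(pixels.ravel())
        best_thr, best_var = None, -1.0
        for thr in (flat[:-1] + flat[1:]) / 2:
            below, above = flat[flat <= thr], flat[flat > thr]
            w0, w1 = below.size / flat.size, above.size / flat.size
            var = w0 * w1 * (below.mean() - above.mean()) ** 2
            if var > best_var:
                best_var, best_thr = var, thr
        assert 0.2 < best_thr < 0.7
        np.testing.assert_array_equal(mask, pixels > best_thr)

    def test_otsu_restricted_to_roi(self):
        pixels = np.zeros((10, 10))
        pixels[:, 5:] = 0.8
        roi = np.zeros((10, 10), bool)
        roi[:, 5:] = True  # constant inside ROI -> nothing above background
        assert not threshold_map(pixels, roi, "otsu").any()


class TestColocalization:
    def test_disjoint_masks_have_empty_overlap(self):
        a = np.array([[True, False], [False, False]])
        b = np.array([[False, True], [False, False]])
        assert not colocalize(a, b).overlap_mask.any()

    def test_identical_masks_overlap_fully(self):
        a = np.array([[True, False], [True, True]])
        masks = colocalize(a, a)
        np.testing.assert_array_equal(masks.overlap_mask, a)

    def test_toy_overlap_count(self):
        nbt = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 0]], bool)
        mg = np.array([[1, 0, 0], [1, 0, 1], [0, 0, 0]], bool)
        assert colocalize(nbt, mg).overlap_mask.sum() == 2  # hand enumeration

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            colocalize(np.ones((2, 2), bool), np.ones((3, 3), bool))

    def test_masks_clipped_to_roi(self):
        a = np.ones((2, 2), bool)
        roi = np.array([[True, False], [False, False]])
        masks = colocalize(a, a, roi)
        assert masks.nbt_mask.sum() == 1


class TestSampleMetrics:
    def test_hand_computed_toy_partition(self):
        """3x3 field: NBT on 4 pixels at 1.0 OD, one of them nuclear."""
        nbt_conc = np.array([[1.0, 1.0, 0], [1.0, 1.0, 0], [0, 0, 0]])
        mg_mask = np.array([[True, False, False]] + [[False] * 3] * 2)
        maps = make_maps(nbt_conc)
        masks = colocalize(nbt_conc > 0, mg_mask)
        m = compute_sample_metrics(maps, masks)
        assert m.total_signal_full == pytest.approx(4.0)
        assert m.total_signal_overlap == pytest.approx(1.0)
        assert m.signal_cyto == pytest.approx(3.0)
        assert m.area_cyto_px == 3 and m.area_nuc_px == 1
        assert m.avg_signal_cyto == pytest.approx(1.0)
        assert m.avg_signal_nuc == pytest.approx(1.0)
        assert m.nc_ratio == pytest.approx(1.0)
        assert m.expression_fraction_roi == pytest.approx(4 / 9)
        assert m.mean_od == pytest.approx(1.0)

    def test_average_signal_is_total_over_area(self):
        nbt_conc = np.zeros((3, 3))
        nbt_conc[0, :2] = [5.0, 7.0]
        maps = make_maps(nbt_conc)
        masks = colocalize(nbt_conc > 0, np.zeros((3, 3), bool))
        m = compute_sample_metrics(maps, masks)
        assert m.avg_signal_cyto == pytest.approx(12.0 / 2)

    def test_empty_expression_is_flagged_not_raised(self):
        maps = make_maps(np.zeros((3, 3)))
        masks = colocalize(np.zeros((3, 3), bool), np.zeros((3, 3), bool))
        m = compute_sample_metrics(maps, masks)
        assert m.expression_fraction_roi == 0.0
        assert m.degenerate
        assert np.isnan(m.avg_signal_cyto) and m.grade is None

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_signal_conservation_on_random_fields(self, seed):
        """cytoplasmic + nuclear signal == total signal, exactly."""
        rng = np.random.default_rng(seed)
        nbt_conc = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.5)
        mg = rng.random((8, 8)) < 0.4
        maps = make_maps(nbt_conc)
        masks = colocalize(nbt_conc > 0, mg)
        m = compute_sample_metrics(maps, masks)
        assert m.signal_cyto + m.total_signal_overlap == pytest.approx(
            m.total_signal_full, rel=1e-13, abs=1e-13)
        assert m.area_cyto_px + m.area_nuc_px == int(masks.nbt_mask.sum())
        assert 0.0 <= m.expression_fraction_roi <= 1.0


class TestGrading:
    def test_printed_cutoffs_are_the_default_scale(self):
        scale = default_grade_scale()
        assert scale.cutoffs == PRINTED_CUTOFFS
        assert scale.od_min == PRINTED_OD_MIN and scale.od_max == PRINTED_OD_MAX

    @pytest.mark.parametrize("value,expected", [
        (0.377, "negative"),          # boundary inclusive below
        (0.20825, "negative"),        # observed minimum
        (0.378, "weak_positive"),
        (0.5105, "weak_positive"),    # upper bound inclusive
        (0.5106, "moderate"),
        (0.68025, "moderate"),
        (0.68026, "strong_positive"),
        (0.9455, "strong_positive"),  # observed maximum
    ])
    def test_four_tier_binning(self, value, expected):
        assert grade_od(value) == expected

    def test_negative_od_rejected(self):
        with pytest.raises(ParameterError):
            grade_od(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0, max_value=2, allow_nan=False),
           st.floats(min_value=0, max_value=2, allow_nan=False))
    def test_grading_is_monotone_and_total(self, v1, v2):
        g1, g2 = grade_od(min(v1, v2)), grade_od(max(v1, v2))
        assert grade_code(g1) <= grade_code(g2)
        assert g1 in GRADE_LABELS and g2 in GRADE_LABELS

    def test_quartiles_of_one_to_five(self):
        scale = derive_grade_scale([1, 2, 3, 4, 5])
        assert scale.cutoffs == (2.0, 3.0, 4.0)  # sorted-order interpolation

    def test_constant_values_are_degenerate(self):
        with pytest.raises(DegeneracyError):
            derive_grade_scale([0.5, 0.5, 0.5, 0.5])

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_grade_scale([0.2, 0.5, 0.9])

    def test_uniform_sample_quartiles_approach_theory(self):
        rng = np.random.default_rng(123)
        scale = derive_grade_scale(rng.uniform(0, 1, 20000))
        np.testing.assert_allclose(scale.cutoffs, (0.25, 0.5, 0.75), atol=0.02)
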
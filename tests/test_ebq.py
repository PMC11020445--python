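"""EBQ measurement geometry and the rater reconciliation rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebqspine import (CsfRegion, EndplateAnnotation, Image2D, RaterPanel,
                      RegionMask, compute_ebq, extract_band, mask_mean,
                      polygon_mask, reconcile)
from ebqspine.ebq import ReconciliationError, UnmeasurableROIError
from oracles import brute_force_band, brute_force_tube


def _ann(polyline, hint, level="C5/6", role="upper_endplate"):
    return EndplateAnnotation(level=level, role=role,
                              polyline_mm=np.asarray(polyline, float),
                              body_side_hint_mm=np.asarray(hint, float))


class TestExtractBand:
    def test_flat_band_area_is_depth_times_length(self, flat_image):
        """A 10 mm endplate with a 3 mm band at 0.5 mm spacing covers
        120 pixels (6 rows x 20 columns), with no end caps."""
        ann = _ann([(5, 10), (15, 10)], (10, 12))
        mask = extract_band(flat_image, ann, 3.0)
        assert abs(mask.n_pixels - 120) <= 20  # within one pixel-row
        assert mask.n_pixels == 120  # exact for this axis-aligned layout
        assert np.array_equal(mask.mask, brute_force_band(flat_image, ann, 3.0))

    def test_depth_smaller_than_center_offset_is_empty(self, flat_image):
        # polyline on a pixel boundary: nearest centres sit 0.25 mm away
        ann = _ann([(2, 1.0), (18, 1.0)], (10, 3))
        with pytest.raises(UnmeasurableROIError):
            extract_band(flat_image, ann, 0.25)

    def test_hint_reflection_partitions_the_tube(self, flat_image):
        below = _ann([(5, 10), (15, 10)], (10, 12))
        above = _ann([(5, 10), (15, 10)], (10, 8))
        m_below = extract_band(flat_image, below, 3.0).mask
        m_above = extract_band(flat_image, above, 3.0).mask
        assert not (m_below & m_above).any()
        tube = brute_force_tube(flat_image, below.polyline_mm, 3.0)
        assert np.array_equal(m_below | m_above, tube)

    def test_polyline_outside_image_rejected(self, flat_image):
        ann = _ann([(5, 10), (25, 10)], (10, 12))
        with pytest.raises(ValueError, match="outside"):
            extract_band(flat_image, ann, 3.0)

    def test_curved_polyline_matches_oracle(self, flat_image):
        xs = np.linspace(4, 16, 17)
        ys = 10 + 1.2 * np.sin(np.pi * (xs - 4) / 12)
        ann = _ann(np.column_stack([xs, ys]), (10, 15))
        mask = extract_band(flat_image, ann, 2.5)
        assert np.array_equal(mask.mask, brute_force_band(flat_image, ann, 2.5))


class TestMaskMean:
    def test_constant_image(self, flat_image):
        img = Image2D(np.full((40, 40), 7.0), 0.5)
        roi = RegionMask(np.zeros((40, 40), bool) | (np.arange(40)[:, None] < 3))
        mean, n = mask_mean(img, roi)
        assert mean == 7.0 and n == 120

    def test_three_pixel_roi(self):
        px = np.zeros((2, 3))
        px[0] = [10, 20, 30]
        img = Image2D(px, 1.0)
        roi = np.zeros((2, 3), bool)
        roi[0] = True
        mean, n = mask_mean(img, RegionMask(roi))
        assert mean == 20.0 and n == 3

    def test_fully_excluded_roi_raises(self):
        img = Image2D(np.ones((4, 4)), 1.0)
        roi = RegionMask(np.ones((4, 4), bool))
        with pytest.raises(UnmeasurableROIError, match="after exclusion"):
            mask_mean(img, roi, exclusions=RegionMask(np.ones((4, 4), bool)))


def _handmade_case():
    """Image where the upper band mean is 120, lower 80, CSF 100."""
    px = np.ones((40, 40))
    px[4:10, 10:30] = 120.0   # centres y in (2, 5), x in (5, 15)
    px[14:20, 10:30] = 80.0   # centres y in (7, 10)
    px[32:38, 32:38] = 100.0  # centres inside [16, 19]^2
    img = Image2D(px, 0.5)
    upper = _ann([(5, 5), (15, 5)], (10, 3), role="upper_endplate")
    lower = _ann([(5, 7), (15, 7)], (10, 9), role="lower_endplate")
    csf = CsfRegion(np.array([(16, 16), (19, 16), (19, 19), (16, 19)], float))
    return img, upper, lower, csf


class TestComputeEbq:
    def test_mean_of_band_means_over_csf(self):
        img, upper, lower, csf = _handmade_case()
        m = compute_ebq(img, upper, lower, csf)
        assert (m.si_upper, m.si_lower, m.si_csf) == (120.0, 80.0, 100.0)
        assert m.ebq == pytest.approx(1.0, abs=1e-15)
        assert m.ebq_display == 1.0

    def test_scale_invariance(self):
        img, upper, lower, csf = _handmade_case()
        base = compute_ebq(img, upper, lower, csf).ebq
        scaled = compute_ebq(img.scaled(3.7), upper, lower, csf).ebq
        assert scaled == pytest.approx(base, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_property(self, c):
        img, upper, lower, csf = _handmade_case()
        base = compute_ebq(img, upper, lower, csf).ebq
        assert compute_ebq(img.scaled(c), upper, lower, csf).ebq == pytest.approx(
            base, rel=1e-9)

    def test_intensity_offset_changes_ebq(self):
        """Additive offsets are NOT normalized away (documented behaviour).

        Uses a case with EBQ != 1: at EBQ = 1 an offset cancels trivially.
        """
        img, upper, lower, csf = _handmade_case()
        px = img.pixels.copy()
        px[32:38, 32:38] = 50.0  # CSF mean 50 -> EBQ = 2
        img2 = Image2D(px, img.spacing_mm)
        base = compute_ebq(img2, upper, lower, csf).ebq
        assert base == pytest.approx(2.0, abs=1e-12)
        shifted = Image2D(px + 50.0, img.spacing_mm)
        assert compute_ebq(shifted, upper, lower, csf).ebq == pytest.approx(1.5, abs=1e-12)

    def test_pooled_option_weights_by_area(self):
        img, upper, lower, csf = _handmade_case()
        # equal band areas here: pooled equals the mean-of-means
        m1 = compute_ebq(img, upper, lower, csf)
        m2 = compute_ebq(img, upper, lower, csf, pooled=True)
        assert m2.ebq == pytest.approx(m1.ebq, rel=1e-12)

    def test_level_mismatch_rejected(self):
        img, upper, _, csf = _handmade_case()
        other = _ann([(5, 7), (15, 7)], (10, 9), level="C6/7", role="lower_endplate")
        with pytest.raises(ValueError, match="levels differ"):
            compute_ebq(img, upper, other, csf)


class TestReconcile:
    def test_concordant_pair_averages(self):
        final, used = reconcile(RaterPanel(measurements=[4.1, 4.3]))
        assert final == pytest.approx(4.2) and used is False

    def test_discordant_pair_uses_arbiter(self):
        final, used = reconcile(RaterPanel(measurements=[3.0, 5.5], arbiter=5.2))
        assert final == 5.2 and used is True

    def test_discordant_without_arbiter_raises(self):
        with pytest.raises(ReconciliationError, match="re-measurement"):
            reconcile(RaterPanel(measurements=[3.0, 5.5]))

    def test_boundary_discrepancy_counts_as_concordant(self):
        final, used = reconcile(RaterPanel(measurements=[3.0, 5.0]))
        assert final == 4.0 and used is False

    def test_panel_needs_two_measurements(self):
        with pytest.raises(ValueError, match="at least 2"):
            RaterPanel(measurements=[4.0])


class TestAnnotationValidation:
    def test_hint_on_polyline_rejected(self):
        with pytest.raises(ValueError, match="ambiguous|on the polyline"):
            _ann([(0, 5), (10, 5)], (5, 5))

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            _ann([(3, 3), (3, 3)], (5, 5))

    def test_csf_polygon_must_be_simple(self):
        bowtie = np.array([(0, 0), (2, 2), (2, 0), (0, 2)], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            CsfRegion(bowtie)
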
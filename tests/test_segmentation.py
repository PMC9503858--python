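import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from planardose import (
    body_mask,
    count_uptake_foci,
    nuf_curve,
    segment_compartments,
    select_plateau_threshold,
    select_segmentation_threshold,
    threshold_index,
)
from planardose.segmentation import NufCurve, threshold_from_index

from conftest import flood_fill_nuf


class TestThresholdIndex:
    @pytest.mark.parametrize(
        "c_thr,c_max,expected",
        [(100, 100, 0.0), (0, 100, 1.0), (25, 100, 0.75)],
    )
    def test_examples(self, c_thr, c_max, expected):
        assert threshold_index(c_thr, c_max) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            threshold_index(1, 0)
        with pytest.raises(ValueError):
            threshold_index(101, 100)

    def test_inversion(self):
        assert threshold_from_index(threshold_index(37.0, 200.0), 200.0) == pytest.approx(37.0)


class TestCountUptakeFoci:
    @pytest.mark.parametrize(
        "image,c_thr,expected",
        [
            ([[5, 0, 5]], 1, 2),
            ([[0, 0], [0, 0]], 0, 0),
            ([[5] * 3] * 3, 1, 1),
        ],
    )
    def test_examples(self, image, c_thr, expected):
        assert count_uptake_foci(np.array(image, dtype=float), c_thr) == expected

    def test_diagonal_connectivity_difference(self):
        img = np.array([[5.0, 0.0], [0.0, 5.0]])
        assert count_uptake_foci(img, 1, connectivity=8) == 1
        assert count_uptake_foci(img, 1, connectivity=4) == 2

    @given(
        img=arrays(np.float64, (7, 9), elements=st.integers(0, 5).map(float)),
        c_thr=st.integers(0, 4),
        conn=st.sampled_from([4, 8]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_flood_fill_oracle(self, img, c_thr, conn):
        """Labeling agrees with an explicit BFS flood fill on small images."""
        assert count_uptake_foci(img, c_thr, conn) == flood_fill_nuf(img, c_thr, conn)

    @given(
        img=arrays(np.float64, (6, 6), elements=st.integers(0, 3).map(float)),
        c_thr=st.integers(0, 2),
    )
    @settings(max_examples=60, deadline=None)
    def test_conn8_never_exceeds_conn4(self, img, c_thr):
        assert count_uptake_foci(img, c_thr, 8) <= count_uptake_foci(img, c_thr, 4)


class TestNufCurve:
    def two_focus_image(self):
        img = np.zeros((6, 6))
        img[1, 1] = 10.0
        img[4, 4] = 8.0
        return img

    def test_normalization(self):
        curve = nuf_curve(self.two_focus_image(), n_steps=50)
        assert curve.nnuf.max() == 1.0
        np.testing.assert_allclose(curve.nnuf, curve.nuf / curve.nuf.max())

    def test_two_separated_foci_plateau(self):
        """NUF = 2 at every ThI strictly between the peaks' gap (brute force)."""
        img = self.two_focus_image()
        curve = nuf_curve(img, n_steps=101)
        for thi, c_thr, nuf in zip(curve.thi, curve.c_thr, curve.nuf):
            assert nuf == flood_fill_nuf(img, c_thr)
            if 0.21 < thi < 0.99:  # c_thr strictly between 8 and 0
                assert nuf == 2

    def test_single_focus_nuf_at_most_one(self):
        img = np.zeros((5, 5))
        img[2, 2] = 7.0
        img[2, 3] = 6.0
        curve = nuf_curve(img, n_steps=40)
        assert set(np.unique(curve.nuf)) <= {0, 1}

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            nuf_curve(np.zeros((4, 4)))


class TestThresholdSelection:
    def test_cutoff_rule_examples(self):
        curve = NufCurve(
            thi=np.array([0.1, 0.2, 0.3]),
            c_thr=np.array([9.0, 8.0, 7.0]),
            nuf=np.array([1, 2, 4]),
            nnuf=np.array([0.25, 0.5, 1.0]),
        )
        assert select_segmentation_threshold(curve, 0.5) == (8.0, 0.2)
        assert select_segmentation_threshold(curve, 1.0) == (7.0, 0.3)
        assert select_segmentation_threshold(curve, 1e-9) == (9.0, 0.1)

    def test_cutoff_out_of_range(self):
        curve = NufCurve(
            thi=np.array([0.1, 0.2]), c_thr=np.array([2.0, 1.0]),
            nuf=np.array([1, 1]), nnuf=np.array([1.0, 1.0]),
        )
        with pytest.raises(ValueError):
            select_segmentation_threshold(curve, 0.0)

    def test_plateau_rule_lands_between_foci_and_background(self):
        img = np.zeros((16, 16))
        img[2:4, 2:4] = 100.0
        img[10:12, 10:12] = 90.0
        img[4:14, 4:9] = 5.0  # background patch
        curve = nuf_curve(img, n_steps=100)
        c_thr, _ = select_plateau_threshold(curve)
        assert 5.0 < c_thr < 90.0
        assert count_uptake_foci(img, c_thr) == 2


class TestSegmentCompartments:
    def fixture_image(self):
        """8x8 body with one 2x2 focus of value 50 on background 3."""
        img = np.zeros((8, 8))
        img[1:7, 1:7] = 3.0
        img[2:4, 2:4] = 50.0
        return img

    def test_masks_partition_body(self):
        img = self.fixture_image()
        seg = segment_compartments(img, 10.0)
        assert np.all(seg.high_mask <= seg.body_mask)
        np.testing.assert_array_equal(seg.low_mask, seg.body_mask & ~seg.high_mask)
        assert not np.any(seg.high_mask & seg.low_mask)

    def test_counts_conservation_and_focus_sum(self):
        img = self.fixture_image()
        seg = segment_compartments(img, 10.0, acquisition_duration_s=100.0)
        assert seg.counts_high == pytest.approx(4 * 50.0)  # hand-summed focus
        assert seg.counts_high + seg.counts_low == pytest.approx(img[seg.body_mask].sum())
        assert seg.cps_high == pytest.approx(2.0)
        assert len(seg.foci) == 1

    def test_threshold_at_cmax_empty_high(self):
        img = self.fixture_image()
        seg = segment_compartments(img, img.max())
        assert not seg.high_mask.any()
        np.testing.assert_array_equal(seg.low_mask, seg.body_mask)

    def test_zero_threshold_high_covers_positive_body(self):
        img = self.fixture_image()
        seg = segment_compartments(img, 0.0)
        np.testing.assert_array_equal(seg.high_mask, img > 0)

    def test_ties_fall_to_low(self):
        img = self.fixture_image()
        seg = segment_compartments(img, 3.0)  # ties the background value
        assert seg.counts_high == pytest.approx(200.0)
        assert not np.any(img[seg.high_mask] == 3.0)

    def test_skeletal_lesion_flagging(self):
        img = self.fixture_image()
        seg = segment_compartments(img, 10.0, skeletal_lesion_labels=[1])
        assert seg.foci[0].is_skeletal_lesion


class TestBodyMask:
    def test_uniform_image_full_frame(self):
        mask = body_mask(np.full((5, 5), 7.0), 0.0)
        assert mask.all()

    def test_zero_fraction_keeps_positive_pixels(self):
        img = np.zeros((6, 6))
        img[2:5, 2:5] = 4.0
        img[3, 3] = 0.0  # interior hole gets filled
        mask = body_mask(img, 0.0)
        assert mask[3, 3]
        np.testing.assert_array_equal(mask, np.pad(np.ones((3, 3), bool), ((2, 1), (2, 1))))

    def test_ellipse_phantom_support_covered(self):
        from planardose.phantom import PhantomSpec, generate_phantom_scan
        from planardose.imaging import geometric_mean_image

        scan, truth = generate_phantom_scan(PhantomSpec(noise="none"))
        gm = geometric_mean_image(scan)
        mask = body_mask(gm.values, 0.001)
        assert np.all(mask[truth.body_mask])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            body_mask(np.zeros((3, 3)), 0.0)
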
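"""Spot segmentation inside S and the accuracy/reproducibility metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexspot import (
    InvalidInputError,
    PairingError,
    UndefinedMetricError,
    agreement_metrics,
    center_distance_metrics,
    cv_spot,
    replicate_metrics,
    segment_spot,
    spot_intensity,
    spot_r2,
)
from hexspot.localize import SpotRecord


def _record(area, center=None, radii=(7.0, 7.0)):
    x0, y0, x1, y1 = area
    if center is None:
        center = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
    return SpotRecord(
        line=1, col=1, parity="even", center=center, radii=radii, area=area
    )


def _disk_image(radius=7, amplitude=1000.0, background=100.0, size=28):
    img = np.full((size, size), background)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius ** 2
    img[mask] += amplitude
    return img, mask


class TestSegmentSpot:
    def test_ideal_disk_iou(self):
        img, true_mask = _disk_image()
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        inter = (rec.fg_mask & true_mask).sum()
        union = (rec.fg_mask | true_mask).sum()
        assert inter / union >= 0.90
        assert not rec.missing

    def test_flat_area_marked_missing(self):
        rec = segment_spot(np.full((30, 30), 55.0), _record((2, 2, 22, 22)))
        assert rec.missing
        assert not rec.fg_mask.any()
        assert rec.bg_mask.all()

    def test_only_central_component_kept(self):
        img = np.full((28, 28), 100.0)
        yy, xx = np.mgrid[0:28, 0:28]
        central = (yy - 14) ** 2 + (xx - 14) ** 2 <= 16
        corner = (yy - 2) ** 2 + (xx - 2) ** 2 <= 4
        img[central] = 1000.0
        img[corner] = 1000.0
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        assert rec.fg_mask[14, 14]
        assert not rec.fg_mask[2, 2]

    def test_masks_partition_area(self, pipeline_run):
        for rec in pipeline_run.records[:40]:
            x0, y0, x1, y1 = rec.area
            assert rec.fg_mask.shape == (y1 - y0, x1 - x0)
            assert not (rec.fg_mask & rec.bg_mask).any()
            assert (rec.fg_mask | rec.bg_mask).all()

    def test_empty_area_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_spot(np.ones((10, 10)), _record((5, 5, 5, 9), center=(5.0, 6.0)))


class TestSpotIntensity:
    def test_background_subtraction(self):
        img, mask = _disk_image(amplitude=800.0, background=200.0)
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        assert spot_intensity(img, rec) == pytest.approx(800.0, abs=1.0)

    def test_equal_foreground_background_gives_zero(self):
        img, _ = _disk_image(amplitude=500.0)
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        flat = np.full_like(img, 300.0)
        assert spot_intensity(flat, rec) == 0.0

    def test_shift_invariance(self):
        img, _ = _disk_image(amplitude=700.0, background=150.0)
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        base = spot_intensity(img, rec)
        shifted = spot_intensity(img + 1234.0, rec)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_requires_masks(self):
        with pytest.raises(InvalidInputError):
            spot_intensity(np.ones((20, 20)), _record((0, 0, 20, 20)))


class TestSpotR2:
    def test_exact_gaussian_model_gives_one(self):
        yy, xx = np.mgrid[0:28, 0:28]
        img = 100.0 + 900.0 * np.exp(-((xx - 14) ** 2 + (yy - 14) ** 2) / (2 * 4.0 ** 2))
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        assert spot_r2(img, rec) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_gives_low_r2(self, rng):
        scores = []
        for _ in range(50):
            img = rng.normal(1000.0, 50.0, size=(14, 14))
            img -= img.min() - 1.0
            rec = _record((0, 0, 14, 14))
            rec.fg_mask = np.ones((14, 14), dtype=bool)
            rec.bg_mask = ~rec.fg_mask
            scores.append(spot_r2(img, rec))
        assert np.mean(scores) < 0.1

    def test_constant_area_gives_zero(self):
        rec = _record((0, 0, 14, 14))
        rec.fg_mask = np.ones((14, 14), dtype=bool)
        rec.bg_mask = ~rec.fg_mask
        assert spot_r2(np.full((14, 14), 9.0), rec) == 0.0


class TestCV:
    def test_constant_spot_zero(self):
        img, _ = _disk_image(amplitude=600.0)
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        assert cv_spot(img, rec) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ratio(self):
        img = np.full((4, 4), 0.0)
        img[1:3, 1:3] = [[2.0, 6.0], [2.0, 6.0]]
        rec = _record((0, 0, 4, 4), center=(1.5, 1.5))
        rec.fg_mask = np.zeros((4, 4), dtype=bool)
        rec.fg_mask[1:3, 1:3] = True
        rec.bg_mask = ~rec.fg_mask
        # fg - bg_mean(0) = [2,6,2,6]: sigma=2, nu=4
        assert cv_spot(img, rec) == pytest.approx(0.5)

    @given(st.floats(min_value=0.1, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        img, _ = _disk_image(amplitude=500.0, background=100.0)
        yy, xx = np.mgrid[0:28, 0:28]
        img = img + 5.0 * np.sin(xx / 3.0)  # non-constant foreground
        rec = segment_spot(img, _record((0, 0, 28, 28)))
        assert cv_spot(img * c, rec) == pytest.approx(cv_spot(img, rec), rel=1e-9)

    def test_zero_mean_undefined(self):
        img = np.zeros((6, 6))
        rec = _record((0, 0, 6, 6), center=(3.0, 3.0))
        rec.fg_mask = np.zeros((6, 6), dtype=bool)
        rec.fg_mask[2:4, 2:4] = True
        rec.bg_mask = ~rec.fg_mask
        with pytest.raises(UndefinedMetricError):
            cv_spot(img, rec)


class TestCenterDistanceMetrics:
    def test_identical_lists(self):
        pts = np.array([[1.0, 2.0], [5.0, 9.0]])
        mE, std, acc = center_distance_metrics(pts, pts, spot_diameter=14)
        assert mE == 0.0 and std == 0.0 and acc == 100.0

    def test_three_four_five_offset(self):
        det = np.array([[3.0, 4.0], [0.0, 0.0]])
        ref = np.zeros((2, 2))
        mE, std, acc = center_distance_metrics(det, ref, spot_diameter=14)
        assert mE == pytest.approx(2.5)
        assert std == pytest.approx(2.5)
        assert acc == 100.0

    def test_accuracy_counts_half_diameter(self):
        det = np.array([[8.0, 0.0], [0.0, 0.0]])
        ref = np.zeros((2, 2))
        _, _, acc = center_distance_metrics(det, ref, spot_diameter=14)
        assert acc == 50.0

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            center_distance_metrics(np.zeros((3, 2)), np.zeros((2, 2)), 14)


class TestReplicateMetrics:
    def test_identical_replicates_zero(self):
        table = np.tile(np.array([[5.0], [9.0]]), (1, 4))
        mae, avg = replicate_metrics(table)
        assert np.allclose(mae, 0.0) and avg == 0.0

    def test_hand_example(self):
        mae, avg = replicate_metrics(np.array([[8.0, 12.0]]))
        assert mae[0] == pytest.approx(2.0) and avg == pytest.approx(2.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidInputError):
            replicate_metrics(np.array([[1.0], [2.0]]))

    @given(
        st.lists(
            st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_mae_nonnegative(self, rows):
        mae, avg = replicate_metrics(np.array(rows))
        assert (mae >= 0).all() and avg >= 0


class TestAgreementMetrics:
    def test_identical_vectors(self):
        r, avgdiff = agreement_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert r == pytest.approx(1.0) and avgdiff == 0.0

    def test_anti_correlated(self):
        r, avgdiff = agreement_metrics([0.0, 1.0], [1.0, 0.0])
        assert r == pytest.approx(-1.0) and avgdiff == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            agreement_metrics([0.5, 0.5], [0.1, 0.9])

    def test_r2_agreement_with_true_model_reference(self, hex_case, pipeline_run):
        """Fitted-model R² tracks the R² against the true generator model."""
        cfg, _, truth = hex_case
        sigma = cfg.spot_diameter / (2 * np.sqrt(2 * np.log(2)))
        raw = pipeline_run.corrected_raw
        ours, refs = [], []
        for rec in pipeline_run.records:
            if rec.missing:
                continue
            row = truth.spots[
                (truth.spots.line == rec.line) & (truth.spots.col == rec.col)
            ].iloc[0]
            x0, y0, x1, y1 = rec.area
            yy, xx = np.mgrid[y0:y1, x0:x1]
            model = row.amplitude * np.exp(
                -((xx - row.x) ** 2 + (yy - row.y) ** 2) / (2 * sigma ** 2)
            )
            r = np.corrcoef(raw[y0:y1, x0:x1].ravel(), model.ravel())[0, 1]
            refs.append(np.clip(r, 0, 1) ** 2)
            ours.append(rec.r2)
        r, avgdiff = agreement_metrics(np.array(ours), np.array(refs))
        assert len(ours) >= 140
        assert r >= 0.98
        assert avgdiff < 0.01
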
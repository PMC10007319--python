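"""Line-band detection and decomposition into parity sub-images."""

import numpy as np
import pytest

from hexspot import (
    InvalidInputError,
    NoStructureError,
    PatternError,
    SpotGeometry,
    SyntheticConfig,
    decompose,
    detect_line_bands,
    elliptical_se,
    extract_parity_subimage,
    generate_hex_microarray,
)
from hexspot.pipeline import PipelineConfig, preprocess_image

from oracles import grey_opening


class TestEllipticalSE:
    def test_unit_radii_give_plus_shape(self):
        se = elliptical_se(1, 1)
        expected = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        np.testing.assert_array_equal(se, expected)

    @pytest.mark.parametrize("r", [2, 3, 5])
    def test_equal_radii_give_disk(self, r):
        se = elliptical_se(r, r)
        y, x = np.mgrid[-r:r + 1, -r:r + 1]
        np.testing.assert_array_equal(se, x ** 2 + y ** 2 <= r ** 2)

    def test_transpose_symmetry(self):
        np.testing.assert_array_equal(elliptical_se(4, 2), elliptical_se(2, 4).T)

    def test_invalid_radii(self):
        with pytest.raises(InvalidInputError):
            elliptical_se(0, 3)


class TestDetectLineBands:
    def test_hand_worked_pattern(self):
        """Four interleaved line pairs: uneven u=1 spans neighbour centres 42..102."""
        pos = [10, 14, 40, 44, 70, 74, 100, 104]
        bands = detect_line_bands(pos)
        assert len(bands) == 4
        by = {(b.parity, b.index): b for b in bands}
        band = by[("uneven", 1)]
        assert (band.top, band.bottom) == (42, 102)
        assert band.center == pytest.approx(72.0)
        # parities alternate with row order
        assert [b.parity for b in bands] == ["uneven", "even", "uneven", "even"]

    def test_too_few_inflexions(self):
        with pytest.raises(NoStructureError):
            detect_line_bands([10, 14, 40])

    def test_irregular_spacing_rejected(self):
        with pytest.raises(PatternError):
            detect_line_bands([10, 14, 40, 44, 45, 49, 140, 144])

    def test_bands_of_equal_parity_are_disjoint(self):
        pos = np.array([10, 14, 40, 44, 70, 74, 100, 104, 130, 134, 160, 164])
        bands = detect_line_bands(pos)
        for parity in ("even", "uneven"):
            fam = sorted((b for b in bands if b.parity == parity), key=lambda b: b.top)
            for first, second in zip(fam[:-1], fam[1:]):
                assert first.bottom <= second.top


class TestExtractParitySubimage:
    def _fixture(self):
        """Full disk centred in the band, half disks cut at the band edges."""
        img = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        for cy in (10, 30, 50):
            img[(yy - cy) ** 2 + (xx - 30) ** 2 <= 25] = 100.0
        from hexspot.grid import LineBand

        band = LineBand(parity="uneven", index=1, top=10, bottom=50, center=30.0)
        geom = SpotGeometry(a=5, b=5, pitch_x=20, pitch_y=20)
        return img, band, geom

    def test_keeps_full_spot_suppresses_half_spots(self):
        img, band, geom = self._fixture()
        out = extract_parity_subimage(img, [band], geom)
        # the centred disk survives the opening unchanged (flat disk = SE)
        assert out[30, 30] == 100.0
        assert out[28:33, 28:33].min() >= 90.0
        # half-spots at the band edges are suppressed below 10% amplitude
        assert out[12, 30] <= 10.0
        assert out[48, 30] <= 10.0

    def test_matches_bruteforce_opening_of_padded_strip(self):
        img, band, geom = self._fixture()
        out = extract_parity_subimage(img, [band], geom)
        pad = 3  # ceil(b/2)
        strip = img[10:50]
        padded = np.zeros((strip.shape[0] + 2 * pad, strip.shape[1]))
        padded[pad:-pad] = strip
        oracle = np.asarray(grey_opening(padded.tolist(), 5, 5))[pad:-pad]
        np.testing.assert_allclose(out[10:50], oracle)

    def test_constant_image_returns_minimum(self):
        from hexspot.grid import LineBand

        img = np.full((40, 40), 5.0)
        band = LineBand(parity="even", index=1, top=5, bottom=35, center=20.0)
        out = extract_parity_subimage(img, [band], SpotGeometry(3, 3, 10, 10))
        assert np.allclose(out, 5.0)

    def test_band_outside_image_rejected(self):
        from hexspot.grid import LineBand

        img = np.ones((20, 20))
        band = LineBand(parity="even", index=1, top=30, bottom=40, center=35.0)
        with pytest.raises(InvalidInputError):
            extract_parity_subimage(img, [band], SpotGeometry(2, 2, 8, 8))

    def test_anti_extensive(self):
        img, band, geom = self._fixture()
        out = extract_parity_subimage(img, [band], geom)
        assert np.all(out <= img + 1e-9)


@pytest.fixture(scope="module")
def preprocessed(hex_case):
    _, image, _ = hex_case
    pre, _, _, _ = preprocess_image(image, PipelineConfig(rotation_correction=False))
    return pre


class TestDecompose:
    def test_line_count_and_band_parities(self, preprocessed):
        dec = decompose(preprocessed)
        assert dec.n_lines == 8
        assert dec.layout == "hexagonal"
        assert sum(b.parity == "even" for b in dec.bands) == 4
        assert sum(b.parity == "uneven" for b in dec.bands) == 4

    def test_band_centers_match_truth_lines(self, preprocessed, hex_case):
        _, _, truth = hex_case
        dec = decompose(preprocessed)
        truth_ys = sorted(truth.spots.y.unique())
        centers = sorted(b.center for b in dec.bands)
        np.testing.assert_allclose(centers, truth_ys, atol=1.0)

    def test_each_band_holds_one_truth_line_of_its_parity(self, preprocessed, hex_case):
        _, _, truth = hex_case
        dec = decompose(preprocessed)
        for k, band in enumerate(sorted(dec.bands, key=lambda b: b.center), start=1):
            line = truth.spots[truth.spots.line == k]
            assert band.parity == line.parity.iloc[0]
            y = line.y.iloc[0]
            assert band.top <= y <= band.bottom

    def test_superposition_covers_truth_spots(self, preprocessed, hex_case):
        _, _, truth = hex_case
        dec = decompose(preprocessed)
        mx = np.maximum(dec.I_ev, dec.I_uev)
        med = float(np.median(mx))
        rng = float(mx.max() - med)
        for row in truth.spots.itertuples():
            if row.missing:
                continue
            cy, cx = int(row.y), int(row.x)
            core = mx[cy - 1:cy + 2, cx - 1:cx + 2].mean()
            assert core > med + 0.02 * rng

    def test_estimated_geometry_close_to_truth(self, preprocessed):
        geom = decompose(preprocessed).geometry
        assert geom.pitch_x == pytest.approx(28, abs=1)
        assert geom.pitch_y == pytest.approx(28, abs=1)
        assert geom.a == pytest.approx(7, abs=2)
        assert geom.b == pytest.approx(7, abs=2)

    def test_rectangular_grid_single_family(self):
        image, _ = generate_hex_microarray(SyntheticConfig(seed=5, hex_offset=0.0))
        pre, _, _, _ = preprocess_image(image, PipelineConfig(rotation_correction=False))
        dec = decompose(pre)
        assert dec.layout == "rectangular"
        assert all(b.parity == "even" for b in dec.bands)
        assert np.allclose(dec.I_uev, dec.I_uev.min())

    def test_constant_image_rejected(self):
        with pytest.raises(NoStructureError):
            decompose(np.full((100, 100), 3.0))
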
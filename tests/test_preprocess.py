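"""Image preprocessing: Bruch detection, flattening, ILM tracing, scaling."""

import dataclasses

import numpy as np
import pytest

import foveometrics as fm
from foveometrics.errors import (
    CorrectionLookupError,
    InsufficientContextError,
    SegmentationError,
)


def _bscan(truth, geometry, **kw):
    return fm.gen_bscan(truth, geometry, **kw)


@pytest.fixture(scope="module")
def clean_scan(sym_truth, small_geometry):
    return _bscan(sym_truth, small_geometry)


@pytest.fixture(scope="module")
def speckled_scan(sym_truth, small_geometry):
    truth = dataclasses.replace(sym_truth, seed=3)
    return _bscan(truth, small_geometry, speckle_sd=0.15)


class TestDetectBruch:
    def test_noise_off_within_one_pixel_everywhere(self, clean_scan):
        image, truth = clean_scan
        rows, failed = fm.detect_bruch(image)
        assert not failed.any()
        assert np.all(np.abs(rows - truth.bruch_rows) <= 1.0)

    def test_uniform_image_raises(self):
        img = fm.BScanImage(data=np.full((64, 64), 50.0),
                            axial_um_per_px=4.0, lateral_um_per_px=20.0)
        with pytest.raises(SegmentationError):
            fm.detect_bruch(img)

    def test_speckle_95_percent_within_two_pixels(self, speckled_scan):
        image, truth = speckled_scan
        rows, _ = fm.detect_bruch(image)
        assert np.mean(np.abs(rows - truth.bruch_rows) <= 2.0) >= 0.95

    def test_tilted_bruch_follows_ramp(self, sym_truth, small_geometry):
        geo = dataclasses.replace(small_geometry, bruch_tilt_px=30.0)
        image, truth = _bscan(sym_truth, geo)
        rows, _ = fm.detect_bruch(image)
        assert np.all(np.abs(rows - truth.bruch_rows) <= 1.5)


class TestFlatten:
    def test_already_flat_is_identity(self, clean_scan):
        image, truth = clean_scan
        ref = int(round(truth.bruch_rows[0]))
        flat, shifts = fm.flatten_bscan(image, np.full(image.n_cols, float(ref)), ref)
        assert np.array_equal(flat.data, image.data)
        assert np.all(shifts == 0)

    def test_constant_offset_shifts_every_column_equally(self, clean_scan):
        image, truth = clean_scan
        ref = int(round(truth.bruch_rows[0]))
        bruch = np.full(image.n_cols, float(ref + 5))
        flat, shifts = fm.flatten_bscan(image, bruch, ref)
        assert np.all(shifts == -5)
        assert np.array_equal(flat.data[:-5], image.data[5:])

    def test_linear_ramp_flattens_to_constant(self, sym_truth, small_geometry):
        geo = dataclasses.replace(small_geometry, bruch_tilt_px=30.0)
        image, _ = _bscan(sym_truth, geo)
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        re_bruch, _ = fm.detect_bruch(flat)
        assert re_bruch.max() - re_bruch.min() <= 1.0 + 1.0  # +-1 px quantization

    def test_flatten_is_idempotent(self, clean_scan):
        image, _ = clean_scan
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        b2, _ = fm.detect_bruch(flat)
        flat2, shifts2 = fm.flatten_bscan(flat, b2, ref)
        assert np.max(np.abs(shifts2)) <= 1


class TestSegmentILM:
    def test_noise_off_rmse_below_one_pixel(self, clean_scan):
        image, truth = clean_scan
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        prof = fm.segment_ilm(flat, ref)
        h_true = truth.bruch_rows - truth.ilm_rows
        assert np.sqrt(np.mean((prof.h - h_true) ** 2)) <= 1.0

    def test_speckle_rmse_below_two_pixels(self, speckled_scan):
        image, truth = speckled_scan
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        prof = fm.segment_ilm(flat, ref)
        h_true = truth.bruch_rows - truth.ilm_rows
        assert np.sqrt(np.mean((prof.h - h_true) ** 2)) <= 2.0

    def test_flat_contour_traced_flat(self, small_geometry):
        truth = fm.ProfileTruth(
            baseline_height=200.0,
            nasal=fm.SideTruth(1e-6, 4000.0, 1e-9, 5000.0),
            temporal=fm.SideTruth(1e-6, 4000.0, 1e-9, 5000.0),
            noise_sd=0.0,
        )
        image, _ = _bscan(truth, small_geometry)
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        prof = fm.segment_ilm(flat, ref)
        assert prof.h.max() - prof.h.min() <= 1.0

    def test_dark_image_raises(self):
        img = fm.BScanImage(data=np.full((64, 64), 10.0),
                            axial_um_per_px=4.0, lateral_um_per_px=20.0)
        with pytest.raises(SegmentationError):
            fm.segment_ilm(img, reference_row=50)

    def test_override_corrections_applied(self, clean_scan):
        image, _ = clean_scan
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        prof = fm.segment_ilm(flat, ref, overrides=[(10, ref - 42.0)])
        assert prof.h[10] == pytest.approx(42.0)


class TestSelectFovealBscan:
    def _volume(self, deepest_at, n_slices, geometry):
        vol = []
        for i in range(n_slices):
            depth = 1.0 - 0.04 * abs(i - deepest_at)
            t = fm.ProfileTruth(
                noise_sd=0.0,
                nasal=fm.SideTruth(120.0 * depth, 400.0, 60.0, 1500.0),
                temporal=fm.SideTruth(120.0 * depth, 400.0, 60.0, 1500.0),
            )
            img, _ = fm.gen_bscan(t, geometry)
            vol.append(img)
        return vol

    def test_selects_known_deepest_slice(self, small_geometry):
        vol = self._volume(deepest_at=10, n_slices=21, geometry=small_geometry)
        assert fm.select_foveal_bscan(vol) == 10

    def test_candidate_near_edge_raises(self, small_geometry):
        vol = self._volume(deepest_at=2, n_slices=15, geometry=small_geometry)
        with pytest.raises(InsufficientContextError):
            fm.select_foveal_bscan(vol)

    def test_tie_broken_toward_center(self, small_geometry):
        vol = self._volume(deepest_at=8, n_slices=21, geometry=small_geometry)
        # duplicate the deepest slice away from the centre: 8 and 14 tie;
        # 8 is closer to the central slice 10
        vol[14] = vol[8]
        assert fm.select_foveal_bscan(vol) == 8

    def test_too_few_slices_raises(self, small_geometry):
        vol = self._volume(deepest_at=3, n_slices=7, geometry=small_geometry)
        with pytest.raises(InsufficientContextError):
            fm.select_foveal_bscan(vol)


class TestToMicrometers:
    def _pixel_profile(self, clean_scan):
        image, _ = clean_scan
        bruch, _ = fm.detect_bruch(image)
        ref = int(round(np.median(bruch)))
        flat, _ = fm.flatten_bscan(image, bruch, ref)
        return fm.segment_ilm(flat, ref)

    def test_identity_correction_spacing_equals_lateral_scale(self, clean_scan):
        prof_px = self._pixel_profile(clean_scan)
        prof = fm.to_micrometers(prof_px, lateral_correction=1.0)
        spacing = np.diff(prof.x)
        assert np.allclose(spacing, clean_scan[0].lateral_um_per_px)

    def test_half_correction_halves_widths(self, clean_scan):
        prof_px = self._pixel_profile(clean_scan)
        p1 = fm.to_micrometers(prof_px, lateral_correction=1.0)
        p2 = fm.to_micrometers(prof_px, lateral_correction=0.5)
        w1 = fm.DoGModel(p1).fit().metrics().width
        w2 = fm.DoGModel(p2).fit().metrics().width
        assert w2 == pytest.approx(0.5 * w1, rel=1e-2)

    def test_pit_centered_at_zero(self, clean_scan):
        prof = fm.to_micrometers(self._pixel_profile(clean_scan))
        i0 = np.argmin(np.abs(prof.x))
        # one sample at or adjacent to x = 0
        assert abs(prof.x[i0]) <= prof.spacing

    def test_missing_correction_entry_raises(self):
        table = fm.CorrectionTable({(36, 28): 0.85})
        assert table.lookup(36.2, 27.9) == pytest.approx(0.85)
        with pytest.raises(CorrectionLookupError):
            table.lookup(40, 24)
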
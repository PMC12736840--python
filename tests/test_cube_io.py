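"""Cube container, ENVI round trips, interleave layouts and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import peelscan as ps
from peelscan.exceptions import (
    CalibrationError,
    CubeIntegrityError,
    EnviFormatError,
    GeometryMismatchError,
    ParameterError,
)


def _make_cube(shape=(3, 4, 5), dtype=np.float32, calibrated=False, seed=0):
    rng = np.random.default_rng(seed)
    if np.issubdtype(dtype, np.integer):
        data = rng.integers(0, 4000, size=shape).astype(dtype)
    else:
        data = rng.random(shape).astype(dtype)
    wl = 400.0 + 10.0 * np.arange(shape[2])
    return ps.HyperspectralCube(data=data, wavelengths_nm=wl, is_calibrated=calibrated)


class TestCubeValidation:
    def test_wavelength_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ps.HyperspectralCube(data=np.zeros((2, 2, 4)), wavelengths_nm=[400, 500, 600])

    def test_non_increasing_wavelengths_rejected(self):
        with pytest.raises(ParameterError):
            ps.HyperspectralCube(data=np.zeros((2, 2, 2)), wavelengths_nm=[500, 400])

    def test_calibrated_cube_must_lie_in_unit_interval(self):
        with pytest.raises(ParameterError):
            ps.HyperspectralCube(
                data=np.full((1, 1, 1), 1.5), wavelengths_nm=[500.0], is_calibrated=True
            )

    def test_zero_band_cube_rejected(self):
        with pytest.raises(ParameterError):
            ps.HyperspectralCube(data=np.zeros((2, 2, 0)), wavelengths_nm=[])


class TestEnviIO:
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.uint16, np.uint8])
    def test_write_read_roundtrip(self, tmp_path, dtype):
        cube = _make_cube(dtype=dtype)
        ps.write_envi_cube(cube, tmp_path / "cube.hdr")
        back = ps.read_envi_cube(tmp_path / "cube.hdr")
        assert back.data.dtype == np.dtype(dtype)
        assert np.array_equal(back.data, cube.data)
        assert np.allclose(back.wavelengths_nm, cube.wavelengths_nm)
        assert back.is_calibrated == cube.is_calibrated

    def test_calibrated_flag_roundtrips(self, tmp_path):
        cube = _make_cube(calibrated=True)
        ps.write_envi_cube(cube, tmp_path / "cal.hdr")
        assert ps.read_envi_cube(tmp_path / "cal.hdr").is_calibrated

    def test_single_band_cube_roundtrips(self, tmp_path):
        cube = ps.HyperspectralCube(data=np.ones((2, 3, 1), np.float32), wavelengths_nm=[592.0])
        ps.write_envi_cube(cube, tmp_path / "one.hdr")
        assert np.array_equal(ps.read_envi_cube(tmp_path / "one.hdr").data, cube.data)

    @pytest.mark.parametrize("interleave", ["bil", "bip"])
    def test_interleave_layouts_match_index_arithmetic(self, tmp_path, tiny_cube, interleave):
        """A hand-enumerated 12-value cube stored as BIL/BIP reads back identically.

        Oracle: explicit index arithmetic.  BIL stores value (r, c, b) at flat
        position r*B*W + b*W + c; BIP at r*W*B + c*B + b.
        """
        h, w, b = tiny_cube.data.shape
        flat = np.empty(h * w * b, dtype=np.float32)
        for r in range(h):
            for c in range(w):
                for k in range(b):
                    if interleave == "bil":
                        pos = r * b * w + k * w + c
                    else:
                        pos = r * w * b + c * b + k
                    flat[pos] = tiny_cube.data[r, c, k]
        (tmp_path / "cube.img").write_bytes(flat.tobytes())
        header = (
            "ENVI\nsamples = 2\nlines = 2\nbands = 3\nheader offset = 0\n"
            f"data type = 4\ninterleave = {interleave}\nbyte order = 0\n"
            "wavelength = {400, 500, 600}\n"
        )
        (tmp_path / "cube.hdr").write_text(header)
        back = ps.read_envi_cube(tmp_path / "cube.hdr")
        assert np.array_equal(back.data, tiny_cube.data)

    def test_wavelength_count_mismatch_is_format_error(self, tmp_path):
        (tmp_path / "bad.img").write_bytes(b"\x00" * 4 * 4)
        (tmp_path / "bad.hdr").write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 4\ndata type = 1\n"
            "interleave = bsq\nwavelength = {400, 500, 600}\n"
        )
        with pytest.raises(EnviFormatError, match="wavelength"):
            ps.read_envi_cube(tmp_path / "bad.hdr")

    def test_missing_required_field_names_it(self, tmp_path):
        (tmp_path / "bad.img").write_bytes(b"\x00" * 8)
        (tmp_path / "bad.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 1\ndata type = 1\nwavelength = {400}\n"
        )
        with pytest.raises(EnviFormatError, match="bands"):
            ps.read_envi_cube(tmp_path / "bad.hdr")

    def test_payload_size_mismatch_is_integrity_error(self, tmp_path):
        cube = _make_cube()
        ps.write_envi_cube(cube, tmp_path / "cube.hdr")
        binary = tmp_path / "cube.img"
        binary.write_bytes(binary.read_bytes()[:-4])
        with pytest.raises(CubeIntegrityError):
            ps.read_envi_cube(tmp_path / "cube.hdr")


class TestCalibration:
    @staticmethod
    def _refs(shape=(2, 3, 4), white=4000.0, dark=100.0):
        wl = 400.0 + 10 * np.arange(shape[2])
        mk = lambda v: ps.HyperspectralCube(np.full(shape, v, np.float64), wl)
        return ps.ReferencePair(white=mk(white), dark=mk(dark)), wl

    def test_white_maps_to_one_dark_to_zero_midpoint_to_half(self):
        refs, wl = self._refs()
        for raw_val, expected in [(4000.0, 1.0), (100.0, 0.0), (2050.0, 0.5)]:
            raw = ps.HyperspectralCube(np.full((2, 3, 4), raw_val), wl)
            cal = ps.calibrate_reflectance(raw, refs)
            assert np.allclose(cal.data, expected, atol=1e-12)
            assert cal.is_calibrated

    @settings(derandomize=True, max_examples=40)
    @given(alpha=st.floats(0.0, 1.0, allow_nan=False))
    def test_linearity_recovers_alpha(self, alpha):
        """raw = B + alpha * (W - B) calibrates to alpha everywhere."""
        refs, wl = self._refs()
        raw = ps.HyperspectralCube(np.full((2, 3, 4), 100.0 + alpha * 3900.0), wl)
        cal = ps.calibrate_reflectance(raw, refs)
        assert np.allclose(cal.data, alpha, atol=1e-12)

    def test_already_calibrated_refused(self):
        refs, wl = self._refs()
        cal = ps.HyperspectralCube(np.zeros((2, 3, 4)), wl, is_calibrated=True)
        with pytest.raises(CalibrationError):
            ps.calibrate_reflectance(cal, refs)

    def test_output_clipped_to_unit_interval(self):
        refs, wl = self._refs()
        raw = ps.HyperspectralCube(np.full((2, 3, 4), 9000.0), wl)  # specular
        assert ps.calibrate_reflectance(raw, refs).data.max() == 1.0

    def test_dead_sites_zeroed_and_tallied(self):
        wl = np.array([500.0])
        white = np.full((2, 2, 1), 4000.0)
        white[0, 0, 0] = 50.0  # below dark
        with pytest.warns(UserWarning, match="white < dark"):
            refs = ps.ReferencePair(
                white=ps.HyperspectralCube(white, wl),
                dark=ps.HyperspectralCube(np.full((2, 2, 1), 100.0), wl),
            )
        raw = ps.HyperspectralCube(np.full((2, 2, 1), 2050.0), wl)
        cal = ps.calibrate_reflectance(raw, refs)
        assert cal.data[0, 0, 0] == 0.0
        assert cal.meta["n_invalid"] == 1

    def test_single_row_references_broadcast_along_rows(self):
        wl = 400.0 + 10 * np.arange(3)
        refs = ps.ReferencePair(
            white=ps.HyperspectralCube(np.full((1, 4, 3), 4000.0), wl),
            dark=ps.HyperspectralCube(np.full((1, 4, 3), 100.0), wl),
        )
        raw = ps.HyperspectralCube(np.full((6, 4, 3), 2050.0), wl)
        assert np.allclose(ps.calibrate_reflectance(raw, refs).data, 0.5, atol=1e-12)

    def test_geometry_mismatch_rejected(self):
        refs, _ = self._refs(shape=(2, 3, 4))
        raw = ps.HyperspectralCube(np.zeros((2, 5, 4)), 400.0 + 10 * np.arange(4))
        with pytest.raises(GeometryMismatchError):
            ps.calibrate_reflectance(raw, refs)


class TestWavelengthLookup:
    def test_nearest_band(self):
        cube = ps.HyperspectralCube(np.zeros((1, 1, 3)), [390.0, 400.0, 410.0])
        assert ps.wavelength_to_band(cube, 401.0) == 1

    def test_exact_midpoint_ties_to_lower_index(self):
        cube = ps.HyperspectralCube(np.zeros((1, 1, 2)), [390.0, 400.0])
        assert ps.wavelength_to_band(cube, 395.0) == 0

    def test_out_of_range_rejected(self):
        cube = ps.HyperspectralCube(np.zeros((1, 1, 2)), [390.0, 400.0])
        with pytest.raises(ParameterError):
            ps.wavelength_to_band(cube, 300.0)

    def test_half_spacing_margin_accepted_at_edges(self):
        cube = ps.HyperspectralCube(np.zeros((1, 1, 3)), [390.0, 400.0, 410.0])
        assert ps.wavelength_to_band(cube, 385.5) == 0
        assert ps.wavelength_to_band(cube, 414.5) == 2
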
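"""Cube I/O, black/white reflectance correction and ROI extraction."""

import numpy as np
import pytest

from teaspec import SpectralAxis
from teaspec.cube_io import (HyperspectralCube, build_spectrum_matrix,
                             correct_reflectance, extract_roi_mean, read_cube,
                             write_cube)

DN_MAX = 65552


def _cube(fill, shape=(2, 2, 3), axis=None, dn_max=DN_MAX):
    axis = axis or SpectralAxis.default(shape[2])
    return HyperspectralCube(data=np.full(shape, fill, dtype=np.uint32),
                             axis=axis, dn_max=dn_max)


class TestCorrection:
    def test_fixed_points(self):
        white, black = _cube(1000), _cube(200)
        img = correct_reflectance(_cube(1000), white, black)
        assert np.allclose(img.data, DN_MAX)
        img = correct_reflectance(_cube(200), white, black)
        assert np.allclose(img.data, 0.0)

    def test_direct_arithmetic(self):
        img = correct_reflectance(_cube(600), _cube(1000), _cube(200))
        assert np.allclose(img.data, DN_MAX * 400 / 800)
        assert np.allclose(img.data, 32776.0)

    def test_affine_in_raw_dn(self, rng):
        axis = SpectralAxis.default(4)
        w = HyperspectralCube(rng.integers(3000, 5000, (3, 3, 4)), axis)
        b = HyperspectralCube(rng.integers(0, 500, (3, 3, 4)), axis)
        r0 = HyperspectralCube(rng.integers(500, 3000, (3, 3, 4)), axis)
        a = 0.4
        blended = HyperspectralCube(
            a * r0.data.astype(float) + (1 - a) * b.data.astype(float), axis)
        lhs = correct_reflectance(blended, w, b).data
        rhs = a * correct_reflectance(r0, w, b).data
        assert np.allclose(lhs, rhs)

    def test_equal_references_masked(self):
        w = _cube(1000)
        bad = w.data.copy()
        bad[0, 0, :] = 200
        black = HyperspectralCube(bad, w.axis)
        img = correct_reflectance(_cube(600), w, black)
        assert not img.valid[0, 1]
        assert img.valid[0, 0]
        with pytest.raises(ValueError, match="all pixels invalid"):
            correct_reflectance(_cube(600), w, _cube(1000))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            correct_reflectance(_cube(600), _cube(1000, shape=(3, 2, 3)),
                                _cube(200))


class TestRoiMean:
    def test_single_pixel_and_uniform(self):
        img = correct_reflectance(_cube(600), _cube(1000), _cube(200))
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        assert np.allclose(extract_roi_mean(img, mask), img.data[0, 0])
        assert np.allclose(extract_roi_mean(img, np.ones((2, 2), bool)),
                           img.data[0, 0])

    def test_two_pixel_mean(self):
        axis = SpectralAxis.default(3)
        raw = np.zeros((1, 2, 3), dtype=np.uint32)
        raw[0, 0, :] = 10
        raw[0, 1, :] = 20
        img = correct_reflectance(
            HyperspectralCube(raw, axis, dn_max=100),
            HyperspectralCube(np.full((1, 2, 3), 100, np.uint32), axis, dn_max=100),
            HyperspectralCube(np.zeros((1, 2, 3), np.uint32), axis, dn_max=100))
        assert np.allclose(extract_roi_mean(img, np.ones((1, 2), bool)), 15.0)

    def test_empty_mask_rejected(self):
        img = correct_reflectance(_cube(600), _cube(1000), _cube(200))
        with pytest.raises(ValueError, match="no valid pixels"):
            extract_roi_mean(img, np.zeros((2, 2), bool))

    def test_roi_mean_commutes_with_correction_for_uniform_references(self, rng):
        axis = SpectralAxis.default(5)
        raw = HyperspectralCube(rng.integers(100, 900, (4, 4, 5)), axis)
        img = correct_reflectance(raw, _cube(1000, (4, 4, 5)), _cube(50, (4, 4, 5)))
        mask = np.ones((4, 4), bool)
        mean_then_correct = DN_MAX * (raw.data.astype(float).mean((0, 1)) - 50) / 950
        assert np.allclose(extract_roi_mean(img, mask), mean_then_correct)


class TestEnviRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        axis = SpectralAxis.default(3)
        cube = HyperspectralCube(rng.integers(0, DN_MAX, (2, 2, 3)), axis)
        write_cube(cube, tmp_path / "toy")
        back = read_cube(tmp_path / "toy")
        assert np.array_equal(back.data, cube.data)
        assert back.axis == cube.axis
        assert back.dn_max == cube.dn_max

    def test_known_toy_values(self, tmp_path):
        axis = SpectralAxis([400.0, 500.0, 600.0])
        data = np.arange(12, dtype=np.uint32).reshape(2, 2, 3)
        write_cube(HyperspectralCube(data, axis), tmp_path / "t")
        assert np.array_equal(read_cube(tmp_path / "t").data, data)

    def test_uint16_used_for_small_dn_max(self, tmp_path):
        axis = SpectralAxis.default(3)
        cube = HyperspectralCube(np.full((2, 2, 3), 1000, np.uint32), axis,
                                 dn_max=65535)
        write_cube(cube, tmp_path / "s")
        assert "data type = 12" in (tmp_path / "s.hdr").read_text()
        assert np.array_equal(read_cube(tmp_path / "s").data, cube.data)

    def test_header_errors_distinct(self, tmp_path, rng):
        axis = SpectralAxis.default(3)
        cube = HyperspectralCube(rng.integers(0, 100, (2, 2, 3)), axis)
        write_cube(cube, tmp_path / "bad")
        hdr = (tmp_path / "bad.hdr")
        text = hdr.read_text()
        hdr.write_text(text.replace("interleave = bsq", "interleave = bil"))
        with pytest.raises(ValueError, match="unsupported interleave"):
            read_cube(tmp_path / "bad")
        hdr.write_text(text.replace("bands = 3", "bands = 4"))
        with pytest.raises(ValueError, match="wavelength list"):
            read_cube(tmp_path / "bad")
        hdr.write_text("\n".join(l for l in text.splitlines()
                                 if not l.startswith("samples")))
        with pytest.raises(ValueError, match="missing header field: samples"):
            read_cube(tmp_path / "bad")
        hdr.write_text(text)
        (tmp_path / "bad.img").write_bytes(b"\x00" * 10)
        with pytest.raises(ValueError, match="size mismatch"):
            read_cube(tmp_path / "bad")


class TestBuildSpectrumMatrix:
    @staticmethod
    def _samples(n, axis, stage="withering"):
        out = []
        for i in range(n):
            out.append((np.full(axis.n_bands, float(i)),
                        {"sample_id": f"s{i}", "stage": stage,
                         "time_h": float(n - i), "replicate": 1}))
        return out

    def test_single_sample_shape(self, axis20):
        sm = build_spectrum_matrix(self._samples(1, axis20), axis20)
        assert sm.values.shape == (1, 20)

    def test_order_invariance(self, axis20, rng):
        samples = self._samples(6, axis20)
        sm1 = build_spectrum_matrix(samples, axis20)
        shuffled = [samples[i] for i in rng.permutation(6)]
        sm2 = build_spectrum_matrix(shuffled, axis20)
        assert np.array_equal(sm1.values, sm2.values)
        assert list(sm1.sample_ids) == list(sm2.sample_ids)

    def test_stage_ordering_withering_first(self, axis20):
        samples = (self._samples(2, axis20, "fermentation")
                   + [(np.zeros(20), {"sample_id": "w", "stage": "withering",
                                      "time_h": 99.0, "replicate": 1})])
        sm = build_spectrum_matrix(samples, axis20)
        assert sm.metadata.loc[0, "stage"] == "withering"

    def test_duplicate_and_mismatch_rejected(self, axis20):
        samples = self._samples(2, axis20)
        samples[1] = (samples[1][0], {**samples[1][1], "sample_id": "s0"})
        with pytest.raises(ValueError, match="duplicate"):
            build_spectrum_matrix(samples, axis20)
        with pytest.raises(ValueError, match="does not match axis"):
            build_spectrum_matrix([(np.zeros(5), {"sample_id": "x",
                                                  "stage": "withering",
                                                  "time_h": 0.0,
                                                  "replicate": 1})], axis20)
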
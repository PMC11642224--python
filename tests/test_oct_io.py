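import json

import numpy as np
import pytest
import tifffile

from oactool import oct_io
from oactool.errors import ConfigurationError, DataError
from oactool.oct_io import (BOUNDARY_SENTINEL, BoundarySurface, EnFaceImage,
                            OCTVolume, read_boundary, read_enface, read_volume,
                            write_boundary, write_enface, write_volume)


class TestVolumeIO:
    def test_tiff_roundtrip_is_bitwise(self, small_volume, tmp_path):
        path = tmp_path / "vol.tif"
        write_volume(small_volume, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, small_volume.data)
        assert back.dz == small_volume.dz
        assert back.lateral_shape == small_volume.lateral_shape

    def test_identity_volume_of_ones(self, tmp_path):
        path = tmp_path / "ones.tif"
        tifffile.imwrite(path, np.ones((4, 2, 2), dtype=np.float32))
        sidecar = {"shape": [4, 2, 2], "dtype": "float32", "scale": "linear",
                   "dz_um": 5.0, "dx_um": 10.0, "dy_um": 10.0}
        (tmp_path / "ones.tif.json").write_text(json.dumps(sidecar))
        vol = read_volume(path)
        assert vol.shape == (4, 2, 2)
        assert np.all(vol.data == 1.0)
        assert vol.dz == 5.0

    def test_db_scale_converted_to_linear(self, tmp_path):
        # a stored value of 10 dB must come back as 10^(10/10) = 10 linear
        path = tmp_path / "db.tif"
        tifffile.imwrite(path, np.full((2, 2, 2), 10.0, dtype=np.float64))
        sidecar = {"scale": "dB", "dz_um": 2.6, "dx_um": 10.0, "dy_um": 10.0}
        (tmp_path / "db.tif.json").write_text(json.dumps(sidecar))
        vol = read_volume(path)
        np.testing.assert_allclose(vol.data, 10.0 ** (10.0 / 10.0))
        assert vol.meta["scale"] == "linear"

    def test_raw_binary_reader(self, small_volume, tmp_path):
        path = tmp_path / "vol.raw"
        data32 = small_volume.data.astype(np.float32)
        data32.tofile(path)
        sidecar = {"shape": list(data32.shape), "dtype": "float32",
                   "scale": "linear", "dz_um": 2.6, "dx_um": 11.7, "dy_um": 11.7}
        (tmp_path / "vol.raw.json").write_text(json.dumps(sidecar))
        vol = read_volume(path)
        np.testing.assert_array_equal(vol.data, data32)

    def test_missing_sidecar_field_is_configuration_error(self, tmp_path):
        path = tmp_path / "v.tif"
        tifffile.imwrite(path, np.ones((2, 2, 2), dtype=np.float32))
        (tmp_path / "v.tif.json").write_text(json.dumps({"dz_um": 2.6}))
        with pytest.raises(ConfigurationError):
            read_volume(path)

    def test_sidecar_shape_mismatch_rejected(self, tmp_path):
        path = tmp_path / "v.tif"
        tifffile.imwrite(path, np.ones((2, 2, 2), dtype=np.float32))
        sidecar = {"shape": [3, 2, 2], "dz_um": 1, "dx_um": 1, "dy_um": 1}
        (tmp_path / "v.tif.json").write_text(json.dumps(sidecar))
        with pytest.raises(ConfigurationError):
            read_volume(path)

    def test_negative_intensity_rejected(self):
        with pytest.raises(DataError):
            OCTVolume(-np.ones((2, 2, 2)), dz=1, dx=1, dy=1)


class TestEnfaceIO:
    def test_float_preserves_values(self, tmp_path):
        img = EnFaceImage(np.full((4, 4), 0.5), kind="attenuation", units="mm^-1")
        write_enface(img, tmp_path / "e.tif", bit_depth="float")
        back = read_enface(tmp_path / "e.tif")
        np.testing.assert_array_equal(back.data, 0.5)
        assert back.kind == "attenuation"

    def test_8bit_forces_min_max(self, tmp_path):
        img = EnFaceImage(np.array([[0.0, 1.0], [1.0, 0.0]]))
        write_enface(img, tmp_path / "e.tif", bit_depth=8)
        raw = tifffile.imread(tmp_path / "e.tif")
        np.testing.assert_array_equal(raw, [[0, 255], [255, 0]])

    @pytest.mark.parametrize("bit_depth,tol", [(8, 1 / 255), (16, 1 / 65535)])
    def test_integer_roundtrip_within_quantization(self, rng, tmp_path, bit_depth, tol):
        img = EnFaceImage(rng.random((8, 8)) * 3.0 + 1.0)
        write_enface(img, tmp_path / "e.tif", bit_depth=bit_depth)
        back = read_enface(tmp_path / "e.tif")
        span = img.data.max() - img.data.min()
        assert np.abs(back.data - img.data).max() <= tol * span + 1e-12

    def test_constant_integer_writes_zeros_with_warning(self, tmp_path):
        img = EnFaceImage(np.full((3, 3), 2.0))
        with pytest.warns(UserWarning):
            write_enface(img, tmp_path / "c.tif", bit_depth=8)
        assert np.all(tifffile.imread(tmp_path / "c.tif") == 0)


class TestBoundaryIO:
    def test_csv_parse(self, tmp_path):
        (tmp_path / "b.csv").write_text("3,3\n4,4\n")
        b = read_boundary(tmp_path / "b.csv")
        np.testing.assert_array_equal(b.z_index, [[3, 3], [4, 4]])
        assert b.valid_mask.all()

    def test_sentinel_marks_invalid(self, tmp_path):
        z = np.array([[3, int(BOUNDARY_SENTINEL)], [4, 4]])
        (tmp_path / "b.csv").write_text("\n".join(",".join(map(str, r)) for r in z))
        b = read_boundary(tmp_path / "b.csv")
        assert not b.valid_mask[0, 1]
        assert b.valid_mask.sum() == 3

    @pytest.mark.parametrize("suffix", [".tif", ".csv"])
    def test_roundtrip(self, tmp_path, suffix):
        b = BoundarySurface(z_index=np.array([[3, 7], [2, 9]]),
                            valid_mask=np.array([[True, False], [True, True]]))
        path = tmp_path / f"b{suffix}"
        write_boundary(b, path)
        back = read_boundary(path)
        np.testing.assert_array_equal(back.valid_mask, b.valid_mask)
        np.testing.assert_array_equal(back.z_index[b.valid_mask],
                                      b.z_index[b.valid_mask])
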
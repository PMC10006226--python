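"""Micrograph/ROI ingestion: gray conversion, cropping, quantization."""

import numpy as np
import pytest
import imageio.v3 as iio
from hypothesis import given, settings, strategies as st

from nucleotexture.ingest import (
    GrayPatch,
    Micrograph,
    QuantizationConfig,
    RoiRecord,
    load_roi,
    quantize_gray,
    read_manifest,
    rgb_to_gray,
    write_manifest,
)


class TestRgbToGray:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 100, 100), 100)],
    )
    def test_fixed_points(self, rgb, expected):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        out = rgb_to_gray(Micrograph(pixels=img))
        assert out.pixels.dtype == np.uint8
        assert (out.pixels == expected).all()

    def test_luma_weights(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 200  # pure red
        out = rgb_to_gray(Micrograph(pixels=img))
        assert (out.pixels == round(0.299 * 200)).all()

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            Micrograph(pixels=np.zeros((4, 4, 2), dtype=np.uint8))


class TestLoadRoi:
    def _write(self, tmp_path, img, mask):
        iio.imwrite(tmp_path / "img.png", img)
        iio.imwrite(tmp_path / "mask.png", mask)
        return RoiRecord("r1", "img.png", "mask.png", 0, "a1")

    def test_full_mask_is_whole_image(self, tmp_path, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        rec = self._write(tmp_path, img, np.full((10, 10), 255, np.uint8))
        patch = load_roi(rec, QuantizationConfig(levels=256, strategy="bitshift"), root=tmp_path)
        assert patch.shape == (10, 10)
        assert patch.origin == (0, 0)
        assert (patch.raw == img).all()

    def test_bounding_box_crop(self, tmp_path, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        mask = np.zeros((10, 10), np.uint8)
        mask[2:6, 3:8] = 255  # rows 2–5, cols 3–7
        patch = load_roi(self._write(tmp_path, img, mask), root=tmp_path)
        assert patch.shape == (4, 5)
        assert patch.origin == (2, 3)

    def test_masked_multiset_preserved(self, tmp_path, rng):
        """Cropping must not alter the masked-in pixel population."""
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        mask = rng.random((12, 12)) < 0.4
        mask[5:8, 5:8] = True  # ensure ≥8 pixels
        rec = self._write(tmp_path, img, mask.astype(np.uint8) * 255)
        patch = load_roi(rec, QuantizationConfig(levels=256, strategy="bitshift"), root=tmp_path)
        np.testing.assert_array_equal(
            np.sort(patch.raw[patch.mask]), np.sort(img[mask])
        )

    def test_empty_mask_and_shape_mismatch(self, tmp_path, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        rec = self._write(tmp_path, img, np.zeros((10, 10), np.uint8))
        with pytest.raises(ValueError):
            load_roi(rec, root=tmp_path)
        iio.imwrite(tmp_path / "mask.png", np.full((8, 10), 255, np.uint8))
        with pytest.raises(ValueError):
            load_roi(rec, root=tmp_path)

    def test_mask_round_trip(self, tmp_path, rng):
        mask = rng.random((20, 20)) < 0.5
        iio.imwrite(tmp_path / "m.png", mask.astype(np.uint8) * 255)
        back = iio.imread(tmp_path / "m.png") != 0
        np.testing.assert_array_equal(back, mask)


class TestQuantize:
    def _patch(self, values):
        arr = np.asarray(values)
        return GrayPatch(intensities=arr, mask=np.ones(arr.shape, bool), levels=256)

    def test_constant_minmax_maps_to_zero(self):
        patch = self._patch(np.full((4, 4), 77))
        q = quantize_gray(patch, 64, "minmax")
        assert (q.intensities == 0).all()
        assert q.levels == 64

    def test_bitshift_is_right_shift(self):
        vals = np.arange(256).reshape(16, 16)
        q = quantize_gray(self._patch(vals), 64, "bitshift")
        np.testing.assert_array_equal(q.intensities, vals >> 2)

    def test_minmax_endpoints(self):
        vals = np.where(np.indices((4, 4)).sum(0) % 2 == 0, 10, 250)
        q = quantize_gray(self._patch(vals), 64, "minmax")
        assert set(np.unique(q.intensities)) == {0, 63}
        assert q.intensities[vals == 10].max() == 0
        assert q.intensities[vals == 250].min() == 63

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            quantize_gray(self._patch(np.zeros((4, 4), int)), 60)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        data=st.lists(st.integers(0, 255), min_size=9, max_size=64),
        levels=st.sampled_from([8, 16, 32, 64, 128, 256]),
        strategy=st.sampled_from(["minmax", "bitshift", "sigma3"]),
    )
    def test_range_and_monotonicity(self, data, levels, strategy):
        """Quantized values stay in [0, G−1] and preserve intensity order."""
        n = len(data)
        arr = np.array(data + [0] * (9 - n) if n < 9 else data).reshape(1, -1)
        patch = GrayPatch(intensities=arr, mask=np.ones(arr.shape, bool), levels=256)
        q = quantize_gray(patch, levels, strategy).intensities.ravel()
        assert q.min() >= 0 and q.max() <= levels - 1
        order = np.argsort(arr.ravel(), kind="stable")
        assert (np.diff(q[order]) >= 0).all()


def test_manifest_round_trip(tmp_path):
    records = [
        RoiRecord("r1", "img/a.png", "mask/a.png", 0, "ctrl_01"),
        RoiRecord("r2", "img/b.png", "mask/b.png", 1, "aki_02"),
    ]
    write_manifest(records, tmp_path / "m.csv")
    assert read_manifest(tmp_path / "m.csv") == records


def test_manifest_missing_column(tmp_path):
    (tmp_path / "bad.csv").write_text("roi_id,image_path\nr1,x.png\n")
    with pytest.raises(ValueError, match="missing"):
        read_manifest(tmp_path / "bad.csv")
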
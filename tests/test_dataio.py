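"""Image/mask I/O conventions, ROI cropping, resizing, and split arithmetic."""

import io

import numpy as np
import pytest
from PIL import Image

from discseg import dataio
from discseg.dataio import (
    ROISpec,
    crop_roi,
    decode_mask,
    encode_mask,
    read_grayscale,
    read_mask,
    resize_patch,
    split_dataset,
    write_grayscale,
    write_mask,
)


class TestReadGrayscale:
    def test_png_round_trip_bit_exact(self, tmp_path, rng):
        img = rng.integers(0, 256, size=(32, 40), dtype=np.uint8)
        write_grayscale(tmp_path / "a.png", img)
        np.testing.assert_array_equal(read_grayscale(tmp_path / "a.png"), img)

    def test_dicom_minmax_scales_to_full_range(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian

        # synthetic single-frame 16-bit DICOM with pixel values {0, 1000}
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "a.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = 2, 2
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        arr = np.array([[0, 1000], [1000, 0]], dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(tmp_path / "a.dcm", enforce_file_format=True)

        out = read_grayscale(tmp_path / "a.dcm")
        np.testing.assert_array_equal(out, np.array([[0, 255], [255, 0]], np.uint8))

    def test_rgb_jpeg_converted_by_luminance(self, tmp_path, rng):
        rgb = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        Image.fromarray(rgb, "RGB").save(tmp_path / "a.jpg", quality=95)
        out = read_grayscale(tmp_path / "a.jpg")
        assert out.shape == (24, 24)
        with Image.open(tmp_path / "a.jpg") as im:
            decoded = np.asarray(im.convert("RGB")).astype(np.float64)
        # ITU-R 601 luma oracle on the decoded JPEG pixels
        ref = decoded @ [0.299, 0.587, 0.114]
        assert np.abs(out.astype(np.float64) - ref).max() <= 1.0

    def test_unsupported_format_rejected(self, tmp_path):
        (tmp_path / "a.tiff").write_bytes(b"x")
        with pytest.raises(ValueError, match="unsupported"):
            read_grayscale(tmp_path / "a.tiff")


class TestMaskCoding:
    def test_exact_white_fill_decodes_to_fill_count(self, rng):
        mask = (rng.random((30, 30)) > 0.7).astype(np.uint8)
        rgb = encode_mask(mask)
        assert set(np.unique(rgb)) <= {0, 255}
        decoded = decode_mask(rgb)
        np.testing.assert_array_equal(decoded, mask)
        assert decoded.sum() == mask.sum()

    def test_all_zero_image_decodes_empty(self):
        assert decode_mask(np.zeros((8, 8, 3), np.uint8)).sum() == 0

    def test_two_channel_input_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            decode_mask(np.zeros((8, 8)))

    def test_jpeg_recompression_keeps_fill_within_2_percent(self, rng):
        mask = np.zeros((64, 64), np.uint8)
        mask[16:48, 12:52] = 1  # solid block, known fill
        buf = io.BytesIO()
        Image.fromarray(encode_mask(mask), "RGB").save(buf, format="JPEG", quality=90)
        buf.seek(0)
        with Image.open(buf) as im:
            decoded = decode_mask(np.asarray(im.convert("RGB")))
        fill = int(mask.sum())
        assert abs(int(decoded.sum()) - fill) <= 0.02 * fill

    def test_write_read_round_trip(self, tmp_path, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        write_mask(tmp_path / "m.png", mask)
        np.testing.assert_array_equal(read_mask(tmp_path / "m.png"), mask)


class TestCropROI:
    def test_default_roi_from_512_image(self, rng):
        img = rng.integers(0, 256, size=(512, 512), dtype=np.uint8)
        out = crop_roi(img, ROISpec(origin=(100, 120)))
        assert out.shape == (161, 184)
        np.testing.assert_array_equal(out, img[100:261, 120:304])

    def test_whole_image_roi_is_identity(self, rng):
        img = rng.integers(0, 256, size=(32, 40), dtype=np.uint8)
        np.testing.assert_array_equal(crop_roi(img, ROISpec((0, 0), 32, 40)), img)

    def test_one_pixel_overflow_rejected(self):
        img = np.zeros((512, 512), np.uint8)
        with pytest.raises(ValueError, match=r"cols \[329,513\)"):
            crop_roi(img, ROISpec(origin=(0, 329)))

    def test_crop_writeback_identity(self, rng):
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        roi = ROISpec(origin=(10, 20), height=16, width=24)
        patch = crop_roi(img, roi)
        img2 = img.copy()
        img2[10:26, 20:44] = patch
        np.testing.assert_array_equal(img2, img)


class TestResizePatch:
    def test_mask_resize_stays_binary(self, rng):
        mask = (rng.random((161, 184)) > 0.5).astype(np.uint8)
        out = resize_patch(mask, (224, 256), mode="mask")
        assert set(np.unique(out)) <= {0, 1}
        assert out.shape == (224, 256)

    def test_constant_image_stays_constant(self):
        out = resize_patch(np.full((40, 46), 7.0), (64, 64), mode="image")
        np.testing.assert_allclose(out, 7.0, atol=1e-9)

    def test_mask_up_down_round_trip_agreement(self, small_cohort):
        mask = small_cohort[0].mask
        up = resize_patch(mask, (mask.shape[0] * 2, mask.shape[1] * 2), mode="mask")
        back = resize_patch(up, mask.shape, mode="mask")
        agreement = (back == mask).mean()
        assert agreement >= 0.95

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            resize_patch(np.zeros((4, 4)), (0, 4))


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n,expected_train,expected_test",
        [(217, 173, 44), (111, 88, 23), (106, 84, 22), (10, 8, 2)],
    )
    def test_floor_rule_split_sizes(self, n, expected_train, expected_test):
        samples = [{"group": "normal"}] * n
        sp = split_dataset(samples, 0.8, seed=0)
        assert (len(sp.train), len(sp.test)) == (expected_train, expected_test)

    def test_partition_property_over_sizes(self):
        for n in range(2, 501, 7):
            sp = split_dataset([{"group": "normal"}] * n, 0.8, seed=n)
            assert len(sp.train) + len(sp.test) == n
            assert set(sp.train) | set(sp.test) == set(range(n))
            assert set(sp.train) & set(sp.test) == set()

    def test_deterministic_under_seed(self):
        samples = [{"group": "normal"}] * 50
        a = split_dataset(samples, 0.8, seed=3)
        b = split_dataset(samples, 0.8, seed=3)
        assert a.train == b.train and a.test == b.test

    def test_stratum_filters_by_group(self, small_cohort):
        sp = split_dataset(small_cohort, 0.8, seed=0, stratum="displaced")
        assert all(small_cohort[i].group == "displaced" for i in sp.train + sp.test)

    def test_too_small_pool_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset([{"group": "normal"}], 0.8, seed=0)
        with pytest.raises(ValueError, match="fraction"):
            split_dataset([{"group": "normal"}] * 5, 1.2, seed=0)


class TestPreprocess:
    def test_patch_pair_contract(self, small_cohort, small_roi):
        pair = dataio.preprocess_sample(small_cohort[0], small_roi, (64, 64))
        assert pair.image_patch.shape == pair.mask_patch.shape == (64, 64)
        assert 0.0 <= pair.image_patch.min() and pair.image_patch.max() <= 1.0
        assert set(np.unique(pair.mask_patch)) <= {0, 1}
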
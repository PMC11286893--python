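"""Volume model, coordinate conventions, MetaImage and DICOM I/O."""

import numpy as np
import pytest

from fdctreg import (FormatError, GeometryError, Volume3D, index_to_physical,
                     physical_to_index, read_dicom_series, read_mha, write_mha)
from fdctreg.io import parse_mha_header

from conftest import random_geometry


class TestCoordinates:
    def test_origin_anchors_index_zero(self, rng):
        vol = random_geometry(rng)
        assert np.allclose(index_to_physical(vol, [0, 0, 0]), vol.origin, atol=1e-12)
        assert np.allclose(physical_to_index(vol, vol.origin), [0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("idx,spacing,expected", [
        ((1, 2, 3), (1, 1, 1), (1, 2, 3)),
        ((10, 0, 0), (0.1965, 0.1965, 0.1965), (1.965, 0, 0)),  # FDCT voxel size
    ])
    def test_axis_aligned_mapping(self, idx, spacing, expected):
        vol = Volume3D(np.zeros((16, 16, 16)), spacing)
        assert np.allclose(index_to_physical(vol, idx), expected, atol=1e-12)

    def test_anisotropic_ct_grid_inverse(self):
        vol = Volume3D(np.zeros((8, 8, 8)), (0.38, 0.38, 0.7), origin=(5.0, -3.0, 2.0))
        p = vol.origin + np.array([0.38, 0.76, 1.4])
        assert np.allclose(physical_to_index(vol, p), [1, 2, 2], atol=1e-9)

    def test_round_trip_random_geometries(self, rng):
        for _ in range(10):
            vol = random_geometry(rng)
            pts = rng.uniform(-50, 80, (100, 3))
            idx = physical_to_index(vol, pts)
            assert np.allclose(index_to_physical(vol, idx), pts, atol=1e-9)
            idx2 = rng.uniform(-5, 20, (100, 3))
            assert np.allclose(
                physical_to_index(vol, index_to_physical(vol, idx2)), idx2, atol=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            Volume3D(np.zeros((4, 4, 4)), (1.0, -1.0, 1.0))
        with pytest.raises(GeometryError):  # sheared direction matrix
            Volume3D(np.zeros((4, 4, 4)), (1, 1, 1),
                     direction=[[1, 0.2, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(GeometryError):  # reflection
            Volume3D(np.zeros((4, 4, 4)), (1, 1, 1),
                     direction=np.diag([1.0, 1.0, -1.0]))


class TestMha:
    @pytest.mark.parametrize("dtype", [np.int16, np.float32, np.float64])
    def test_round_trip_lossless(self, tmp_path, rng, dtype):
        data = (rng.normal(0, 300, (5, 6, 7)) if np.issubdtype(dtype, np.floating)
                else rng.integers(-1000, 3000, (5, 6, 7))).astype(dtype)
        vol = random_geometry(rng)
        vol = Volume3D(data, vol.spacing, vol.origin, vol.direction)
        path = tmp_path / "vol.mha"
        write_mha(vol, path)
        back = read_mha(path)
        assert back.data.dtype == dtype
        assert np.array_equal(back.data, vol.data)
        assert np.array_equal(back.spacing, vol.spacing)
        assert np.array_equal(back.origin, vol.origin)
        assert np.array_equal(back.direction, vol.direction)

    def test_constant_volume_round_trip(self, tmp_path):
        vol = Volume3D(np.full((4, 4, 4), 7, dtype=np.int16), (1, 1, 1))
        write_mha(vol, tmp_path / "c.mha")
        back = read_mha(tmp_path / "c.mha")
        assert np.array_equal(back.data, vol.data)
        assert back.size == (4, 4, 4)

    def test_clinical_fdct_header_parses(self):
        header_text = (
            "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
            "DimSize = 512 512 497\n"
            "ElementSpacing = 0.1965 0.1965 0.1965\n"
            "ElementType = MET_SHORT\nElementDataFile = LOCAL\n")
        header, offset = parse_mha_header(header_text.encode())
        assert header["DimSize"].split() == ["512", "512", "497"]
        assert [float(v) for v in header["ElementSpacing"].split()] == [0.1965] * 3
        assert offset == len(header_text)

    def test_missing_spacing_names_the_key(self, tmp_path):
        p = tmp_path / "bad.mha"
        p.write_bytes(b"ObjectType = Image\nNDims = 3\nDimSize = 1 1 1\n"
                      b"ElementType = MET_UCHAR\nElementDataFile = LOCAL\n\x00")
        with pytest.raises(FormatError, match="ElementSpacing"):
            read_mha(p)

    def test_wrong_dimensionality_rejected(self, tmp_path):
        p = tmp_path / "bad.mha"
        p.write_bytes(b"NDims = 2\nDimSize = 1 1\nElementSpacing = 1 1\n"
                      b"ElementType = MET_UCHAR\nElementDataFile = LOCAL\n\x00")
        with pytest.raises(FormatError, match="NDims"):
            read_mha(p)

    def test_truncated_payload_rejected(self, tmp_path):
        p = tmp_path / "bad.mha"
        p.write_bytes(b"NDims = 3\nDimSize = 4 4 4\nElementSpacing = 1 1 1\n"
                      b"ElementType = MET_SHORT\nElementDataFile = LOCAL\n\x00\x00")
        with pytest.raises(FormatError, match="payload"):
            read_mha(p)

    def test_cross_validation_against_simpleitk(self, tmp_path, rng):
        sitk = pytest.importorskip("SimpleITK")
        vol = random_geometry(rng, size=(6, 5, 4))
        vol = Volume3D(vol.data.astype(np.float32), vol.spacing, vol.origin, vol.direction)
        ours = tmp_path / "ours.mha"
        write_mha(vol, ours)
        img = sitk.ReadImage(str(ours))
        assert img.GetSize() == (6, 5, 4)
        assert np.allclose(img.GetSpacing(), vol.spacing)
        assert np.allclose(img.GetOrigin(), vol.origin)
        assert np.allclose(np.array(img.GetDirection()).reshape(3, 3), vol.direction)
        # sitk arrays are indexed [z, y, x]
        assert np.allclose(sitk.GetArrayFromImage(img).transpose(2, 1, 0), vol.data)

        theirs = tmp_path / "theirs.mha"
        sitk.WriteImage(img, str(theirs), useCompression=False)
        back = read_mha(theirs)
        assert np.allclose(back.data, vol.data)
        assert np.allclose(back.origin, vol.origin)


def _write_slice(path, z, series_uid, rows=4, cols=6, pixel_spacing=(0.5, 0.25),
                 values=None):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [10.0, -20.0, float(z)]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = (np.full((rows, cols), int(z * 10), dtype=np.int16)
           if values is None else np.asarray(values, dtype=np.int16))
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    UID = "1.2.840.99999.1"

    def test_slice_spacing_inferred_from_positions(self, tmp_path):
        for i, z in enumerate([0.0, 0.7, 1.4]):
            _write_slice(tmp_path / f"s{i}.dcm", z, self.UID)
        vol = read_dicom_series(tmp_path)
        assert vol.size == (6, 4, 3)  # (x, y, z) = (cols, rows, slices)
        assert np.allclose(vol.spacing, [0.25, 0.5, 0.7])
        assert np.allclose(vol.origin, [10.0, -20.0, 0.0])
        assert np.allclose(vol.data[:, :, 1], 7)  # z=0.7 slice filled with 7

    def test_order_independent_of_filenames(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.mkdir(), b.mkdir()
        zs = [0.0, 0.7, 1.4, 2.1]
        for i, z in enumerate(zs):
            _write_slice(a / f"s{i}.dcm", z, self.UID)
        for i, z in enumerate(reversed(zs)):  # shuffled on-disk order
            _write_slice(b / f"s{i}.dcm", z, self.UID)
        va, vb = read_dicom_series(a), read_dicom_series(b)
        assert np.array_equal(va.data, vb.data)
        assert np.allclose(va.origin, vb.origin)

    def test_mixed_series_rejected(self, tmp_path):
        _write_slice(tmp_path / "s0.dcm", 0.0, self.UID)
        _write_slice(tmp_path / "s1.dcm", 0.7, "1.2.840.99999.2")
        with pytest.raises(FormatError, match="series"):
            read_dicom_series(tmp_path)

    def test_non_uniform_gaps_rejected_with_indices(self, tmp_path):
        for i, z in enumerate([0.0, 0.7, 1.6]):  # second gap is 0.9
            _write_slice(tmp_path / f"s{i}.dcm", z, self.UID)
        with pytest.raises(FormatError, match="non-uniform"):
            read_dicom_series(tmp_path)
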
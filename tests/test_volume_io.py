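"""Volume/mask/transform I/O, DICOM readers, dilation, and resampling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctalert import (
    FormatError,
    MaskVolume,
    PreconditionError,
    RigidTransform,
    VolumeGrid,
    generate_course,
    identity_transform,
    load_dicom_registration,
    load_dicom_series,
    load_mask,
    load_transform,
    load_volume,
    mask_from_external,
    resample_onto,
    rtstruct_to_mask,
    save_mask,
    save_transform,
    save_volume,
)
from cbctalert.synthetic_phantom import CourseSpec


def ramp_volume(shape=(4, 4, 4), spacing=(1.0, 2.0, 3.0), origin=(-1.0, 0.5, 2.0)):
    data = np.arange(np.prod(shape), dtype=float).reshape(shape)
    return VolumeGrid(data, spacing, origin)


class TestResearchFormat:
    def test_round_trip_is_bit_stable(self, tmp_path):
        vol = ramp_volume()
        save_volume(vol, tmp_path / "ramp")
        back = load_volume(tmp_path / "ramp")
        assert np.array_equal(back.data, vol.data)
        assert np.array_equal(back.spacing, vol.spacing)
        assert np.array_equal(back.origin, vol.origin)
        # physical coordinates reproduce to well under 1e-9 mm
        idx = np.array([3, 2, 1])
        assert np.abs(back.index_to_physical(idx) - vol.index_to_physical(idx)).max() < 1e-12

    def test_generator_output_round_trip(self, tmp_path, quiet_phantom):
        course = generate_course(quiet_phantom, CourseSpec(n_fractions=3, cbct_schedule="daily", seed=2))
        vol = course.acquisitions[0].volume
        save_volume(vol, tmp_path / "phantom")
        back = load_volume(tmp_path / "phantom")
        assert np.abs(back.data - vol.data).max() == 0.0

    def test_non_finite_voxels_rejected(self, tmp_path):
        vol = ramp_volume()
        vol.data[1, 1, 1] = np.nan
        save_volume(vol, tmp_path / "bad")
        with pytest.raises(FormatError, match="non-finite"):
            load_volume(tmp_path / "bad")
        assert load_volume(tmp_path / "bad", allow_non_finite=True) is not None

    def test_mask_round_trip(self, tmp_path):
        vol = ramp_volume()
        mask = MaskVolume(vol.data > 20, provenance="test")
        save_mask(mask, vol, tmp_path / "m")
        back, grid = load_mask(tmp_path / "m")
        assert np.array_equal(back.data, mask.data)
        assert np.array_equal(grid.spacing, vol.spacing)

    def test_missing_sidecar_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="sidecar"):
            load_volume(tmp_path / "nope")


class TestTransforms:
    def test_text_round_trip(self, tmp_path):
        angle = 0.3
        rot = np.array(
            [[1, 0, 0], [0, np.cos(angle), -np.sin(angle)], [0, np.sin(angle), np.cos(angle)]]
        )
        t = RigidTransform(rot, [1.25, -3.5, 0.125])
        save_transform(t, tmp_path / "a.tfm")
        back = load_transform(tmp_path / "a.tfm")
        assert np.array_equal(back.rotation, t.rotation)
        assert np.array_equal(back.translation, t.translation)
        assert back.direction == t.direction

    def test_inverse_composes_to_identity(self):
        rot = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1]], dtype=float)
        t = RigidTransform(rot, [5.0, -2.0, 7.0])
        pts = np.random.default_rng(0).normal(0, 50, size=(20, 3))
        round_tripped = t.inverse().apply(t.apply(pts))
        assert np.abs(round_tripped - pts).max() < 1e-9

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(PreconditionError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(PreconditionError, match="determinant"):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


class TestDicomReaders:
    def test_series_load_matches_pixels(self, dicom_series_dir):
        d, hu = dicom_series_dir
        vol = load_dicom_series(d)
        assert vol.shape == (4, 8, 8)
        assert np.array_equal(vol.data, hu)
        assert np.allclose(vol.spacing, [3.0, 2.0, 2.0])
        assert np.allclose(vol.origin, [10.0, 0.0, 0.0])

    def test_missing_slice_raises_named_gap(self, dicom_series_dir):
        d, _ = dicom_series_dir
        (d / "slice1.dcm").unlink()  # break the contiguous stack
        with pytest.raises(FormatError, match="gap"):
            load_dicom_series(d)

    def test_non_image_dicom_rejected(self, tmp_path, dicom_series_dir):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        d, _ = dicom_series_dir
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.PatientName = "not an image"
        ds.save_as(d / "aaa_rogue.dcm", enforce_file_format=True)
        with pytest.raises(FormatError):
            load_dicom_series(d)

    def test_spatial_registration_round_trip(self, tmp_path):
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        # xyz-ordered 4x4 matrix: rotation about patient z + translation
        a = 0.1
        mat = np.eye(4)
        mat[:3, :3] = [
            [np.cos(a), -np.sin(a), 0],
            [np.sin(a), np.cos(a), 0],
            [0, 0, 1],
        ]
        mat[:3, 3] = [4.0, -1.5, 2.0]

        inner = Dataset()
        inner.FrameOfReferenceTransformationMatrixType = "RIGID"
        inner.FrameOfReferenceTransformationMatrix = [float(v) for v in mat.ravel()]
        mreg = Dataset()
        mreg.MatrixSequence = [inner]
        reg = Dataset()
        reg.MatrixRegistrationSequence = [mreg]
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.RegistrationSequence = [reg]
        ds.save_as(tmp_path / "reg.dcm", enforce_file_format=True)

        tfm = load_dicom_registration(tmp_path / "reg.dcm")
        # a point mapped in xyz must match the zyx-ordered transform
        p_xyz = np.array([10.0, 20.0, 30.0])
        expected = mat[:3, :3] @ p_xyz + mat[:3, 3]
        got = tfm.apply(p_xyz[::-1])[::-1]
        assert np.abs(got - expected).max() < 1e-9

    def test_rtstruct_square_contour(self, tmp_path):
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        grid = VolumeGrid(np.zeros((3, 10, 10)), (3.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        # square covering pixel centres x,y in [4, 12] mm on slice z=3
        square = [5, 3, 13, 3, 13, 13, 5, 13]  # x1 y1 x2 y2 ... (closed implicitly)
        contour_data = []
        for x, y in zip(square[::2], square[1::2]):
            contour_data += [float(x) - 1.2, float(y) - 1.2, 3.0]

        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = "External"
        contour = Dataset()
        contour.ContourData = contour_data
        contour.ContourGeometricType = "CLOSED_PLANAR"
        rc = Dataset()
        rc.ReferencedROINumber = 1
        rc.ContourSequence = [contour]
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.StructureSetROISequence = [roi]
        ds.ROIContourSequence = [rc]
        ds.save_as(tmp_path / "rs.dcm", enforce_file_format=True)

        mask = rtstruct_to_mask(tmp_path / "rs.dcm", grid)
        assert mask.data[0].sum() == 0 and mask.data[2].sum() == 0
        rows, cols = np.nonzero(mask.data[1])
        # pixel centres (2 mm pitch) strictly inside [3.8, 11.8] x [1.8, 11.8] mm
        assert rows.min() == 1 and rows.max() == 5
        assert cols.min() == 2 and cols.max() == 5
        assert mask.data[1].sum() == 5 * 4


class TestMaskDilation:
    def test_zero_margin_is_identity(self):
        mask = MaskVolume(np.random.default_rng(1).random((6, 6, 6)) > 0.7)
        out = mask_from_external(mask, (1.0, 1.0, 1.0), 0.0)
        assert np.array_equal(out.data, mask.data)

    def test_single_seed_matches_distance_oracle(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        out = mask_from_external(MaskVolume(mask), (1.0, 1.0, 1.0), 2.0)
        zz, yy, xx = np.mgrid[0:9, 0:9, 0:9]
        dist = np.sqrt((zz - 4.0) ** 2 + (yy - 4.0) ** 2 + (xx - 4.0) ** 2)
        assert np.array_equal(out.data, dist <= 2.0 + 1e-9)

    def test_anisotropic_spacing_respected(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        out = mask_from_external(MaskVolume(mask), (4.0, 1.0, 1.0), 4.0)
        assert out.data[3, 4, 4] and out.data[5, 4, 4]  # one coarse step = 4 mm
        assert not out.data[2, 4, 4]  # two steps = 8 mm > margin
        assert out.data[4, 4, 8] and out.data[4, 0, 4]  # 4 fine steps = 4 mm

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=6.0),
        b=st.floats(min_value=0.0, max_value=6.0),
    )
    def test_dilation_monotone_in_margin(self, a, b):
        lo, hi = sorted((a, b))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3:5, 2:6, 3:4] = True
        small = mask_from_external(MaskVolume(mask), (2.0, 2.0, 2.0), lo)
        big = mask_from_external(MaskVolume(mask), (2.0, 2.0, 2.0), hi)
        assert np.all(big.data[small.data])

    def test_empty_mask_rejected(self):
        with pytest.raises(PreconditionError, match="empty"):
            mask_from_external(MaskVolume(np.zeros((4, 4, 4), dtype=bool)), (1, 1, 1), 5.0)


class TestResample:
    def test_identity_on_coincident_grids_is_exact(self):
        vol = ramp_volume(shape=(5, 6, 7))
        out = resample_onto(vol, identity_transform(), vol)
        assert np.array_equal(out.data, vol.data)

    def test_one_voxel_translation_matches_index_shift(self):
        rng = np.random.default_rng(3)
        vol = VolumeGrid(rng.normal(0, 100, (6, 6, 6)), (2.0, 3.0, 4.0), (0.0, 0.0, 0.0))
        t = RigidTransform(np.eye(3), [2.0, 0.0, 0.0])  # +1 voxel along slice axis
        out = resample_onto(vol, t, vol, fill_value=-1000.0)
        assert np.array_equal(out.data[1:], vol.data[:-1])
        assert np.all(out.data[0] == -1000.0)

    def test_double_half_turn_is_identity_within_interp_tolerance(self, quiet_phantom):
        course = generate_course(
            quiet_phantom, CourseSpec(n_fractions=2, cbct_schedule="daily", setup_jitter_mm=0.0, seed=0)
        )
        vol = course.acquisitions[0].volume
        half_turn = RigidTransform(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
        once = resample_onto(vol, half_turn, vol)
        twice = resample_onto(once, half_turn, vol)
        assert np.abs(twice.data - vol.data).max() < 1.0

    def test_mask_resampling_is_order_preserving(self):
        mask = np.zeros((6, 6, 6))
        mask[2:4, 2:4, 2:4] = 1.0
        vol = VolumeGrid(mask, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        t = RigidTransform(np.eye(3), [0.5, 0.0, 0.0])
        out = resample_onto(vol, t, vol, fill_value=0.0, interpolation="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}
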
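"""DICOM discovery, assembly, ordering, and attribute extraction."""

import shutil

import numpy as np
import pydicom
import pytest

from mriqa import phantom, volume_io


@pytest.fixture(scope="module")
def small_study():
    spec = phantom.default_breast_spec(shape=(6, 32, 32), seed=3)
    return phantom.make_dce_study(spec)


@pytest.fixture()
def study_dir(small_study, tmp_path):
    phantom.write_dicom_series(small_study, tmp_path / "study")
    return tmp_path / "study"


class TestDiscovery:
    def test_conventional_single_directory(self, study_dir):
        descriptors = volume_io.discover_inputs(study_dir / "t0", "Conventional")
        assert len(descriptors) == 1
        assert len(descriptors[0].files[0]) == 6

    def test_dce_groups_seven_timepoints_in_order(self, study_dir):
        descriptors = volume_io.discover_inputs(study_dir, "DCE")
        assert len(descriptors) == 1
        assert [d.name for d in descriptors[0].directories] == \
            [f"t{i}" for i in range(7)]

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(volume_io.SeriesReadError, match="no DICOM series"):
            volume_io.discover_inputs(tmp_path, "Conventional")

    def test_mixed_files_and_directories_rejected(self, study_dir):
        stray = study_dir / "stray.dcm"
        shutil.copy(study_dir / "t0" / "slice000.dcm", stray)
        with pytest.raises(volume_io.SeriesReadError, match="stray.dcm"):
            volume_io.discover_inputs(study_dir, "DCE")

    def test_timepoints_reordered_by_acquisition_time(self, small_study, tmp_path):
        # write phases under names whose lexicographic order disagrees
        # with their acquisition times
        root = tmp_path / "scrambled"
        for name, t in (("a", 2), ("b", 0), ("c", 1)):
            phantom.write_dicom_series(small_study.timepoints[t], root / name)
        # patch acquisition times so a,b,c carry 180 s, 0 s, 90 s
        for name, seconds in (("a", 180.0), ("b", 0.0), ("c", 90.0)):
            for f in sorted((root / name).iterdir()):
                ds = pydicom.dcmread(f)
                ds.AcquisitionTime = phantom._format_acquisition_time(seconds)
                ds.save_as(f, enforce_file_format=True)
        descriptor = volume_io.discover_inputs(root, "DCE")[0]
        assert [d.name for d in descriptor.directories] == ["b", "c", "a"]


class TestReading:
    def test_roundtrip_preserves_pixels_within_quantisation(self, small_study,
                                                            study_dir):
        back = volume_io.read_series(volume_io.discover_inputs(study_dir, "DCE")[0])
        assert back.n_timepoints == small_study.n_timepoints
        for t in range(small_study.n_timepoints):
            a = small_study.timepoints[t].to_array()
            b = back.timepoints[t].to_array()
            step = (a.max() - a.min()) / 65535.0
            rms = np.sqrt(np.mean((a - b) ** 2))
            assert rms <= step / 2

    def test_slices_sorted_by_position(self, small_study, tmp_path):
        vol = small_study.timepoints[0]
        out = tmp_path / "shuffled"
        phantom.write_dicom_series(vol, out)
        # shuffle file names so directory order disagrees with geometry
        files = sorted(out.iterdir())
        renamed = [f.with_name(f"z{i}_{f.name}") for i, f in enumerate(files)]
        rng = np.random.default_rng(0)
        for f, target in zip(files, rng.permutation(renamed)):
            f.rename(target)
        back = volume_io.read_series(
            volume_io.discover_inputs(out, "Conventional")[0])
        locations = [s.slice_location for s in back.slices]
        assert locations == sorted(locations)
        assert np.allclose(back.to_array(), vol.to_array(), atol=0.05)

    def test_non_dicom_file_skipped_with_warning(self, study_dir):
        (study_dir / "t0" / "notes.txt").write_text("not dicom")
        with pytest.warns(UserWarning, match="notes.txt"):
            back = volume_io.read_series(
                volume_io.discover_inputs(study_dir / "t0", "Conventional")[0])
        assert back.n_slices == 6

    def test_unequal_timepoint_slice_counts_rejected(self, study_dir):
        extra = sorted((study_dir / "t1").iterdir())[-1]
        extra.unlink()
        with pytest.raises(volume_io.SeriesReadError, match="slices"):
            volume_io.read_series(volume_io.discover_inputs(study_dir, "DCE")[0])

    def test_inconsistent_inplane_dims_rejected(self, study_dir, tmp_path):
        spec = phantom.default_breast_spec(shape=(1, 16, 16), seed=0)
        odd_vol = phantom.make_volume(spec)
        out = tmp_path / "mixed"
        out.mkdir()
        for f in (study_dir / "t0").iterdir():
            shutil.copy(f, out / f.name)
        phantom.write_dicom_series(odd_vol, tmp_path / "odd")
        odd_file = out / "odd.dcm"
        shutil.copy(next((tmp_path / "odd").iterdir()), odd_file)
        ds = pydicom.dcmread(odd_file)
        ds.ImagePositionPatient = [0, 0, 999]   # distinct slice position
        ds.SliceLocation = 999
        ds.InstanceNumber = 99
        ds.save_as(odd_file, enforce_file_format=True)
        with pytest.raises(volume_io.SeriesReadError, match="dims"):
            volume_io.read_series(
                volume_io.discover_inputs(out, "Conventional")[0])


class TestAttributes:
    def test_written_header_fields_echoed(self, study_dir):
        vol = volume_io.read_series(
            volume_io.discover_inputs(study_dir / "t0", "Conventional")[0])
        attrs = volume_io.extract_attributes(vol)
        assert attrs.repetition_time_ms == pytest.approx(4.5)
        assert attrs.echo_time_ms == pytest.approx(1.8)
        assert attrs.slice_thickness_mm == pytest.approx(2.0)
        assert attrs.field_strength_T == pytest.approx(3.0)
        assert attrs.manufacturer == "mriqa phantom"

    def test_missing_tag_stays_absent(self, study_dir):
        for f in sorted((study_dir / "t0").iterdir()):
            ds = pydicom.dcmread(f)
            del ds.MagneticFieldStrength
            ds.save_as(f, enforce_file_format=True)
        vol = volume_io.read_series(
            volume_io.discover_inputs(study_dir / "t0", "Conventional")[0])
        attrs = volume_io.extract_attributes(vol)
        assert attrs.field_strength_T is None
        assert "field_strength_T" not in attrs.as_dict()

    def test_positive_invariant_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            volume_io.AttributeSummary(repetition_time_ms=-1.0)


class TestInvariants:
    def test_slice_minimum_size(self):
        with pytest.raises(ValueError, match="8x8"):
            volume_io.ImageSlice(pixels=np.zeros((4, 4)))

    def test_nonfinite_pixels_rejected(self):
        bad = np.zeros((16, 16))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            volume_io.ImageSlice(pixels=bad)

    def test_study_needs_two_timepoints(self, small_study):
        with pytest.raises(ValueError, match="2 timepoints"):
            volume_io.DynamicStudy(timepoints=[small_study.timepoints[0]])

    def test_rescale_applied_exactly_once(self, tmp_path):
        """Stored integers times slope plus intercept equal returned floats."""
        spec = phantom.default_breast_spec(shape=(2, 16, 16), seed=9)
        vol = phantom.make_volume(spec)
        phantom.write_dicom_series(vol, tmp_path / "v")
        f = sorted((tmp_path / "v").iterdir())[0]
        ds = pydicom.dcmread(f)
        manual = ds.pixel_array * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        back = volume_io.read_series(
            volume_io.discover_inputs(tmp_path / "v", "Conventional")[0])
        assert np.allclose(back.slices[0].pixels, manual)
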
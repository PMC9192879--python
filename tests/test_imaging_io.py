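"""Round-trips and frame consistency for every reader/writer pair."""

import json

import numpy as np
import pytest
import pydicom
import trimesh

from condylar.imaging_io import (
    BinaryMask,
    CtVolume,
    LandmarkSet,
    SurfaceMesh,
    VolumeLoadError,
    read_landmarks,
    read_mesh,
    read_volume,
    write_dicom_series,
    write_landmarks,
    write_mesh,
    write_volume,
)
from condylar.morphometry import ramus_height
from condylar.imaging_io import LandmarkMissingError


@pytest.fixture()
def small_volume(rng):
    data = rng.normal(300.0, 100.0, size=(11, 9, 7)).astype(np.float32)
    return CtVolume(data, spacing=(0.5, 0.6, 0.7), origin=(-3.0, 2.0, 10.0))


def test_nifti_round_trip_identity(tmp_path, small_volume):
    path = tmp_path / "v.nii.gz"
    write_volume(small_volume, path)
    back = read_volume(path)
    assert back.shape == small_volume.shape
    np.testing.assert_allclose(back.data, small_volume.data, rtol=0, atol=1e-5)
    np.testing.assert_allclose(back.spacing, small_volume.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, small_volume.origin, atol=1e-5)
    assert back.orientation.startswith("LPS")


def test_dicom_series_round_trip_within_rounding(tmp_path, small_volume):
    write_dicom_series(small_volume, tmp_path / "dcm")
    back = read_volume(tmp_path / "dcm")
    assert back.shape == small_volume.shape
    # int16 storage quantises to whole HU
    assert np.abs(back.data - small_volume.data).max() <= 0.5 + 1e-6
    np.testing.assert_allclose(back.origin, small_volume.origin, atol=1e-4)
    np.testing.assert_allclose(back.spacing, small_volume.spacing, atol=1e-6)


def test_dicom_rescale_slope_intercept_applied(tmp_path, small_volume):
    # stored 762 with slope 2 / intercept -1024 must read back as 500 HU
    d = tmp_path / "dcm"
    write_dicom_series(small_volume, d)
    for f in sorted(d.glob("*.dcm")):
        ds = pydicom.dcmread(str(f))
        ds.RescaleSlope = 2.0
        ds.RescaleIntercept = -1024.0
        arr = np.full((ds.Rows, ds.Columns), 762, dtype=np.int16)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(f))
    back = read_volume(d)
    np.testing.assert_allclose(back.data, 500.0, atol=1e-4)


def test_dicom_inconsistent_slice_spacing_rejected(tmp_path, small_volume):
    d = tmp_path / "dcm"
    write_dicom_series(small_volume, d)
    files = sorted(d.glob("*.dcm"))
    ds = pydicom.dcmread(str(files[3]))
    ds.ImagePositionPatient = [
        ds.ImagePositionPatient[0],
        ds.ImagePositionPatient[1],
        float(ds.ImagePositionPatient[2]) + 0.4,
    ]
    ds.save_as(str(files[3]))
    with pytest.raises(VolumeLoadError, match="slice spacing"):
        read_volume(d)


def test_voxel_center_maps_to_index(small_volume):
    idx = np.array([4, 2, 5])
    point = small_volume.index_to_physical(idx)
    np.testing.assert_allclose(small_volume.physical_to_index(point), idx, atol=1e-9)


def test_volume_validation():
    with pytest.raises(ValueError, match="positive"):
        CtVolume(np.zeros((2, 2, 2)), spacing=(1, -1, 1))
    with pytest.raises(ValueError, match="finite"):
        CtVolume(np.full((2, 2, 2), np.nan), spacing=(1, 1, 1))


def test_mask_congruence_check(small_volume):
    mask = BinaryMask(np.ones((2, 2, 2), bool), small_volume.spacing, small_volume.origin)
    with pytest.raises(ValueError, match="congruent"):
        mask.require_congruent(small_volume)


# ---------------------------------------------------------------------------
# meshes


def test_unit_cube_stl_round_trip(tmp_path):
    box = trimesh.creation.box(extents=(1, 1, 1))
    mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
    write_mesh(mesh, tmp_path / "cube.stl")
    back = read_mesh(tmp_path / "cube.stl").cleaned()
    assert back.n_faces == 12
    assert back.n_vertices == 8


def test_ply_scalar_channel_round_trip(tmp_path, rng):
    box = trimesh.creation.icosphere(subdivisions=2)
    scalars = rng.normal(size=len(box.vertices))
    mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces), scalars=scalars)
    write_mesh(mesh, tmp_path / "m.ply")
    back = read_mesh(tmp_path / "m.ply")
    assert back.scalars is not None
    np.testing.assert_allclose(back.scalars, scalars, atol=1e-6)


def test_stl_drops_scalars_with_warning(tmp_path):
    box = trimesh.creation.box()
    mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces),
                       scalars=np.zeros(len(box.vertices)))
    with pytest.warns(UserWarning, match="scalar"):
        write_mesh(mesh, tmp_path / "m.stl")
    assert read_mesh(tmp_path / "m.stl").scalars is None


def test_unparseable_mesh_rejected(tmp_path):
    bad = tmp_path / "bad.stl"
    bad.write_text("this is not an STL file")
    with pytest.raises(ValueError):
        read_mesh(bad)


# ---------------------------------------------------------------------------
# landmarks


def test_landmark_round_trip(tmp_path):
    ls = LandmarkSet({"condyle_apex": [0.0, 1.5, 2.0], "gonion_lowest": [1, 2, 3]})
    write_landmarks(ls, tmp_path / "lm.json")
    back = read_landmarks(tmp_path / "lm.json")
    for name in ls.points:
        np.testing.assert_allclose(back[name], ls[name])


def test_duplicate_landmark_name_rejected(tmp_path):
    path = tmp_path / "lm.json"
    path.write_text('{"condyle_apex": [0,0,0], "condyle_apex": [1,1,1]}')
    with pytest.raises(ValueError, match="duplicate"):
        read_landmarks(path)


def test_unknown_names_kept_but_flagged(tmp_path):
    path = tmp_path / "lm.json"
    path.write_text(json.dumps({"condyle_apex": [0, 0, 0], "mystery_point": [1, 1, 1]}))
    with pytest.warns(UserWarning, match="mystery_point"):
        ls = read_landmarks(path)
    assert "mystery_point" in ls


def test_missing_landmark_errors_at_measurement_time(tmp_path):
    path = tmp_path / "lm.json"
    path.write_text(json.dumps({"condyle_apex": [0, 0, 0]}))
    ls = read_landmarks(path)  # load succeeds
    with pytest.raises(LandmarkMissingError, match="landmark missing: gonion_lowest"):
        ramus_height(ls)


def test_study_save_load_round_trip(tmp_path, phantom_t0_coarse):
    _, study, _ = phantom_t0_coarse
    study.save(tmp_path / "study")
    from condylar.imaging_io import CondyleStudy

    back = CondyleStudy.load(tmp_path / "study")
    assert back.side == study.side and back.timepoint == study.timepoint
    np.testing.assert_allclose(back.volume.data, study.volume.data, atol=1e-3)
    assert back.mask.count() == study.mask.count()
    np.testing.assert_allclose(back.landmarks["condyle_apex"], study.landmarks["condyle_apex"])
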
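"""Spatial data model and file I/O for the condylar measurement pipeline.

All physical coordinates are expressed in the DICOM patient frame (LPS:
+x left, +y posterior, +z superior), in millimetres.  Voxel indices are
0-based and the grid is assumed axis-aligned: the centre of voxel
``(i, j, k)`` sits at ``origin + index * spacing``.  NIfTI files (RAS
convention) are converted to this internal LPS frame on load and back on
save; the ``orientation`` tag records the convention the array is in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
import trimesh

__all__ = [
    "CtVolume",
    "BinaryMask",
    "SurfaceMesh",
    "LandmarkSet",
    "CondyleStudy",
    "LandmarkMissingError",
    "VolumeLoadError",
    "read_volume",
    "write_volume",
    "write_dicom_series",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]

HU_MIN, HU_MAX = -1024.0, 4000.0

#: Names a complete landmark set provides.  ``<side>`` is ``left`` or
#: ``right``.  Scene-level names (foramen, both condylar centres) may be
#: shared between the two sides of one patient.
REQUIRED_LANDMARKS = (
    "condyle_apex",
    "gonion_lowest",
    "condyle_center_left",
    "condyle_center_right",
    "foramen_magnum_anterior",
    "transverse_medial",
    "transverse_lateral",
    "ramus_axis_inferior",
    "ramus_axis_superior",
)


class LandmarkMissingError(KeyError):
    """A measurement requested a landmark the set does not contain."""


class VolumeLoadError(RuntimeError):
    """A volume could not be read as a consistent CT grid."""


# ---------------------------------------------------------------------------
# volume


@dataclass
class CtVolume:
    """A CT-like voxel grid carrying Hounsfield intensities.

    Parameters
    ----------
    data:
        3-D array of HU values, indexed ``[i, j, k]`` along (x, y, z).
    spacing:
        Voxel spacing per axis in mm, strictly positive.
    origin:
        Physical coordinate (mm, LPS) of the centre of voxel (0, 0, 0).
    orientation:
        Frame tag; ``"LPS"`` is the native internal convention, volumes
        loaded from NIfTI carry ``"LPS(from-RAS)"`` for provenance.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "LPS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("CtVolume.data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if not self.orientation.startswith("LPS"):
            raise ValueError(f"unsupported orientation tag {self.orientation!r}")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN - 0.5 or hi > HU_MAX + 0.5:
            warnings.warn(
                f"intensity range [{lo:.0f}, {hi:.0f}] outside the plausible "
                f"HU range [{HU_MIN:.0f}, {HU_MAX:.0f}]",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to LPS mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map LPS mm coordinates to fractional voxel indices."""
        return (np.asarray(point, float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A boolean voxel grid congruent with a :class:`CtVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask.data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())

    def congruent_with(self, volume: "CtVolume | BinaryMask") -> bool:
        return (
            self.shape == volume.shape
            and np.allclose(self.spacing, volume.spacing)
            and np.allclose(self.origin, volume.origin)
        )

    def require_congruent(self, volume: "CtVolume | BinaryMask") -> None:
        if not self.congruent_with(volume):
            raise ValueError("mask is not congruent with volume (shape/spacing/origin)")


# ---------------------------------------------------------------------------
# mesh


@dataclass
class SurfaceMesh:
    """Triangle surface in patient-frame millimetres.

    ``scalars`` optionally carries one per-vertex channel (the signed
    apposition/resorption distance, mm); it survives PLY round-trips but
    not STL, which has no per-vertex attributes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None
    scalar_name: str = "signed_distance_mm"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=np.float64).reshape(-1)
            if len(self.scalars) != n:
                raise ValueError("scalars must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, scalars: np.ndarray | None = None) -> "SurfaceMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces), scalars=scalars)

    def cleaned(self) -> "SurfaceMesh":
        """Weld duplicate vertices and drop degenerate (zero-area) faces."""
        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=True)
        tm.update_faces(tm.nondegenerate_faces())
        tm.remove_unreferenced_vertices()
        return SurfaceMesh.from_trimesh(tm)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        v = trimesh.transformations.transform_points(self.vertices, matrix)
        return replace(self, vertices=v)


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkSet:
    """Named anatomical points in patient-frame millimetres."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.isfinite(arr).all():
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            clean[str(name)] = arr
        self.points = clean

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkMissingError(f"landmark missing: {name}") from None

    def get(self, name: str, side: str | None = None) -> np.ndarray:
        """Look up ``name``; with ``side`` given, prefer ``name_<side>``."""
        if side is not None and f"{name}_{side}" in self.points:
            return self.points[f"{name}_{side}"]
        return self[name]

    def with_point(self, name: str, point: np.ndarray) -> "LandmarkSet":
        pts = dict(self.points)
        pts[name] = np.asarray(point, float)
        return LandmarkSet(pts)

    def unknown_names(self) -> list[str]:
        """Names outside the documented vocabulary (kept, but flagged)."""
        known = set(REQUIRED_LANDMARKS) | {
            f"{n}_{s}" for n in REQUIRED_LANDMARKS for s in ("left", "right")
        }
        return sorted(set(self.points) - known)

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        pts = np.array(list(self.points.values()))
        moved = trimesh.transformations.transform_points(pts, matrix)
        return LandmarkSet(dict(zip(self.points, moved)))


@dataclass
class CondyleStudy:
    """One condyle at one timepoint: volume + mask + mesh + landmarks."""

    side: str
    timepoint: str
    volume: CtVolume
    mask: BinaryMask
    mesh: SurfaceMesh
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.timepoint not in ("T0", "T1"):
            raise ValueError("timepoint must be 'T0' or 'T1'")
        self.mask.require_congruent(self.volume)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_volume(self.volume, d / "volume.nii.gz")
        mask_vol = CtVolume(
            self.mask.data.astype(np.float32),
            self.mask.spacing,
            self.mask.origin,
        )
        write_volume(mask_vol, d / "mask.nii.gz")
        write_mesh(self.mesh, d / "mesh.ply")
        write_landmarks(self.landmarks, d / "landmarks.json")
        (d / "study.json").write_text(
            json.dumps({"side": self.side, "timepoint": self.timepoint}, indent=1)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "CondyleStudy":
        d = Path(directory)
        meta = json.loads((d / "study.json").read_text())
        volume = read_volume(d / "volume.nii.gz")
        mask_vol = read_volume(d / "mask.nii.gz")
        mask = BinaryMask(mask_vol.data > 0.5, mask_vol.spacing, mask_vol.origin)
        return cls(
            side=meta["side"],
            timepoint=meta["timepoint"],
            volume=volume,
            mask=mask,
            mesh=read_mesh(d / "mesh.ply"),
            landmarks=read_landmarks(d / "landmarks.json"),
        )


# ---------------------------------------------------------------------------
# volume I/O


def _read_nifti(path: Path) -> CtVolume:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS, affine close to diagonal
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-3):
        raise VolumeLoadError(f"{path}: oblique NIfTI orientations are not supported")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = np.abs(np.diag(rot))
    origin_ras = affine[:3, 3].copy()
    # RAS -> LPS: negate x and y; flip the arrays so spacing stays positive
    # with increasing index along +x(left) and +y(posterior).
    n = np.array(data.shape)
    data = data[::-1, ::-1, :].copy()
    origin = np.array(
        [
            -(origin_ras[0] + (n[0] - 1) * spacing[0]),
            -(origin_ras[1] + (n[1] - 1) * spacing[1]),
            origin_ras[2],
        ]
    )
    return CtVolume(data, tuple(spacing), tuple(origin), orientation="LPS(from-RAS)")


def _write_nifti(volume: CtVolume, path: Path) -> None:
    # Internal LPS grid -> RAS NIfTI with positive diagonal affine.
    data = volume.data[::-1, ::-1, :]
    n = np.array(volume.data.shape)
    sp = np.asarray(volume.spacing)
    o = np.asarray(volume.origin)
    origin_ras = np.array([-(o[0] + (n[0] - 1) * sp[0]), -(o[1] + (n[1] - 1) * sp[1]), o[2]])
    affine = np.diag([sp[0], sp[1], sp[2], 1.0])
    affine[:3, 3] = origin_ras
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def _check_dicom_series(files: list[Path]) -> None:
    """Fail early, naming the offending file, on inconsistent slice geometry."""
    headers = []
    for f in files:
        ds = pydicom.dcmread(str(f), stop_before_pixels=True)
        modality = getattr(ds, "Modality", "CT")
        if modality not in ("CT", "OT"):
            warnings.warn(f"{f.name}: modality {modality!r} is not CT; proceeding")
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is None:
            raise VolumeLoadError(f"{f}: missing ImagePositionPatient")
        headers.append((float(pos[2]), f))
    headers.sort()
    zs = np.array([z for z, _ in headers])
    if len(zs) > 2:
        dz = np.diff(zs)
        if dz.max() - dz.min() > 1e-3 * max(1.0, dz.mean()) + 1e-6:
            bad = headers[int(np.argmax(np.abs(dz - dz.mean()))) + 1][1]
            raise VolumeLoadError(f"inconsistent slice spacing near {bad}")


def _read_dicom_series(path: Path) -> CtVolume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise VolumeLoadError(f"{path}: no DICOM series found")
    _check_dicom_series([Path(f) for f in files])
    first = pydicom.dcmread(files[0], stop_before_pixels=True)
    if not hasattr(first, "RescaleSlope"):
        warnings.warn(f"{path}: no rescale tags; treating stored values as HU")
    reader.SetFileNames(files)
    img = reader.Execute()  # SimpleITK applies RescaleSlope/Intercept; LPS frame
    arr = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x)
    data = np.transpose(arr, (2, 1, 0))
    return CtVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()), orientation="LPS")


def read_volume(path: str | Path, format: str | None = None) -> CtVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Intensities are returned in HU (DICOM rescale slope/intercept
    applied) on the internal LPS grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz)."""
    _write_nifti(volume, Path(path))


def write_dicom_series(volume: CtVolume, directory: str | Path, series_uid: str | None = None) -> None:
    """Write a volume as an axial CT DICOM series (int16 stored values).

    Stored values are HU + 1024 with RescaleIntercept −1024 / slope 1, the
    common CT encoding; readers applying the rescale recover HU exactly up
    to integer rounding.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sp = volume.spacing
    if series_uid is None:
        series_uid = pydicom.uid.generate_uid()
    study_uid = pydicom.uid.generate_uid()
    frame_uid = pydicom.uid.generate_uid()
    stored = np.rint(volume.data + 1024.0).astype(np.int16)
    for k in range(volume.shape[2]):
        ds = pydicom.Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = pydicom.uid.generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * sp[2],
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sp[1], sp[0]]  # row spacing (y), column spacing (x)
        ds.SliceThickness = sp[2]
        ds.Rows = volume.shape[1]
        ds.Columns = volume.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        # rows are y, columns are x
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        pydicom.dcmwrite(str(d / f"slice_{k:04d}.dcm"), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# mesh I/O


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an STL or PLY surface; PLY per-vertex scalars are recovered."""
    path = Path(path)
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise ValueError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise ValueError(f"could not parse mesh file {path}")
    scalars = None
    for key, value in getattr(tm, "vertex_attributes", {}).items():
        if key == "signed_distance_mm":
            scalars = np.asarray(value, float)
    if scalars is None and path.suffix.lower() == ".ply":
        raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
        names = getattr(getattr(raw, "dtype", None), "names", None) or ()
        if raw is not None and "signed_distance_mm" in names:
            scalars = np.asarray(raw["signed_distance_mm"], float).reshape(-1)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), scalars=scalars)


def write_mesh(mesh: SurfaceMesh, path: str | Path, format: str | None = None) -> None:
    """Write STL or PLY.  STL cannot carry scalars: they are dropped with a warning."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    tm = mesh.to_trimesh()
    if fmt == "stl":
        if mesh.scalars is not None:
            warnings.warn("STL has no per-vertex attributes: scalar channel dropped")
        tm.export(str(path), file_type="stl")
    elif fmt == "ply":
        if mesh.scalars is not None:
            tm.vertex_attributes["signed_distance_mm"] = mesh.scalars.astype(np.float32)
        tm.export(str(path), file_type="ply", include_attributes=True)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# landmark I/O


def _reject_duplicates(pairs):
    seen = {}
    for key, value in pairs:
        if key in seen:
            raise ValueError(f"duplicate landmark name {key!r}")
        seen[key] = value
    return seen


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a ``{name: [x, y, z]}`` JSON landmark file (mm, patient frame)."""
    raw = json.loads(Path(path).read_text(), object_pairs_hook=_reject_duplicates)
    ls = LandmarkSet({name: np.asarray(p, float) for name, p in raw.items()})
    unknown = ls.unknown_names()
    if unknown:
        warnings.warn(f"unrecognised landmark names kept as-is: {', '.join(unknown)}")
    return ls


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload = {name: [float(v) for v in p] for name, p in landmarks.points.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
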
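"""Pre/post condylar surface comparison.

The post-operative mesh is rigidly registered onto the pre-operative one
(ICP, no scaling — remodelling must not be absorbed by a similarity
transform), per-vertex signed closest-point distances are computed
(positive = target outward along the reference outward normal =
apposition, rendered red; negative = resorption, blue), the condylar
surface is partitioned into the five anatomical regions (anterior,
posterior, medial, lateral, superior), and per-region mean distances are
reported.

Region rule: a vertex whose centroid-relative direction makes less than
45° with the superior axis is *superior*; every other vertex is labelled
by the azimuthal quadrant (90° sectors centred on the anterior, medial,
posterior and lateral axes) of its direction.  The partition is total and
equivariant under joint rigid motion of mesh and frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .imaging_io import LandmarkSet, SurfaceMesh
from .proximity import closest_point_on_surface, icp_point_to_surface

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "CondylarFrame",
    "DistanceMap",
    "SurfaceLabelField",
    "SURFACE_LABELS",
    "register_rigid",
    "signed_distances",
    "partition_condylar_surface",
    "per_surface_means",
    "export_colormap",
    "extract_head_submesh",
]

SURFACE_LABELS = ("anterior", "posterior", "medial", "lateral", "superior")

#: Vertices more than this far below the top of the moving mesh form the
#: "stable support" (ramus stump) used for registration when present.
SUPPORT_CAP_MM = 20.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, float)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms: float  # final RMS closest-point distance, mm
    n_support: int
    warning: bool = False  # set when the fit looks non-overlapping


@dataclass(frozen=True)
class CondylarFrame:
    """Orthonormal condylar directions (superior, anterior, medial)."""

    superior: np.ndarray
    anterior: np.ndarray
    medial: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self):
        s = _unit(self.superior)
        m = np.asarray(self.medial, float)
        m = _unit(m - np.dot(m, s) * s)
        a = np.asarray(self.anterior, float)
        a = _unit(a - np.dot(a, s) * s - np.dot(a, m) * m)
        object.__setattr__(self, "superior", s)
        object.__setattr__(self, "medial", m)
        object.__setattr__(self, "anterior", a)
        if self.center is not None:
            object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))

    @classmethod
    def from_landmarks(cls, landmarks: LandmarkSet, side: str) -> "CondylarFrame":
        """Frame from the ramus axis (superior) and transverse line (medial).

        ``anterior`` completes the frame; the cross-product order depends
        on the side because the medial direction mirrors across the
        midsagittal plane.
        """
        sup = landmarks.get("ramus_axis_superior", side) - landmarks.get("ramus_axis_inferior", side)
        med = landmarks.get("transverse_medial", side) - landmarks.get("transverse_lateral", side)
        sup = _unit(sup)
        med = _unit(med - np.dot(med, sup) * sup)
        ant = np.cross(med, sup) if side == "right" else np.cross(sup, med)
        return cls(
            superior=sup,
            anterior=ant,
            medial=med,
            center=landmarks.get("condyle_center", side),
        )

    def rotated(self, rotation: np.ndarray) -> "CondylarFrame":
        r = np.asarray(rotation, float)
        return CondylarFrame(
            r @ self.superior,
            r @ self.anterior,
            r @ self.medial,
            None if self.center is None else r @ self.center,
        )


@dataclass
class DistanceMap:
    """Per-vertex signed distances (mm) on a reference mesh."""

    distances: np.ndarray
    reference_timepoint: str = "T0"
    sign_convention: str = "positive=outward=apposition"

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float).reshape(-1)
        if not np.isfinite(self.distances).all():
            raise ValueError("distances must be finite")


@dataclass
class SurfaceLabelField:
    """Per-vertex region labels; a total partition of the mesh."""

    labels: np.ndarray  # array of strings from SURFACE_LABELS

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - set(SURFACE_LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate (zero-length) direction")
    return v / n


def _oriented_trimesh(mesh: SurfaceMesh) -> trimesh.Trimesh:
    """Trimesh copy with consistent outward-pointing normals."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.fix_normals()
    if not tm.is_winding_consistent:
        raise ValueError(
            "mesh normals are not consistently orientable; re-orient the mesh "
            "before computing signed distances"
        )
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return tm


# ---------------------------------------------------------------------------
# registration


def register_rigid(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    init: RigidTransform | None = None,
    support: str = "support",
    superior_axis: np.ndarray = (0.0, 0.0, 1.0),
    support_cap_mm: float = SUPPORT_CAP_MM,
    max_points: int = 2000,
    threshold: float = 1e-6,
    max_iterations: int = 300,
    sanity_rms_mm: float = 5.0,
    seed: int = 0,
) -> RegistrationResult:
    """Refine ``init`` by ICP so that ``moving`` maps onto ``fixed``.

    ``support="support"`` registers on the ramus stump — the moving
    vertices lying more than ``support_cap_mm`` below the mesh top along
    ``superior_axis`` — because remodelling is concentrated on the head;
    if the stump is absent (or ``support="full"``) the whole mesh is used.
    No scaling or reflection is ever applied.
    """
    if moving.n_vertices == 0 or fixed.n_vertices == 0:
        raise ValueError("cannot register empty meshes")
    if init is None:
        init = RigidTransform.identity()
    pts = np.asarray(moving.vertices, float)
    if support == "support":
        up = _unit(np.asarray(superior_axis, float))
        h = pts @ up
        stump = h < h.max() - support_cap_mm
        if stump.sum() >= 100:
            pts = pts[stump]
    elif support != "full":
        raise ValueError("support must be 'support' or 'full'")
    if len(pts) > max_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=max_points, replace=False)]
    fixed_tm = fixed.to_trimesh()
    matrix, rms, _ = icp_point_to_surface(
        pts,
        fixed_tm,
        initial=init.matrix,
        threshold=threshold,
        max_iterations=max_iterations,
    )
    transform = RigidTransform.from_matrix(matrix)
    warn = rms > sanity_rms_mm
    if warn:
        warnings.warn(f"registration RMS {rms:.2f} mm exceeds sanity bound; meshes may not overlap")
    return RegistrationResult(transform=transform, rms=rms, n_support=len(pts), warning=warn)


# ---------------------------------------------------------------------------
# signed distances


def signed_distances(reference: SurfaceMesh, target: SurfaceMesh) -> DistanceMap:
    """Signed closest-point distance from each reference vertex to the target surface.

    Point-to-surface (not point-to-vertex), so the result does not depend
    on the target's tessellation density.  The sign is positive where the
    target lies outward along the reference outward vertex normal.
    """
    ref_tm = _oriented_trimesh(reference)
    tgt_tm = _oriented_trimesh(target)
    closest, dist, _ = closest_point_on_surface(tgt_tm, np.asarray(reference.vertices, float))
    normals = np.asarray(ref_tm.vertex_normals)
    toward = closest - np.asarray(reference.vertices, float)
    sign = np.sign(np.einsum("ij,ij->i", toward, normals))
    sign[dist < 1e-12] = 0.0
    return DistanceMap(distances=sign * dist)


# ---------------------------------------------------------------------------
# parcellation


def partition_condylar_surface(
    mesh: SurfaceMesh,
    frame: CondylarFrame,
    centroid: np.ndarray | None = None,
) -> SurfaceLabelField:
    """Label every vertex with one of the five condylar surfaces.

    Directions are taken from ``centroid`` (default: the frame centre if
    set, else the vertex mean).
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh is empty")
    if centroid is None:
        centroid = frame.center if frame.center is not None else mesh.vertices.mean(axis=0)
    d = mesh.vertices - np.asarray(centroid, float)
    norms = np.linalg.norm(d, axis=1)
    norms[norms < 1e-12] = 1.0
    d = d / norms[:, None]
    up = d @ frame.superior
    az = np.degrees(np.arctan2(d @ frame.medial, d @ frame.anterior))
    labels = np.empty(mesh.n_vertices, dtype=object)
    labels[np.abs(az) <= 45.0] = "anterior"
    labels[(az > 45.0) & (az <= 135.0)] = "medial"
    labels[np.abs(az) > 135.0] = "posterior"
    labels[(az < -45.0) & (az >= -135.0)] = "lateral"
    labels[up > np.cos(np.radians(45.0))] = "superior"
    return SurfaceLabelField(labels=labels.astype(str))


def per_surface_means(distmap: DistanceMap, labels: SurfaceLabelField) -> dict[str, dict]:
    """Mean/sd/count of signed distance per anatomical surface.

    Surfaces with no vertices report ``mean``/``sd`` as NaN (missing).
    Full precision is retained; reports round to 2 decimals.
    """
    d = distmap.distances
    if len(d) != len(labels.labels):
        raise ValueError("distance map and label field refer to different meshes")
    out: dict[str, dict] = {}
    for name in SURFACE_LABELS:
        sel = d[labels.labels == name]
        out[name] = {
            "mean": float(sel.mean()) if len(sel) else float("nan"),
            "sd": float(sel.std(ddof=1)) if len(sel) > 1 else float("nan"),
            "n_vertices": int(len(sel)),
        }
    return out


def extract_head_submesh(
    mesh: SurfaceMesh,
    apex: np.ndarray,
    axis_down: np.ndarray,
    depth: float = 15.0,
) -> tuple[SurfaceMesh, np.ndarray]:
    """Faces whose vertices all lie within ``depth`` mm below the apex.

    Mirrors the volumetric ROI clip so surface statistics cover the same
    condylar head region.  Returns the submesh and the indices of its
    vertices in the parent mesh.
    """
    axis_down = _unit(np.asarray(axis_down, float))
    t = (mesh.vertices - np.asarray(apex, float)) @ axis_down
    keep_v = (t >= -1e-9) & (t < depth)
    keep_f = keep_v[mesh.faces].all(axis=1)
    if not keep_f.any():
        raise ValueError("head submesh is empty: check apex/axis/depth")
    used = np.unique(mesh.faces[keep_f])
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceMesh(
        vertices=mesh.vertices[used],
        faces=remap[mesh.faces[keep_f]],
        scalars=None if mesh.scalars is None else mesh.scalars[used],
    )
    return sub, used


# ---------------------------------------------------------------------------
# colour-map export


def export_colormap(
    mesh: SurfaceMesh,
    distmap: DistanceMap,
    path,
    dmax: float = 1.0,
) -> None:
    """Write a PLY with the signed-distance channel and a diverging colour map.

    Blue at ``-dmax`` (resorption) through white at 0 to red at ``+dmax``
    (apposition); distances are clamped symmetrically at ``±dmax``.
    """
    if len(distmap.distances) != mesh.n_vertices:
        raise ValueError("distance map is not defined on this mesh")
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    t = np.clip(distmap.distances / dmax, -1.0, 1.0)
    rgb = np.empty((mesh.n_vertices, 3))
    pos = t >= 0
    rgb[pos, 0] = 255.0
    rgb[pos, 1] = rgb[pos, 2] = 255.0 * (1.0 - t[pos])
    rgb[~pos, 2] = 255.0
    rgb[~pos, 0] = rgb[~pos, 1] = 255.0 * (1.0 + t[~pos])
    tm = mesh.to_trimesh()
    tm.visual.vertex_colors = np.rint(rgb).astype(np.uint8)
    tm.vertex_attributes["signed_distance_mm"] = distmap.distances.astype(np.float32)
    tm.export(str(path), file_type="ply", include_attributes=True)
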
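"""Synthetic condyle phantoms with exact ground truth.

The phantom is a deliberately schematic condyle: a capsule-shaped ramus
(cylinder with spherical caps) carrying an ellipsoidal condylar head,
voxelised into an HU volume with a constant cortical shell over a noisy
trabecular core, air outside.  Geometry is analytic throughout, so every
quantity the measurement pipeline estimates — ramus height,
intercondylar angle, coronal axis inclination, ROI volume, mean HU,
per-region surface offsets — has an exact (or quadrature-exact) recorded
truth value.

A pre→post remodelling step applies prescribed changes: a height change
(the head slides along the ramus axis), a coronal rotation of the head
(axis-inclination change), per-region radial surface offsets (blended
over a 10° band at region borders), a density scale factor with fresh
additive noise, and an intercondylar-angle change realised at the
landmark level (the contralateral condylar centre is a virtual scene
landmark; the angle measurement is purely landmark-based).

The head is a spheroid whose medio-lateral and supero-inferior semi-axes
are equal by default, so its coronal cross-section is circular and a
coronal rotation changes the landmark-based inclination without
deforming the surface — the rotation and surface-offset ground truths
stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from . import morphometry
from .imaging_io import BinaryMask, CondyleStudy, CtVolume, LandmarkSet, SurfaceMesh
from .surface_morphology import SURFACE_LABELS

__all__ = [
    "PhantomSpec",
    "RemodelSpec",
    "PhantomTruth",
    "generate_phantom",
    "apply_remodeling",
    "generate_cohort",
    "PhantomPatient",
    "COHORT_REMODEL_DISTRIBUTIONS",
]

AIR_HU = -1000.0
_REGION_BLEND_DEG = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy and imaging parameters of one synthetic condyle."""

    side: str = "right"
    ramus_length_mm: float = 47.0  # gonion-end to head centre along the axis
    #: ML and AP radii of the ramus cross-section.  Elliptical on purpose:
    #: a circular ramus would leave rotation about its own axis
    #: unconstrained during surface registration.
    ramus_radii_mm: tuple[float, float] = (6.0, 4.5)
    head_semiaxes_mm: tuple[float, float, float] = (9.0, 7.0, 9.0)  # ML, AP, SI
    head_tilt_deg: float = 15.0  # initial coronal tilt of the head
    #: The head sits slightly behind the ramus axis (breaks the 180°
    #: ambiguity of the elliptical ramus) while staying small enough that
    #: the apex-down-15 mm band remains purely ellipsoidal surface.
    head_posterior_offset_mm: float = 1.0
    cortical_thickness_mm: float = 1.5
    cortical_hu: float = 1400.0
    trabecular_hu: float = 550.0
    trabecular_sd: float = 50.0
    voxel_spacing_mm: float = 0.5
    margin_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        lengths = (
            self.ramus_length_mm,
            *self.ramus_radii_mm,
            *self.head_semiaxes_mm,
            self.cortical_thickness_mm,
            self.voxel_spacing_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom lengths must be positive")
        if self.cortical_hu <= self.trabecular_hu:
            raise ValueError("cortical HU must exceed the trabecular mean")
        if self.voxel_spacing_mm > self.cortical_thickness_mm:
            raise ValueError("voxel spacing too coarse to resolve the cortical shell")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class RemodelSpec:
    """Prescribed T0→T1 changes (the six-parameter ground truth)."""

    height_delta_mm: float = 0.0
    axis_rotation_deg: float = 0.0
    intercondylar_delta_deg: float = 0.0
    surface_offsets_mm: dict = field(default_factory=dict)  # region -> mm
    density_scale: float = 1.0
    hu_noise_sd: float = 0.0

    def __post_init__(self):
        bad = set(self.surface_offsets_mm) - set(SURFACE_LABELS)
        if bad:
            raise ValueError(f"unknown surface regions {bad}")
        if any(abs(v) > 2.0 for v in self.surface_offsets_mm.values()):
            raise ValueError("surface offsets must lie within ±2 mm")
        if not (0.0 < self.density_scale <= 2.0):
            raise ValueError("density scale must lie in (0, 2]")

    def offsets_vector(self) -> np.ndarray:
        return np.array([self.surface_offsets_mm.get(r, 0.0) for r in SURFACE_LABELS])


@dataclass
class PhantomTruth:
    """Exact realised parameter values at T0 and (after remodelling) T1."""

    height_mm: dict
    intercondylar_deg: dict
    axis_inclination_deg: dict
    roi_volume_mm3: dict
    roi_mean_hu: dict
    surface_offsets_mm: dict  # timepoint -> {region: mm}
    scene_params: dict

    def delta(self, name: str):
        a = getattr(self, name)
        if a.get("T1") is None:
            raise ValueError(f"{name}: no T1 value recorded yet")
        return a["T1"] - a["T0"]


# ---------------------------------------------------------------------------
# analytic scene


def _smoothstep01(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


class _Scene:
    """Analytic right-condyle geometry; left sides mirror x on evaluation."""

    def __init__(self, spec: PhantomSpec, head_shift_mm: float = 0.0,
                 head_tilt_deg: float | None = None,
                 offsets: np.ndarray | None = None):
        self.spec = spec
        self.mirror = spec.side == "left"
        self.L = spec.ramus_length_mm
        self.rx, self.ry = spec.ramus_radii_mm
        self.rb = min(self.rx, self.ry)  # bottom-cap radius / sdf scale
        self.a, self.b, self.c = spec.head_semiaxes_mm
        self.tilt = np.radians(spec.head_tilt_deg if head_tilt_deg is None else head_tilt_deg)
        self.center = np.array([0.0, spec.head_posterior_offset_mm, self.L + head_shift_mm])
        self.offsets = np.zeros(len(SURFACE_LABELS)) if offsets is None else np.asarray(offsets, float)
        if np.any(min(self.a, self.b, self.c) + self.offsets <= 0.5):
            raise ValueError("surface offsets would collapse (self-intersect) the head")
        # canonical right-side condylar frame for offset regions (fixed, not tilted)
        self.f_superior = np.array([0.0, 0.0, 1.0])
        self.f_medial = np.array([1.0, 0.0, 0.0])
        self.f_anterior = np.array([0.0, -1.0, 0.0])
        t = self.tilt  # head rotation about the AP (y) axis
        self.R_head = np.array(
            [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
        )

    # -- geometry in canonical (right-side) coordinates

    def _canon(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        if self.mirror:
            pts = pts * np.array([-1.0, 1.0, 1.0])
        return pts

    def _world(self, pts: np.ndarray) -> np.ndarray:
        if self.mirror:
            return np.asarray(pts, float) * np.array([-1.0, 1.0, 1.0])
        return np.asarray(pts, float)

    def _capsule_sdf(self, pts: np.ndarray) -> np.ndarray:
        """Pseudo-sdf of the elliptical-section ramus with rounded ends.

        Exact zero level set; the scaled quadratic form underestimates
        interior depth slightly, which only pads the cortical shell.
        """
        z = pts[:, 2]
        dz = np.where(z < 0, z, np.where(z > self.L, z - self.L, 0.0)) / self.rb
        q = np.sqrt((pts[:, 0] / self.rx) ** 2 + (pts[:, 1] / self.ry) ** 2 + dz**2)
        return (q - 1.0) * self.rb

    def _region_weights(self, u: np.ndarray) -> np.ndarray:
        """Smooth per-region weights (N, 5) ordered like SURFACE_LABELS."""
        band = _REGION_BLEND_DEG
        elev = np.degrees(np.arccos(np.clip(u @ self.f_superior, -1.0, 1.0)))
        w_sup = _smoothstep01((45.0 - elev) / band + 0.5)
        az = np.degrees(np.arctan2(u @ self.f_medial, u @ self.f_anterior))
        centers = {"anterior": 0.0, "medial": 90.0, "posterior": 180.0, "lateral": -90.0}
        w_az = np.zeros((len(u), 4))
        for j, name in enumerate(("anterior", "posterior", "medial", "lateral")):
            d = np.abs((az - centers[name] + 180.0) % 360.0 - 180.0)
            w_az[:, j] = _smoothstep01((45.0 - d) / band + 0.5)
        total = w_az.sum(axis=1)
        total[total < 1e-9] = 1.0
        w_az /= total[:, None]
        out = np.zeros((len(u), 5))
        out[:, :4] = w_az * (1.0 - w_sup)[:, None]
        out[:, 4] = w_sup
        return out

    def _head_radius(self, u: np.ndarray) -> np.ndarray:
        """Radial surface distance from the head centre along unit dirs ``u``."""
        up = u @ self.R_head  # components in the head frame (R^T u)
        base = 1.0 / np.sqrt(
            (up[:, 0] / self.a) ** 2 + (up[:, 1] / self.b) ** 2 + (up[:, 2] / self.c) ** 2
        )
        if np.any(self.offsets != 0.0):
            base = base + self._region_weights(u) @ self.offsets
        return base

    def _head_sdf(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        rho = np.linalg.norm(d, axis=1)
        safe = np.where(rho < 1e-9, 1.0, rho)
        u = d / safe[:, None]
        u[rho < 1e-9] = [0.0, 0.0, 1.0]
        return rho - self._head_radius(u)

    def sdf(self, world_pts: np.ndarray) -> np.ndarray:
        pts = self._canon(world_pts)
        return np.minimum(self._capsule_sdf(pts), self._head_sdf(pts))

    def inside(self, world_pts: np.ndarray) -> np.ndarray:
        return self.sdf(world_pts) < 0.0

    # -- landmarks (canonical, then mirrored to world)

    def _apex_canonical(self) -> np.ndarray:
        # topmost point of the (unoffset) ellipsoid ...
        D = np.diag([self.a, self.b, self.c])
        v = D @ self.R_head.T @ np.array([0.0, 0.0, 1.0])
        p = self.R_head @ D @ (v / np.linalg.norm(v))
        # ... displaced radially by the local (superior-region) offset
        u = p / np.linalg.norm(p)
        off = float((self._region_weights(u[None, :]) @ self.offsets)[0])
        return self.center + p + off * u

    def landmarks(self) -> LandmarkSet:
        sp = self.spec
        med = self.f_medial
        apex = self._apex_canonical()
        trans_dir = self.R_head @ np.array([1.0, 0.0, 0.0])
        if trans_dir @ med < 0:
            trans_dir = -trans_dir  # orient lateral -> medial
        center = self.center
        own = sp.side
        other = "left" if own == "right" else "right"
        foramen = np.array([40.0, -28.0, self.L])
        contralateral = np.array([80.0, 0.0, self.L])
        pts = {
            "condyle_apex": apex,
            "gonion_lowest": np.array([0.0, 0.0, -self.rb]),
            f"condyle_center_{own}": center,
            f"condyle_center_{other}": contralateral,
            "foramen_magnum_anterior": foramen,
            "transverse_medial": center + self.a * trans_dir,
            "transverse_lateral": center - self.a * trans_dir,
            "ramus_axis_inferior": np.array([0.0, 0.0, 5.0]),
            "ramus_axis_superior": np.array([0.0, 0.0, 40.0]),
        }
        return LandmarkSet({k: self._world(v) for k, v in pts.items()})

    # -- rasterisation

    def grid(self) -> tuple[np.ndarray, tuple]:
        sp = self.spec
        h = sp.voxel_spacing_mm
        m = sp.margin_mm
        ext = max(self.a, self.c) + max(abs(float(self.offsets.max(initial=0.0))), 0.0)
        xr = max(ext, self.rx) + m
        yr = max(self.b + abs(self.center[1]), self.ry) + m
        zlo, zhi = -self.rb - m, self.center[2] + self.c + 2.0 + m
        nx = int(np.ceil(2 * xr / h)) + 1
        ny = int(np.ceil(2 * yr / h)) + 1
        nz = int(np.ceil((zhi - zlo) / h)) + 1
        origin = (-xr, -yr, zlo)
        xs = origin[0] + np.arange(nx) * h
        ys = origin[1] + np.arange(ny) * h
        zs = origin[2] + np.arange(nz) * h
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        return pts.reshape(nx, ny, nz, 3), origin

    def quadrature_roi(self, depth: float = 15.0, refine: int = 2) -> tuple[float, float]:
        """ROI volume (mm^3) and expected mean HU by fine-grid quadrature."""
        sp = self.spec
        h = sp.voxel_spacing_mm / refine
        apex = self._apex_canonical()
        ext = max(self.a, self.c) + 1.0 + abs(float(np.abs(self.offsets).max(initial=0.0)))
        xs = np.arange(-ext, ext + h, h)
        yext = max(self.b + abs(self.center[1]), self.ry) + 1.0
        ys = np.arange(-yext, yext + h, h)
        zs = np.arange(apex[2] - depth + h / 2.0, apex[2], h)  # slab [0, depth) below apex
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        s = np.minimum(self._capsule_sdf(pts), self._head_sdf(pts))
        inside = s < 0.0
        shell = inside & (s > -sp.cortical_thickness_mm)
        n_in = int(inside.sum())
        if n_in == 0:
            raise ValueError("empty quadrature ROI")
        f_cort = shell.sum() / n_in
        volume = n_in * h**3
        mean_hu = f_cort * sp.cortical_hu + (1.0 - f_cort) * sp.trabecular_hu
        return float(volume), float(mean_hu)


def _rasterize(scene: _Scene, rng: np.random.Generator,
               hu_scale: float = 1.0, extra_noise_sd: float = 0.0) -> tuple[CtVolume, BinaryMask, SurfaceMesh]:
    sp = scene.spec
    pts, origin = scene.grid()
    nx, ny, nz, _ = pts.shape
    s = scene.sdf(pts.reshape(-1, 3)).reshape(nx, ny, nz)
    inside = s < 0.0
    hu = np.full(inside.shape, AIR_HU, dtype=np.float32)
    trab = rng.normal(hu_scale * sp.trabecular_hu, hu_scale * sp.trabecular_sd, size=int(inside.sum()))
    hu[inside] = trab.astype(np.float32)
    shell = inside & (s > -sp.cortical_thickness_mm)
    hu[shell] = np.float32(hu_scale * sp.cortical_hu)
    if extra_noise_sd > 0:
        hu[inside] += rng.normal(0.0, extra_noise_sd, size=int(inside.sum())).astype(np.float32)
    np.clip(hu, -1024.0, 4000.0, out=hu)
    spacing = (sp.voxel_spacing_mm,) * 3
    volume = CtVolume(hu, spacing, origin)
    mask = BinaryMask(inside, spacing, origin)
    # isosurface of the sampled signed-distance grid (sub-voxel accurate,
    # same provenance as the mask = sdf < 0)
    verts, faces, _, _ = skmeasure.marching_cubes(s, level=0.0, spacing=spacing)
    mesh = SurfaceMesh(vertices=verts + np.asarray(origin), faces=faces).cleaned()
    return volume, mask, mesh


def _truth_from_scene(scene: _Scene, timepoint: str, truth: PhantomTruth | None = None) -> PhantomTruth:
    lm = scene.landmarks()
    side = scene.spec.side
    height = morphometry.ramus_height(lm, side).value
    inter = morphometry.intercondylar_angle(lm).value
    incl = morphometry.axis_inclination_from_landmarks(lm, side).value
    vol, mean_hu = scene.quadrature_roi()
    offsets = {r: float(o) for r, o in zip(SURFACE_LABELS, scene.offsets)}
    if truth is None:
        truth = PhantomTruth(
            height_mm={}, intercondylar_deg={}, axis_inclination_deg={},
            roi_volume_mm3={}, roi_mean_hu={}, surface_offsets_mm={},
            scene_params={"side": side, "spacing": scene.spec.voxel_spacing_mm},
        )
    truth.height_mm[timepoint] = height
    truth.intercondylar_deg[timepoint] = inter
    truth.axis_inclination_deg[timepoint] = incl
    truth.roi_volume_mm3[timepoint] = vol
    truth.roi_mean_hu[timepoint] = mean_hu
    truth.surface_offsets_mm[timepoint] = offsets
    return truth


def generate_phantom(spec: PhantomSpec) -> tuple[CondyleStudy, PhantomTruth]:
    """Voxelise the T0 phantom and record its exact ground truth."""
    scene = _Scene(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    volume, mask, mesh = _rasterize(scene, rng)
    truth = _truth_from_scene(scene, "T0")
    study = CondyleStudy(
        side=spec.side, timepoint="T0",
        volume=volume, mask=mask, mesh=mesh, landmarks=scene.landmarks(),
    )
    return study, truth


def _rotate_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _adjust_intercondylar(lm: LandmarkSet, own_side: str, target_deg: float) -> LandmarkSet:
    """Move the virtual contralateral centre so the angle is exactly ``target_deg``."""
    other = "left" if own_side == "right" else "right"
    v = lm["foramen_magnum_anterior"]
    arm1 = lm[f"condyle_center_{own_side}"] - v
    arm2 = lm[f"condyle_center_{other}"] - v
    current = morphometry.intercondylar_angle(lm).value
    rho = np.radians(target_deg - current)
    n = np.cross(arm1, arm2)
    if np.linalg.norm(n) < 1e-9:
        raise ValueError("degenerate intercondylar geometry (collinear arms)")
    new_arm2 = _rotate_about(n, rho) @ arm2
    return lm.with_point(f"condyle_center_{other}", v + new_arm2)


def apply_remodeling(
    study_t0: CondyleStudy,
    truth: PhantomTruth,
    remodel: RemodelSpec,
    spec: PhantomSpec,
) -> tuple[CondyleStudy, PhantomTruth]:
    """Build the T1 study realising ``remodel`` and update the truth record.

    The prescribed height delta moves the head along the ramus axis; a
    superior surface offset additionally raises the apex, so the realised
    height delta (recorded in the truth) is their sum.
    """
    scene1 = _Scene(
        spec,
        head_shift_mm=remodel.height_delta_mm,
        head_tilt_deg=spec.head_tilt_deg + remodel.axis_rotation_deg,
        offsets=remodel.offsets_vector(),
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    volume, mask, mesh = _rasterize(
        scene1, rng, hu_scale=remodel.density_scale, extra_noise_sd=remodel.hu_noise_sd
    )
    lm = scene1.landmarks()
    target = truth.intercondylar_deg["T0"] + remodel.intercondylar_delta_deg
    lm = _adjust_intercondylar(lm, spec.side, target)
    truth = _truth_from_scene(scene1, "T1", truth)
    truth.intercondylar_deg["T1"] = morphometry.intercondylar_angle(lm).value
    truth.roi_mean_hu["T1"] *= remodel.density_scale
    study = CondyleStudy(
        side=spec.side, timepoint="T1",
        volume=volume, mask=mask, mesh=mesh, landmarks=lm,
    )
    return study, truth


# ---------------------------------------------------------------------------
# cohort generation


#: Remodelling-parameter distributions emulating the reference cohort:
#: (mean, sd) of each prescribed delta, drawn per patient (axis rotation
#: per side).  Density is drawn as a percent change and converted to a
#: scale factor.
COHORT_REMODEL_DISTRIBUTIONS = {
    "height_delta_mm": (-0.7, 0.8),
    "axis_rotation_deg_right": (6.95, 8.9),
    "axis_rotation_deg_left": (1.05, 6.71),
    "intercondylar_delta_deg": (-10.8, 8.22),
    "density_pct": (-33.74, 4.45),
    "surface_anterior_mm": (0.09, 0.65),
    "surface_posterior_mm": (-0.03, 0.55),
    "surface_medial_mm": (0.11, 0.51),
    "surface_lateral_mm": (0.01, 0.61),
    "surface_superior_mm": (0.02, 0.61),
    "hu_noise_sd": (5.0, 0.0),
}


@dataclass
class PhantomPatient:
    patient: int
    sex: str
    angle_class: str
    #: side -> (study_T0, study_T1, truth)
    condyles: dict


def _draw(rng, dist, key, clip=None):
    mu, sd = dist[key]
    v = float(rng.normal(mu, sd)) if sd > 0 else mu
    if clip is not None:
        v = float(np.clip(v, *clip))
    return v


def generate_cohort(
    n_patients: int = 12,
    seed: int = 0,
    sides: tuple[str, ...] = ("right", "left"),
    voxel_spacing_mm: float = 0.5,
    distributions: dict | None = None,
) -> tuple[list[PhantomPatient], pd.DataFrame]:
    """Seeded cohort of paired phantoms with a per-condyle truth table.

    Metadata follows the reference cohort's composition: two thirds male
    (8/4 at n=12) and class II dysmorphism for patients 8 and 12 (class
    III otherwise).  Anatomy varies mildly between patients; remodelling
    parameters are drawn from :data:`COHORT_REMODEL_DISTRIBUTIONS`
    (override single entries via ``distributions``).
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    dist = dict(COHORT_REMODEL_DISTRIBUTIONS)
    if distributions:
        dist.update(distributions)
    ss = np.random.SeedSequence(seed)
    patients: list[PhantomPatient] = []
    truth_rows = []
    for i in range(n_patients):
        sex = "M" if i % 3 != 2 else "F"
        angle_class = "II" if i % 12 in (7, 11) else "III"
        prng = np.random.default_rng(ss.spawn(1)[0])
        condyles = {}
        for side in sides:
            spec = PhantomSpec(
                side=side,
                ramus_length_mm=float(np.clip(prng.normal(47.0, 2.5), 40.0, 54.0)),
                head_tilt_deg=float(np.clip(prng.normal(15.0, 4.0), 2.0, 28.0)),
                voxel_spacing_mm=voxel_spacing_mm,
                seed=int(prng.integers(0, 2**31 - 1)),
            )
            offsets = {
                region: float(
                    np.clip(prng.normal(*dist[f"surface_{region}_mm"]), -1.8, 1.8)
                )
                for region in SURFACE_LABELS
            }
            density_pct = _draw(prng, dist, "density_pct", clip=(-60.0, 20.0))
            remodel = RemodelSpec(
                height_delta_mm=_draw(prng, dist, "height_delta_mm", clip=(-3.5, 2.5)),
                axis_rotation_deg=_draw(prng, dist, f"axis_rotation_deg_{side}", clip=(-25.0, 25.0)),
                intercondylar_delta_deg=_draw(prng, dist, "intercondylar_delta_deg", clip=(-30.0, 10.0)),
                surface_offsets_mm=offsets,
                density_scale=1.0 + density_pct / 100.0,
                hu_noise_sd=dist["hu_noise_sd"][0],
            )
            t0, truth = generate_phantom(spec)
            t1, truth = apply_remodeling(t0, truth, remodel, spec)
            condyles[side] = (t0, t1, truth)
            truth_rows.append(
                {
                    "patient": i + 1,
                    "side": side,
                    "sex": sex,
                    "angle_class": angle_class,
                    "height_delta_mm": truth.delta("height_mm"),
                    "axis_delta_deg": truth.delta("axis_inclination_deg"),
                    "intercondylar_delta_deg": truth.delta("intercondylar_deg"),
                    "volume_delta_mm3": truth.delta("roi_volume_mm3"),
                    "density_delta_pct": 100.0
                    * (truth.roi_mean_hu["T1"] / truth.roi_mean_hu["T0"] - 1.0),
                    **{f"offset_{r}_mm": offsets[r] for r in SURFACE_LABELS},
                }
            )
        patients.append(PhantomPatient(i + 1, sex, angle_class, condyles))
    return patients, pd.DataFrame(truth_rows)


def save_phantom_pair(study_t0: CondyleStudy, study_t1: CondyleStudy,
                      truth: PhantomTruth, out_dir) -> None:
    """Write both timepoints (NIfTI + PLY + JSON) and the truth record."""
    import json

    out = Path(out_dir)
    study_t0.save(out / "T0")
    study_t1.save(out / "T1")
    payload = {
        k: getattr(truth, k)
        for k in (
            "height_mm", "intercondylar_deg", "axis_inclination_deg",
            "roi_volume_mm3", "roi_mean_hu", "surface_offsets_mm", "scene_params",
        )
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
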
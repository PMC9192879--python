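"""End-to-end measurement pipeline: study in, six parameters out.

``measure_study`` evaluates one condyle at one timepoint;
``compare_pair`` evaluates a pre/post pair including mesh registration
and per-region surface distances; ``measure_cohort`` maps a phantom (or
loaded) cohort into the tidy delta table the cohort statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphometry, surface_morphology, volumetrics
from .imaging_io import CondyleStudy
from .surface_morphology import SURFACE_LABELS

__all__ = ["MeasurementRecord", "PairedMeasurement", "measure_study", "compare_pair", "measure_cohort"]


@dataclass(frozen=True)
class MeasurementRecord:
    """The per-condyle/timepoint parameters (surface means are pairwise)."""

    side: str
    timepoint: str
    height_mm: float
    intercondylar_deg: float
    axis_inclination_deg: float
    roi_volume_mm3: float
    roi_mean_hu: float


@dataclass(frozen=True)
class PairedMeasurement:
    side: str
    pre: MeasurementRecord
    post: MeasurementRecord
    height_delta_mm: float
    height_delta_pct: float
    intercondylar_delta_deg: float
    axis_delta_deg: float
    volume_delta_mm3: float
    volume_delta_pct: float
    density_delta_pct: float
    surface_means_mm: dict | None  # region -> mean signed distance
    registration_rms_mm: float | None
    resorption: bool


def _axis_down(study: CondyleStudy) -> np.ndarray:
    """Condylar axis direction pointing from apex toward the gonion."""
    lm = study.landmarks
    d = lm.get("ramus_axis_inferior", study.side) - lm.get("ramus_axis_superior", study.side)
    return d / np.linalg.norm(d)


def measure_study(study: CondyleStudy, roi_depth_mm: float = 15.0) -> MeasurementRecord:
    lm = study.landmarks
    height = morphometry.ramus_height(lm, study.side)
    inter = morphometry.intercondylar_angle(lm)
    incl = morphometry.axis_inclination_from_landmarks(lm, study.side)
    roi = volumetrics.clip_condylar_roi(
        study.mask, _axis_down(study), lm.get("condyle_apex", study.side), roi_depth_mm
    )
    return MeasurementRecord(
        side=study.side,
        timepoint=study.timepoint,
        height_mm=height.value,
        intercondylar_deg=inter.value,
        axis_inclination_deg=incl.value,
        roi_volume_mm3=volumetrics.mask_volume(roi),
        roi_mean_hu=volumetrics.mean_density(study.volume, roi),
    )


def compare_pair(
    pre: CondyleStudy,
    post: CondyleStudy,
    roi_depth_mm: float = 15.0,
    surfaces: bool = True,
    registration_support: str = "support",
) -> PairedMeasurement:
    """Measure both timepoints and their deltas.

    With ``surfaces=True`` the post mesh is ICP-registered onto the pre
    mesh (on the ramus-stump support by default), signed closest-point
    distances are evaluated on the pre condylar-head submesh (the same
    apex-down-15 mm region as the volumetric ROI), and per-region means
    are reported.
    """
    if pre.side != post.side:
        raise ValueError("pre and post studies are from different sides")
    m0 = measure_study(pre, roi_depth_mm)
    m1 = measure_study(post, roi_depth_mm)
    surface_means = None
    reg_rms = None
    if surfaces:
        reg = surface_morphology.register_rigid(
            post.mesh, pre.mesh, support=registration_support
        )
        post_mesh = post.mesh.transformed(reg.transform.matrix)
        reg_rms = reg.rms
        apex = pre.landmarks.get("condyle_apex", pre.side)
        head, _ = surface_morphology.extract_head_submesh(
            pre.mesh, apex, _axis_down(pre), roi_depth_mm
        )
        dmap = surface_morphology.signed_distances(head, post_mesh)
        frame = surface_morphology.CondylarFrame.from_landmarks(pre.landmarks, pre.side)
        labels = surface_morphology.partition_condylar_surface(head, frame)
        stats = surface_morphology.per_surface_means(dmap, labels)
        surface_means = {k: v["mean"] for k, v in stats.items()}
    height_pct = morphometry.delta(m0.height_mm, m1.height_mm, as_percent=True)
    return PairedMeasurement(
        side=pre.side,
        pre=m0,
        post=m1,
        height_delta_mm=morphometry.delta(m0.height_mm, m1.height_mm),
        height_delta_pct=height_pct,
        intercondylar_delta_deg=morphometry.delta(m0.intercondylar_deg, m1.intercondylar_deg),
        axis_delta_deg=morphometry.delta(m0.axis_inclination_deg, m1.axis_inclination_deg),
        volume_delta_mm3=morphometry.delta(m0.roi_volume_mm3, m1.roi_volume_mm3),
        volume_delta_pct=morphometry.delta(m0.roi_volume_mm3, m1.roi_volume_mm3, as_percent=True),
        density_delta_pct=morphometry.delta(m0.roi_mean_hu, m1.roi_mean_hu, as_percent=True),
        surface_means_mm=surface_means,
        registration_rms_mm=reg_rms,
        resorption=morphometry.classify_resorption(height_pct),
    )


def measure_cohort(patients, surfaces: bool = True) -> pd.DataFrame:
    """Tidy per-condyle deltas for :func:`condylar.cohort_stats.build_cohort_report`.

    ``patients`` is an iterable of :class:`~condylar.synthetic_phantom.PhantomPatient`
    (or any object with ``patient`` and a ``condyles`` mapping of side ->
    (pre, post, _)).  Patient-level variables (intercondylar angle,
    volume) are taken from the right condyle when both sides are present.
    """
    rows = []
    for pat in patients:
        sides = list(pat.condyles)
        for side in sides:
            t0, t1, _ = pat.condyles[side]
            pm = compare_pair(t0, t1, surfaces=surfaces)
            rows.append((pat.patient, side, "height_mm", pm.height_delta_mm))
            rows.append((pat.patient, side, "axis_deg", pm.axis_delta_deg))
            rows.append((pat.patient, side, "density_hu", pm.post.roi_mean_hu - pm.pre.roi_mean_hu))
            rows.append((pat.patient, side, "density_pct", pm.density_delta_pct))
            if pm.surface_means_mm is not None:
                for region in SURFACE_LABELS:
                    rows.append((pat.patient, side, f"surface_{region}_mm", pm.surface_means_mm[region]))
            if side == sides[0]:
                rows.append((pat.patient, "both", "intercondylar_deg", pm.intercondylar_delta_deg))
                rows.append((pat.patient, "n/a", "volume_mm3", pm.volume_delta_mm3))
                rows.append((pat.patient, "n/a", "volume_pct", pm.volume_delta_pct))
    return pd.DataFrame(rows, columns=["patient", "side", "variable", "delta"])
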
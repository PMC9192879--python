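"""Landmark-based linear and angular condylar measurements.

Three quantities are measured per condyle and timepoint:

* **ramus height** — Euclidean distance from the most superior point of the
  condylar head (``condyle_apex``) to the most inferior point of the
  mandibular angle (``gonion_lowest``), the Hoppenreijs tangent-line
  measurement reduced to its two defining points;
* **intercondylar angle** — the angle subtended at the anterior border of
  the foramen magnum by the left and right condylar-head centres;
* **condylar axis inclination** — the angle, after orthogonal projection
  onto the coronal plane, between the maximum transverse condylar diameter
  line and the ramus major axis.

Angles are reported in degrees; heights in millimetres.  Pre/post change
is ``T1 − T0`` (optionally as a percentage of T0), and condylar
resorption is flagged when the ramus height has dropped by more than 6 %
of its pre-surgical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import LandmarkSet

__all__ = [
    "AngleMeasurement",
    "HeightMeasurement",
    "ramus_height",
    "intercondylar_angle",
    "condylar_axis_inclination",
    "axis_inclination_from_landmarks",
    "delta",
    "classify_resorption",
    "RESORPTION_THRESHOLD_PCT",
    "CORONAL_NORMAL",
]

#: Ramus-height loss beyond this percentage of the pre-surgical value is
#: classified as condylar resorption (Hoppenreijs criterion).
RESORPTION_THRESHOLD_PCT = 6.0

#: The coronal (frontal) plane is orthogonal to the anterior–posterior
#: axis of the LPS patient frame.
CORONAL_NORMAL = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """A defining vector of an angle has (numerically) zero length."""


@dataclass(frozen=True)
class HeightMeasurement:
    """A ramus height with the two landmarks that define it."""

    value: float  # mm, >= 0
    apex: np.ndarray
    gonion: np.ndarray


@dataclass(frozen=True)
class AngleMeasurement:
    """An angle in degrees with its defining directions, for audit."""

    value: float  # degrees in [0, 180]
    directions: tuple
    plane: str = "3D"  # "3D" or "coronal-projected"


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    # atan2 form is stable near 0 and 180 degrees
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def ramus_height(landmarks: LandmarkSet, side: str | None = None) -> HeightMeasurement:
    """Apex-to-gonion distance in mm for one side."""
    apex = landmarks.get("condyle_apex", side)
    gonion = landmarks.get("gonion_lowest", side)
    return HeightMeasurement(
        value=float(np.linalg.norm(apex - gonion)), apex=apex, gonion=gonion
    )


def intercondylar_angle(landmarks: LandmarkSet) -> AngleMeasurement:
    """Angle at the foramen vertex between the two condylar centres."""
    vertex = landmarks["foramen_magnum_anterior"]
    a = landmarks["condyle_center_left"]
    b = landmarks["condyle_center_right"]
    va = _unit(a - vertex, "vertex->left-centre vector")
    vb = _unit(b - vertex, "vertex->right-centre vector")
    return AngleMeasurement(value=_angle_deg(va, vb), directions=(va, vb), plane="3D")


def condylar_axis_inclination(
    transverse_endpoints: tuple[np.ndarray, np.ndarray],
    ramus_axis_points: tuple[np.ndarray, np.ndarray],
    coronal_normal: np.ndarray = CORONAL_NORMAL,
) -> AngleMeasurement:
    """Coronal-plane angle between the transverse diameter and ramus axis.

    Both lines are taken as *directed*: transverse from its first to its
    second endpoint (the phantom and loaders order them lateral→medial),
    the ramus axis from inferior to superior.  The angle between the two
    projected directions therefore lies in [0, 180), so inclinations on
    either side of perpendicular stay distinguishable and deltas keep a
    meaningful sign.
    """
    n = _unit(np.asarray(coronal_normal, float), "coronal normal")

    def project(p0, p1, what):
        d = np.asarray(p1, float) - np.asarray(p0, float)
        d = d - np.dot(d, n) * n
        if np.linalg.norm(d) < 1e-9:
            raise DegenerateGeometryError(f"{what} is orthogonal to the coronal plane")
        return d / np.linalg.norm(d)

    da = project(*transverse_endpoints, "transverse diameter line")
    db = project(*ramus_axis_points, "ramus axis line")
    return AngleMeasurement(value=_angle_deg(da, db), directions=(da, db), plane="coronal-projected")


def axis_inclination_from_landmarks(landmarks: LandmarkSet, side: str | None = None) -> AngleMeasurement:
    """Convenience wrapper resolving the four defining landmarks."""
    return condylar_axis_inclination(
        (landmarks.get("transverse_lateral", side), landmarks.get("transverse_medial", side)),
        (landmarks.get("ramus_axis_inferior", side), landmarks.get("ramus_axis_superior", side)),
    )


def _value(x) -> float:
    return float(getattr(x, "value", x))


def delta(measure_t0, measure_t1, as_percent: bool = False) -> float:
    """Signed change ``T1 − T0`` (mm/degrees), or ``100·(T1 − T0)/T0``."""
    v0, v1 = _value(measure_t0), _value(measure_t1)
    if as_percent:
        if v0 == 0:
            raise ZeroDivisionError("percent delta undefined: T0 value is zero")
        return 100.0 * (v1 - v0) / v0
    return v1 - v0


def classify_resorption(height_percent_delta: float) -> bool:
    """True iff the ramus height dropped by strictly more than 6 %."""
    if not np.isfinite(height_percent_delta):
        raise ValueError("percent delta must be finite")
    return bool(height_percent_delta < -RESORPTION_THRESHOLD_PCT)
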
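"""C-arm gantry geometry and orthographic silhouette projection.

The patient coordinate frame is fixed throughout the package:

* ``x`` — patient left
* ``y`` — patient posterior
* ``z`` — patient superior

A gantry pose is a pair of angles ``(primary, secondary)`` in degrees with
the interventional sign convention RAO positive / LAO negative for the
primary rotation (about the patient's long axis) and CRAN positive / CAUD
negative for the secondary tilt.  The unit beam direction for a pose
``(alpha, beta)`` is

    v = (-sin(a) cos(b), -cos(a) cos(b), sin(b))

so that the antero-posterior view (0, 0) looks along ``-y`` and a pure
right-lateral view (90, 0) looks along ``-x``.

Projection is orthographic (parallel beam).  Beam divergence of a real
cone-beam system is corrected in practice by in-field catheter
calibration, so it is absorbed here into the calibration noise model
rather than modelled geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

__all__ = [
    "CArmPose",
    "CalibrationMarker",
    "Silhouette",
    "STANDARD_POSE",
    "pose_to_direction",
    "direction_to_pose",
    "image_basis",
    "projected_length",
    "project_points",
    "project_mesh",
    "calibrate",
    "angular_distance_deg",
]


@dataclass(frozen=True)
class CArmPose:
    """Gantry orientation: RAO(+)/LAO(-) primary, CRAN(+)/CAUD(-) secondary."""

    primary_deg: float
    secondary_deg: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.primary_deg <= 180.0:
            raise ValueError(f"primary angle {self.primary_deg} outside [-180, 180]")
        if not -90.0 <= self.secondary_deg <= 90.0:
            raise ValueError(f"secondary angle {self.secondary_deg} outside [-90, 90]")


#: The standard working view for LAA angiography: RAO 30, caudal 20.
STANDARD_POSE = CArmPose(30.0, -20.0)


@dataclass(frozen=True)
class CalibrationMarker:
    """A segment of known physical length in the field of view.

    Stands in for the pigtail catheter used to convert image units to
    millimetres.  In the noise-free model ``true_length_mm`` equals the
    Euclidean distance of the endpoints.
    """

    endpoints_3d: np.ndarray  # (2, 3)
    true_length_mm: float

    @staticmethod
    def from_endpoints(p1, p2) -> "CalibrationMarker":
        pts = np.asarray([p1, p2], dtype=float)
        return CalibrationMarker(pts, float(np.linalg.norm(pts[1] - pts[0])))


@dataclass
class Silhouette:
    """2D outer boundary of an orthographic mesh projection.

    ``outer_boundary`` is a simple counter-clockwise polygon in image-plane
    millimetres (before calibration ``scale`` is applied to measurements).
    ``basis`` holds the orthonormal image axes ``(u, w)`` and the beam
    direction ``v``.  ``projected_points`` carries labelled fiducials
    (e.g. D1/D2, marker endpoints) in the same image coordinates.
    """

    outer_boundary: np.ndarray  # (n, 2), CCW, closed implicitly
    basis: tuple[np.ndarray, np.ndarray, np.ndarray]  # (u, w, v)
    pose: CArmPose
    projected_points: dict[str, np.ndarray] = field(default_factory=dict)
    scale: float | None = None  # mm per image unit, set by calibrate()

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outer_boundary)

    def measure(self, q1: np.ndarray, q2: np.ndarray) -> float:
        """Calibrated distance between two image points (mm)."""
        if self.scale is None:
            raise ValueError("silhouette is not calibrated")
        return float(self.scale * np.linalg.norm(np.asarray(q2) - np.asarray(q1)))


def pose_to_direction(pose: CArmPose) -> np.ndarray:
    """Unit beam direction for a gantry pose, in the patient frame."""
    a = np.deg2rad(pose.primary_deg)
    b = np.deg2rad(pose.secondary_deg)
    v = np.array([-np.sin(a) * np.cos(b), -np.cos(a) * np.cos(b), np.sin(b)])
    return v / np.linalg.norm(v)


def direction_to_pose(v: np.ndarray) -> CArmPose:
    """Invert :func:`pose_to_direction` for a unit direction.

    Unique for secondary in (-90, 90); at the poles the primary angle is
    taken as 0.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    beta = np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    if abs(abs(v[2]) - 1.0) < 1e-12:
        return CArmPose(0.0, beta)
    alpha = np.rad2deg(np.arctan2(-v[0], -v[1]))
    return CArmPose(alpha, beta)


def image_basis(pose: CArmPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal image axes (u, w) and beam direction v for a pose.

    u = normalize(v x z); at the poles (beam along z) v x y is used.
    w = v x u.  (u, w, v) is right-handed and orthonormal.
    """
    v = pose_to_direction(pose)
    ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(v, ref)
    if np.linalg.norm(u) < 1e-9:
        u = np.cross(v, np.array([0.0, 1.0, 0.0]))
    u = u / np.linalg.norm(u)
    w = np.cross(v, u)
    return u, w, v


def projected_length(p1, p2, pose: CArmPose) -> float:
    """Orthographically projected length of the segment p1->p2 (mm).

    Equals |s| sin(theta) where theta is the angle between the segment and
    the beam; it never exceeds the true length, with equality exactly when
    the segment is perpendicular to the beam.  Coincident points give 0.
    """
    s = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    v = pose_to_direction(pose)
    return float(np.linalg.norm(s - np.dot(s, v) * v))


def project_points(points: np.ndarray, pose: CArmPose) -> np.ndarray:
    """Project 3D points to 2D image coordinates (u, w)."""
    u, w, _ = image_basis(pose)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.column_stack([pts @ u, pts @ w])


def project_mesh(mesh, pose: CArmPose, marker: CalibrationMarker | None = None,
                 extra_points: dict[str, np.ndarray] | None = None) -> Silhouette:
    """Orthographic silhouette of a triangle mesh at a gantry pose.

    The silhouette is the outer boundary of the union of all projected
    triangles; internal holes are discarded (the fluoroscopic shadow of a
    filled cardiac chamber has none).  For a closed surface the union of
    the beam-facing triangles covers the full shadow, so back faces are
    culled for speed.
    """
    verts2d = project_points(mesh.vertices, pose)
    v = pose_to_direction(pose)
    faces = np.asarray(mesh.faces)
    # beam-facing subset; keep both-side faces if normals are unreliable
    dots = np.asarray(mesh.face_normals) @ v
    front = faces[dots < 0.0]
    if len(front) < max(4, 0.2 * len(faces)):
        front = faces
    tris = verts2d[front]  # (m, 3, 2)
    # drop degenerate projections
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    tris = tris[area2 > 1e-12]
    if len(tris) == 0:
        raise ValueError("mesh projects to zero area at this pose")
    polys = shapely.polygons(tris)
    polys = shapely.make_valid(polys)
    try:
        union = shapely.union_all(polys)
    except shapely.errors.GEOSException:
        # rare near-degenerate configurations; retry on a snapped grid
        snapped = shapely.set_precision(polys, 1e-7)
        union = shapely.union_all(snapped)
    union = shapely.make_valid(union)
    if union.geom_type == "GeometryCollection":
        parts = [g for g in union.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        union = shapely.union_all(parts)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    if union.is_empty or union.area <= 0:
        raise ValueError("mesh projects to zero area at this pose")
    outer = orient(Polygon(union.exterior), sign=1.0)
    boundary = np.asarray(outer.exterior.coords)[:-1]

    projected: dict[str, np.ndarray] = {}
    if marker is not None:
        mk = project_points(marker.endpoints_3d, pose)
        projected["marker_0"] = mk[0]
        projected["marker_1"] = mk[1]
    if extra_points:
        for name, p in extra_points.items():
            projected[name] = project_points(p, pose)[0]
    u, w, _ = image_basis(pose)
    return Silhouette(outer_boundary=boundary, basis=(u, w, v), pose=pose,
                      projected_points=projected)


def calibrate(silhouette: Silhouette, marker: CalibrationMarker,
              scale_noise: float = 0.0) -> Silhouette:
    """Set the mm-per-image-unit scale from a projected calibration marker.

    The operator reads the marker's apparent length off the image; a
    multiplicative error ``scale_noise`` models reading imprecision:
    scale = true_length / (projected_length * (1 + scale_noise)).
    A marker nearly parallel to the beam cannot calibrate the image.
    """
    if "marker_0" in silhouette.projected_points:
        q0 = silhouette.projected_points["marker_0"]
        q1 = silhouette.projected_points["marker_1"]
        proj = float(np.linalg.norm(q1 - q0))
    else:
        proj = projected_length(marker.endpoints_3d[0], marker.endpoints_3d[1],
                                silhouette.pose)
    if proj < 1e-6 * marker.true_length_mm:
        raise ValueError("calibration marker is parallel to the beam")
    scale = marker.true_length_mm / (proj * (1.0 + scale_noise))
    return replace(silhouette, scale=scale)


def angular_distance_deg(p: CArmPose, q: CArmPose) -> float:
    """Angle in degrees between the beam directions of two poses."""
    c = float(np.clip(np.dot(pose_to_direction(p), pose_to_direction(q)), -1, 1))
    return float(np.rad2deg(np.arccos(c)))
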
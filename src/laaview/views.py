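"""Personalized C-arm view planning.

A segment of interest (the landing-zone diameter D1-D2, or the
implantation-axis chord from the landing-zone centre to the tip) projects
at full length exactly when the beam is perpendicular to it.  The
perpendicular beam directions form a one-parameter family (rotation about
the segment); within the gantry's feasibility box the planner picks the
family member at which both segment endpoints fall on the silhouette
outer border (the fluoroscopic tangency criterion used when marking
fiducials on CT), breaking ties toward the least gantry travel from the
standard working view.

Where a single view serves both the diameter and the length segment
(beam close to the common perpendicular), a combined view is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .anatomy import LAAAnatomy
from .errors import FeasibilityError
from .geometry import (
    STANDARD_POSE,
    CArmPose,
    angular_distance_deg,
    direction_to_pose,
    pose_to_direction,
    project_mesh,
    project_points,
)
from .landing import LandingZone

__all__ = [
    "FeasibilityBox",
    "ViewPlan",
    "derive_diameter_view",
    "derive_length_view",
    "plan_views",
]

#: Distance (image mm) within which a projected fiducial counts as lying
#: on the silhouette border.
TANGENCY_TOL_MM = 0.5


@dataclass(frozen=True)
class FeasibilityBox:
    """Reachable gantry angles (degrees)."""

    primary: tuple[float, float] = (-90.0, 90.0)
    secondary: tuple[float, float] = (-45.0, 45.0)

    def contains(self, pose: CArmPose) -> bool:
        return (self.primary[0] - 1e-9 <= pose.primary_deg <= self.primary[1] + 1e-9
                and self.secondary[0] - 1e-9 <= pose.secondary_deg <= self.secondary[1] + 1e-9)

    def is_empty(self) -> bool:
        return self.primary[0] > self.primary[1] or self.secondary[0] > self.secondary[1]


@dataclass
class ViewPlan:
    """Personalized pose(s) for one case."""

    diameter_pose: CArmPose
    length_pose: CArmPose
    combined: bool
    tangency_ok: bool
    length_tangency_ok: bool
    feasibility_box: FeasibilityBox

    def to_dict(self) -> dict:
        return {
            "diameter_pose": [self.diameter_pose.primary_deg,
                              self.diameter_pose.secondary_deg],
            "length_pose": [self.length_pose.primary_deg,
                            self.length_pose.secondary_deg],
            "combined": self.combined,
            "tangency_ok": self.tangency_ok,
            "length_tangency_ok": self.length_tangency_ok,
        }


def _perp_basis(shat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.cross(shat, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-9:
        p = np.cross(shat, [0.0, 1.0, 0.0])
    p /= np.linalg.norm(p)
    return p, np.cross(shat, p)


def _family_pose(shat: np.ndarray, phi: float) -> CArmPose | None:
    p, q = _perp_basis(shat)
    v = np.cos(phi) * p + np.sin(phi) * q
    try:
        return direction_to_pose(v)
    except Exception:
        return None


def _tangency_distances(mesh, pose: CArmPose, p1: np.ndarray, p2: np.ndarray):
    """Distance of each projected endpoint to the silhouette border."""
    sil = project_mesh(mesh, pose)
    ring = sil.polygon.exterior
    q = project_points(np.vstack([p1, p2]), pose)
    return (float(Point(q[0]).distance(ring)), float(Point(q[1]).distance(ring)))


def _golden_min(f, a: float, b: float, iters: int = 12) -> float:
    """Golden-section minimum of f on [a, b]."""
    inv = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - inv * (b - a)
    x2 = a + inv * (b - a)
    f1, f2 = f(x1), f(x2)
    for _ in range(iters):
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - inv * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + inv * (b - a)
            f2 = f(x2)
    return 0.5 * (a + b)


def derive_segment_view(anatomy: LAAAnatomy, p1: np.ndarray, p2: np.ndarray,
                        box: FeasibilityBox | None = None,
                        scoring_mesh=None,
                        scan_step_deg: float = 4.0) -> tuple[CArmPose, bool]:
    """Personalized pose for an arbitrary 3D segment.

    Scans the perpendicular family; among feasible members with both
    projected endpoints on the silhouette border, returns the one closest
    to the standard view.  If none is tangent, the feasible member with
    the best (golden-section refined) tangency score is returned with
    ``tangency_ok=False``.  An empty feasible family raises
    :class:`FeasibilityError` naming the unconstrained optimum.
    """
    box = box or FeasibilityBox()
    if box.is_empty():
        raise FeasibilityError("feasibility box is empty")
    mesh = scoring_mesh if scoring_mesh is not None else anatomy.mesh
    s = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    shat = s / np.linalg.norm(s)

    phis = np.deg2rad(np.arange(0.0, 360.0, scan_step_deg))
    feasible: list[tuple[float, CArmPose]] = []
    for phi in phis:
        pose = _family_pose(shat, phi)
        if pose is not None and box.contains(pose):
            feasible.append((phi, pose))
    if not feasible:
        opt = _family_pose(shat, 0.0)
        raise FeasibilityError(
            "no perpendicular view inside the feasibility box; "
            f"unconstrained optimum e.g. ({opt.primary_deg:.1f}, {opt.secondary_deg:.1f})")

    scored = []
    for phi, pose in feasible:
        d1, d2 = _tangency_distances(mesh, pose, p1, p2)
        scored.append((phi, pose, d1, d2))
    tangent = [t for t in scored
               if t[2] <= TANGENCY_TOL_MM and t[3] <= TANGENCY_TOL_MM]
    if tangent:
        _, pose, _, _ = min(tangent,
                            key=lambda t: angular_distance_deg(t[1], STANDARD_POSE))
        return pose, True

    # refine the best non-tangent candidate locally
    best = min(scored, key=lambda t: t[2] + t[3])
    phi0, pose0 = best[0], best[1]
    half = np.deg2rad(scan_step_deg)

    def score(phi: float) -> float:
        pose = _family_pose(shat, phi)
        if pose is None or not box.contains(pose):
            return np.inf
        d1, d2 = _tangency_distances(mesh, pose, p1, p2)
        return d1 + d2

    phi_best = _golden_min(score, phi0 - half, phi0 + half)
    pose = _family_pose(shat, phi_best)
    if pose is None or not box.contains(pose):
        pose = pose0
    d1, d2 = _tangency_distances(mesh, pose, p1, p2)
    return pose, bool(d1 <= TANGENCY_TOL_MM and d2 <= TANGENCY_TOL_MM)


def derive_diameter_view(anatomy: LAAAnatomy, zone: LandingZone,
                         box: FeasibilityBox | None = None,
                         scoring_mesh=None) -> tuple[CArmPose, bool]:
    """Pose at which the landing-zone maximum diameter projects at full
    length with both fiducials on the silhouette border."""
    return derive_segment_view(anatomy, zone.D1, zone.D2, box,
                               scoring_mesh=scoring_mesh)


def derive_length_view(anatomy: LAAAnatomy, zone: LandingZone,
                       box: FeasibilityBox | None = None,
                       scoring_mesh=None) -> tuple[CArmPose, bool]:
    """Pose optimized for the implantation-axis chord (zone centre to tip)."""
    return derive_segment_view(anatomy, zone.center,
                               anatomy.landmarks["tip"], box,
                               scoring_mesh=scoring_mesh)


def _max_angle_dev(v: np.ndarray, segments: list[np.ndarray]) -> float:
    """Largest deviation (deg) of v from perpendicularity to the segments."""
    devs = []
    for s in segments:
        shat = s / np.linalg.norm(s)
        devs.append(abs(np.rad2deg(np.arcsin(np.clip(abs(np.dot(v, shat)), 0, 1)))))
    return max(devs)


def plan_views(anatomy: LAAAnatomy, zone: LandingZone,
               box: FeasibilityBox | None = None,
               combined_tol_deg: float = 10.0,
               scoring_mesh=None) -> ViewPlan:
    """Derive the per-case view plan, combining views where feasible.

    A combined view exists when some feasible pose is within
    ``combined_tol_deg`` of perpendicular to both the diameter segment
    and the length chord (their exact common perpendicular is the
    normalized cross product of the two directions).
    """
    box = box or FeasibilityBox()
    d_seg = zone.D2 - zone.D1
    l_seg = np.asarray(anatomy.landmarks["tip"]) - zone.center
    segments = [d_seg, l_seg]

    cross = np.cross(d_seg / np.linalg.norm(d_seg), l_seg / np.linalg.norm(l_seg))
    combined_pose = None
    if np.linalg.norm(cross) < 1e-6:
        # parallel segments: any diameter view serves both
        pose, ok = derive_diameter_view(anatomy, zone, box, scoring_mesh)
        return ViewPlan(pose, pose, True, ok, ok, box)
    for sign in (1.0, -1.0):
        v = sign * cross / np.linalg.norm(cross)
        pose = direction_to_pose(v)
        if box.contains(pose):
            combined_pose = pose
            break
    if combined_pose is None and combined_tol_deg > 0:
        # common perpendicular just outside the box: clip it in and keep
        # it only if still essentially perpendicular to both segments —
        # a single view that foreshortens both is worse for each
        # measurement than two dedicated views
        for sign in (1.0, -1.0):
            v = sign * cross / np.linalg.norm(cross)
            pose = direction_to_pose(v)
            clipped = CArmPose(
                float(np.clip(pose.primary_deg, *box.primary)),
                float(np.clip(pose.secondary_deg, *box.secondary)))
            dev = _max_angle_dev(pose_to_direction(clipped), segments)
            if dev <= min(combined_tol_deg, 1.0):
                combined_pose = clipped
                break
    if combined_pose is not None:
        d1, d2 = _tangency_distances(
            scoring_mesh if scoring_mesh is not None else anatomy.mesh,
            combined_pose, zone.D1, zone.D2)
        ok = d1 <= TANGENCY_TOL_MM and d2 <= TANGENCY_TOL_MM
        return ViewPlan(combined_pose, combined_pose, True, bool(ok), bool(ok), box)

    d_pose, d_ok = derive_diameter_view(anatomy, zone, box, scoring_mesh)
    l_pose, l_ok = derive_length_view(anatomy, zone, box, scoring_mesh)
    return ViewPlan(d_pose, l_pose, False, d_ok, l_ok, box)
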
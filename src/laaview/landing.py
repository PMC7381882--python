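"""Watchman landing-zone definition and Control (ground-truth) measurement.

The landing zone is found on the 3D anatomy the way it is drawn on CT: a
line from the inferior LAA deflection to a point 1-2 cm anterior to the
LUPV limbus, with the anterior offset tuned so the resulting cut plane is
as perpendicular as possible to the local cavity centerline.  Diameters
come from the plane/mesh cross-section contour; the maximum diameter is
the maximum caliper (chord) distance between rim points, matching the
two-fiducial (D1/D2) measurement convention, and the minimum diameter is
the minimal width of the contour's convex hull.

The Control pathway measures the mesh directly, so Control equals ground
truth by construction (up to mesh discretization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .anatomy import LAAAnatomy
from .errors import GeometryError, ParameterError

__all__ = [
    "LandingZone",
    "ControlMeasurement",
    "locate_landing_zone",
    "cross_section_diameters",
    "section_contour",
    "laa_length",
    "eccentricity_metrics",
    "control_measurement",
]


@dataclass
class LandingZone:
    """The cut plane where the occluder seats, with rim fiducials D1/D2."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    max_diameter_mm: float
    min_diameter_mm: float
    lupv_offset_mm: float
    center: np.ndarray          # centerline / plane intersection
    perpendicularity: float     # |normal . centerline tangent|, 1 = ideal
    warning: bool = False       # no candidate within 30 deg of perpendicular
    contour: np.ndarray | None = None  # (n, 3) section rim points


@dataclass(frozen=True)
class ControlMeasurement:
    """Ground-truth landing-zone measurements of one case.

    ``length_mm`` follows the curved cavity centerline (arc length from
    the landing plane to the tip); ``length_chord_mm`` is the straight
    implantation-axis chord, which is what a projected silhouette can
    show.  Eccentricity = 1 - min/max; absolute eccentricity = max - min.
    """

    max_diameter_mm: float
    min_diameter_mm: float
    length_mm: float
    length_chord_mm: float
    eccentricity: float
    absolute_eccentricity_mm: float


def _contours_in_plane(mesh, plane_point, plane_normal):
    """Closed section contours of a mesh, as lists of 3D points."""
    section = mesh.section(plane_origin=plane_point, plane_normal=plane_normal)
    if section is None:
        return []
    return [np.asarray(d) for d in section.discrete if len(d) >= 3]


def _select_contour(contours, anchor):
    """Contour containing (or nearest to) the anchor point."""
    if len(contours) == 1:
        return contours[0]
    best, best_dist = None, np.inf
    for c in contours:
        d = np.min(np.linalg.norm(c - anchor, axis=1))
        centroid_d = np.linalg.norm(c.mean(axis=0) - anchor)
        score = min(d, centroid_d)
        if score < best_dist:
            best, best_dist = c, score
    return best


def _calipers(contour3d, plane_normal):
    """(max_diameter, min_width, P_max1, P_max2) of a planar contour.

    Maximum: max pairwise distance over convex-hull vertices (equivalent
    to rotating calipers).  Minimum: minimal width of the convex hull,
    computed as the smallest over hull edges of the farthest vertex
    distance to the edge line.
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    pts2 = np.column_stack([contour3d @ e1, contour3d @ e2])
    if len(pts2) < 3:
        raise GeometryError("degenerate section contour")
    try:
        hull = ConvexHull(pts2)
        hidx = hull.vertices
    except Exception:
        hidx = np.arange(len(pts2))
    hp = pts2[hidx]
    # max caliper distance
    diff = hp[:, None, :] - hp[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    max_d = float(dist[i, j])
    # min width over hull edges
    m = len(hp)
    widths = []
    for k in range(m):
        a, b = hp[k], hp[(k + 1) % m]
        e = b - a
        ne = np.linalg.norm(e)
        if ne < 1e-12:
            continue
        normal2 = np.array([-e[1], e[0]]) / ne
        widths.append(np.max(np.abs((hp - a) @ normal2)))
    min_d = float(min(widths)) if widths else max_d
    return max_d, min_d, contour3d[hidx[i]], contour3d[hidx[j]]


def section_contour(anatomy: LAAAnatomy, zone: LandingZone) -> np.ndarray:
    """Rim contour of the landing-zone cut (the contour at the
    centerline when the plane yields several)."""
    contours = _contours_in_plane(anatomy.appendage_mesh,
                                  zone.plane_point, zone.plane_normal)
    if not contours:
        raise GeometryError("landing plane does not intersect the appendage")
    if len(contours) > 1:
        warnings.warn("multiple section contours; keeping the one at the "
                      "centerline", stacklevel=2)
    return _select_contour(contours, zone.center)


def cross_section_diameters(anatomy: LAAAnatomy, zone: LandingZone):
    """(max_diameter, min_diameter, D1, D2) of the landing-zone section."""
    contour = section_contour(anatomy, zone)
    max_d, min_d, D1, D2 = _calipers(contour, zone.plane_normal)
    return max_d, min_d, D1, D2


def _centerline_tangent(centerline, point):
    """Unit tangent of the centerline at the sample nearest to a point."""
    i = int(np.argmin(np.linalg.norm(centerline - point, axis=1)))
    i0, i1 = max(i - 1, 0), min(i + 1, len(centerline) - 1)
    t = centerline[i1] - centerline[i0]
    return t / np.linalg.norm(t)


def _plane_centerline_crossing(centerline, plane_point, plane_normal):
    """First crossing of the centerline through the plane (from the
    orifice side), with the index of the segment."""
    s = (centerline - plane_point) @ plane_normal
    sign_change = np.where(s[:-1] * s[1:] <= 0)[0]
    if len(sign_change) == 0:
        return None, None
    k = int(sign_change[0])
    denom = s[k + 1] - s[k]
    t = 0.0 if abs(denom) < 1e-15 else -s[k] / denom
    return centerline[k] + t * (centerline[k + 1] - centerline[k]), k + t


def locate_landing_zone(anatomy: LAAAnatomy, step_mm: float = 0.5) -> LandingZone:
    """Scan the 1-2 cm anterior offset for the most perpendicular cut.

    For each offset ``t`` in [10, 20] mm the candidate landing line runs
    from the inferior deflection to the point ``t`` anterior of the LUPV
    limbus; its plane (the plane through the line whose normal is closest
    to the local centerline tangent) is scored by |normal . tangent|.
    Ties within 1e-9 are broken toward t = 15 mm.  If no candidate is
    within 30 degrees of perpendicular the best zone is still returned,
    flagged with ``warning=True``.
    """
    lm = anatomy.landmarks
    inf_pt = lm["inferior_deflection"]
    limbus = lm["lupv_limbus"]
    ahat = anatomy.anterior_axis / np.linalg.norm(anatomy.anterior_axis)
    centerline = np.asarray(anatomy.centerline, dtype=float)

    candidates = []
    for t in np.arange(10.0, 20.0 + 1e-9, step_mm):
        sup_pt = limbus + t * ahat
        d = sup_pt - inf_pt
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            continue
        dhat = d / nd
        mid = 0.5 * (sup_pt + inf_pt)
        tangent = _centerline_tangent(centerline, mid)
        for _ in range(2):
            n = tangent - np.dot(tangent, dhat) * dhat
            nn = np.linalg.norm(n)
            if nn < 1e-9:
                break
            n = n / nn
            crossing, _ = _plane_centerline_crossing(centerline, mid, n)
            if crossing is None:
                break
            tangent = _centerline_tangent(centerline, crossing)
        else:
            score = abs(np.dot(n, tangent))
            candidates.append((score, -abs(t - 15.0), t, mid, n))
    if not candidates:
        raise GeometryError("no valid landing-zone candidate")
    score, _, t_best, mid, n = max(candidates, key=lambda c: (round(c[0], 9), c[1]))
    warn = score < np.cos(np.deg2rad(30.0))
    crossing, _ = _plane_centerline_crossing(centerline, mid, n)
    center = crossing if crossing is not None else mid
    zone = LandingZone(plane_point=mid, plane_normal=n, D1=np.zeros(3),
                       D2=np.zeros(3), max_diameter_mm=0.0, min_diameter_mm=0.0,
                       lupv_offset_mm=float(t_best), center=center,
                       perpendicularity=float(score), warning=bool(warn))
    contour = section_contour(anatomy, zone)
    max_d, min_d, D1, D2 = _calipers(contour, zone.plane_normal)
    zone.D1, zone.D2 = D1, D2
    zone.max_diameter_mm, zone.min_diameter_mm = max_d, min_d
    zone.contour = contour
    return zone


def laa_length(anatomy: LAAAnatomy, zone: LandingZone) -> float:
    """Arc length of the cavity centerline from the landing plane to the
    tip (the coaxial length a 3D dataset provides)."""
    centerline = np.asarray(anatomy.centerline, dtype=float)
    crossing, frac = _plane_centerline_crossing(
        centerline, zone.plane_point, zone.plane_normal)
    if crossing is None:
        raise GeometryError("centerline does not cross the landing plane")
    k = int(np.floor(frac))
    pts = np.vstack([crossing, centerline[k + 1:]])
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def laa_length_chord(anatomy: LAAAnatomy, zone: LandingZone) -> float:
    """Straight implantation-axis chord from landing-zone centre to tip."""
    return float(np.linalg.norm(anatomy.landmarks["tip"] - zone.center))


def eccentricity_metrics(max_d: float, min_d: float) -> tuple[float, float]:
    """(eccentricity, absolute eccentricity) of an orifice.

    Eccentricity = 1 - min/max is scale-free; absolute eccentricity
    = max - min (mm) carries the size information that predicts
    millimetre-scale projection error.
    """
    if not 0 < min_d <= max_d:
        raise ParameterError(f"need 0 < min ({min_d}) <= max ({max_d})")
    return 1.0 - min_d / max_d, max_d - min_d


def control_measurement(anatomy: LAAAnatomy, zone: LandingZone) -> ControlMeasurement:
    """Full ground-truth measurement set for one case."""
    ecc, abs_ecc = eccentricity_metrics(zone.max_diameter_mm, zone.min_diameter_mm)
    return ControlMeasurement(
        max_diameter_mm=zone.max_diameter_mm,
        min_diameter_mm=zone.min_diameter_mm,
        length_mm=laa_length(anatomy, zone),
        length_chord_mm=laa_length_chord(anatomy, zone),
        eccentricity=ecc,
        absolute_eccentricity_mm=abs_ecc,
    )
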
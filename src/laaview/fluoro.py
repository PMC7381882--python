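"""Simulated fluoroscopic measurement under three strategies.

All strategies measure the landing-zone diameter and the appendage
length on calibrated orthographic silhouettes, three replicates each
with an independent catheter calibration, averaged:

* ``standard`` — fixed working view RAO30/CAUD20.  The operator has no
  3D guidance, so the measurement endpoints are the (foreshortened)
  projections of the true fiducials, perturbed along the silhouette
  border by landmark jitter.
* ``blinded`` — personalized views, but endpoints are re-detected from
  the silhouette alone (width-profile neck detector below).
* ``referred`` — personalized views with the CT-marked fiducials
  available for reference: endpoints are the true projected fiducials
  and only calibration noise remains.

Fluoroscopic length is always the straight landing-zone-centre-to-tip
chord: a single silhouette cannot reveal the curved 3D centerline, so
the chord-versus-arc difference is itself a modelled error source.

The virtual calibration marker is a 10 mm segment placed in the image
plane at the landing-zone centre (perpendicular to the beam), modelling
an ideally read pigtail catheter; reading imprecision is the
multiplicative ``calib_sd`` noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .anatomy import LAAAnatomy
from .geometry import (
    STANDARD_POSE,
    CalibrationMarker,
    CArmPose,
    Silhouette,
    calibrate,
    image_basis,
    project_mesh,
    project_points,
)
from .landing import LandingZone
from .views import ViewPlan

__all__ = [
    "NoiseModel",
    "MeasurementRecord",
    "measure_standard",
    "measure_blinded",
    "measure_referred",
    "acquire",
    "detect_neck",
]

MARKER_LENGTH_MM = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise configuration.

    ``calib_sd`` — s.d. of the multiplicative scale error per
    calibration iteration (3% default, re-drawn for each replicate).
    ``landmark_sd_mm`` — s.d. of operator landmark jitter along the
    silhouette border (Standard and Blinded strategies).
    ``replicates`` — measurements averaged per reported value.
    """

    calib_sd: float = 0.03
    landmark_sd_mm: float = 1.0
    replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.calib_sd < 0 or self.landmark_sd_mm < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @staticmethod
    def noiseless() -> "NoiseModel":
        return NoiseModel(calib_sd=0.0, landmark_sd_mm=0.0, replicates=1)


@dataclass
class MeasurementRecord:
    """Averaged triplicate measurement of one case under one strategy."""

    case_id: str
    strategy: str
    diameter_mm: float
    length_mm: float
    pose_diameter: CArmPose
    pose_length: CArmPose
    replicate_diameters: list[float] = field(default_factory=list)
    replicate_lengths: list[float] = field(default_factory=list)
    degraded: bool = False  # silhouette neck detection fell back to fiducials


def acquire(anatomy: LAAAnatomy, zone: LandingZone, pose: CArmPose,
            cache: dict | None = None) -> Silhouette:
    """Project the full scene at a pose, carrying the fiducials and the
    calibration marker; optionally memoized per case."""
    key = (round(pose.primary_deg, 6), round(pose.secondary_deg, 6))
    if cache is not None and key in cache:
        return cache[key]
    u, _, _ = image_basis(pose)
    marker = CalibrationMarker.from_endpoints(
        zone.center - 0.5 * MARKER_LENGTH_MM * u,
        zone.center + 0.5 * MARKER_LENGTH_MM * u)
    sil = project_mesh(anatomy.mesh, pose, marker=marker, extra_points={
        "D1": zone.D1, "D2": zone.D2, "center": zone.center,
        "tip": anatomy.landmarks["tip"],
    })
    sil._marker = marker  # kept for per-replicate calibration
    if cache is not None:
        cache[key] = sil
    return sil


_SNAP_LIMIT_MM = 3.0


def _boundary_jitter(sil: Silhouette, q: np.ndarray, sd: float, rng) -> np.ndarray:
    """Operator imprecision for a landmark read off the image.

    When the point lies near the silhouette border (within 3 mm) it is
    snapped onto the border and moved along it by a N(0, sd) arc length —
    rim landmarks are picked on the visible edge.  A point far from any
    border (buried in the cardiac shadow) cannot be snapped meaningfully
    and is jittered isotropically in-plane instead.
    """
    ring = sil.polygon.exterior
    pt = Point(q)
    if pt.distance(ring) <= _SNAP_LIMIT_MM:
        s0 = ring.project(pt)
        s1 = (s0 + rng.normal(0, sd)) % ring.length
        p = ring.interpolate(s1)
        return np.array([p.x, p.y])
    return np.asarray(q, float) + rng.normal(0, sd / np.sqrt(2), size=2)


def _replicate_scales(sil: Silhouette, noise: NoiseModel, rng) -> list[float]:
    scales = []
    for _ in range(noise.replicates):
        eps = float(np.clip(rng.normal(0.0, noise.calib_sd), -0.5, 0.5)) \
            if noise.calib_sd > 0 else 0.0
        scales.append(calibrate(sil, sil._marker, scale_noise=eps).scale)
    return scales


def _measure_points(sil: Silhouette, q1, q2, scales, noise, rng,
                    jitter_first: str = "none", jitter_second: str = "none"):
    """Per-replicate calibrated distances between two image points with
    the configured landmark jitter ('boundary', 'plane' or 'none')."""
    vals = []
    for scale in scales:
        a, b = np.asarray(q1, float), np.asarray(q2, float)
        if noise.landmark_sd_mm > 0:
            if jitter_first == "boundary":
                a = _boundary_jitter(sil, a, noise.landmark_sd_mm, rng)
            elif jitter_first == "plane":
                a = a + rng.normal(0, noise.landmark_sd_mm / np.sqrt(2), size=2)
            if jitter_second == "boundary":
                b = _boundary_jitter(sil, b, noise.landmark_sd_mm, rng)
            elif jitter_second == "plane":
                b = b + rng.normal(0, noise.landmark_sd_mm / np.sqrt(2), size=2)
        vals.append(float(scale * np.linalg.norm(b - a)))
    return vals


def _rim_extent_endpoints(anatomy: LAAAnatomy, zone: LandingZone,
                          pose: CArmPose):
    """Apparent neck width: extent of the projected landing-zone rim
    measured perpendicular to the apparent appendage axis.

    An operator without 3D guidance draws the landing line across the
    visible neck, at a right angle to the appendage's apparent long
    axis.  At an oblique view this span mixes the orifice's long and
    short axes, so the induced underestimation is governed by the
    orifice's absolute eccentricity (plus the view tilt) — the
    shape-driven error mechanism of non-personalized views.
    """
    if zone.contour is None or len(zone.contour) < 3:
        return None
    axis2 = (project_points(anatomy.landmarks["tip"], pose)[0]
             - project_points(zone.center, pose)[0])
    norm = np.linalg.norm(axis2)
    if norm < 1e-9:
        return None
    nhat = np.array([-axis2[1], axis2[0]]) / norm
    pts = project_points(zone.contour, pose)
    proj = pts @ nhat
    return pts[int(np.argmin(proj))], pts[int(np.argmax(proj))]


def measure_standard(anatomy: LAAAnatomy, zone: LandingZone,
                     noise: NoiseModel, rng=None,
                     cache: dict | None = None,
                     pose: CArmPose = STANDARD_POSE) -> MeasurementRecord:
    """Measure at the standard working view.

    Foreshortening of the implantation chord is the dominant length
    error.  With landmark noise enabled the diameter is read as the
    widest visible rim span (see :func:`_rim_extent_endpoints`), so its
    error scales with the orifice's absolute eccentricity; with all
    noise off the measurement reduces to the pure projection of the
    D1-D2 fiducial pair (the L cos(theta) foreshortening law).
    """
    rng = np.random.default_rng(noise.rng_seed) if rng is None else rng
    sil = acquire(anatomy, zone, pose, cache)
    scales = _replicate_scales(sil, noise, rng)
    pp = sil.projected_points
    q1, q2 = pp["D1"], pp["D2"]
    if noise.landmark_sd_mm > 0:
        rim = _rim_extent_endpoints(anatomy, zone, pose)
        if rim is not None:
            q1, q2 = rim
    diam = _measure_points(sil, q1, q2, scales, noise, rng,
                           "boundary", "boundary")
    length = _measure_points(sil, pp["center"], pp["tip"], scales, noise, rng,
                             "plane", "boundary")
    return MeasurementRecord(
        case_id=anatomy.case_id, strategy="standard",
        diameter_mm=float(np.mean(diam)), length_mm=float(np.mean(length)),
        pose_diameter=pose, pose_length=pose,
        replicate_diameters=diam, replicate_lengths=length)


# ---------------------------------------------------------------------------
# silhouette-only landmark detection (Blinded strategy)


def _width_chord(poly, point: np.ndarray, normal2: np.ndarray, reach: float = 300.0):
    """Chord of the silhouette through `point` along `normal2`; returns
    (width, endpoint_a, endpoint_b) of the piece nearest the point."""
    line = LineString([point - reach * normal2, point + reach * normal2])
    inter = poly.intersection(line)
    if inter.is_empty:
        return None
    pieces = list(inter.geoms) if hasattr(inter, "geoms") else [inter]
    pieces = [p for p in pieces if p.geom_type == "LineString" and p.length > 1e-9]
    if not pieces:
        return None
    pt = Point(point)
    seg = min(pieces, key=lambda p: p.distance(pt))
    (xa, ya), (xb, yb) = seg.coords[0], seg.coords[-1]
    return seg.length, np.array([xa, ya]), np.array([xb, yb])


def detect_neck(sil: Silhouette, step_mm: float = 1.0, band_mm: float = 6.0):
    """Detect the landing level on a silhouette alone.

    The scan axis is the projected implantation direction (tip towards
    ostium).  The width profile w(s) of the appendage shadow is examined
    inside a band around the projected ostium level: the landing level is
    the most proximal local width minimum in the band (the narrowest
    "waist"); if the profile is monotone, the level just distal to the
    flare into the atrial shadow is used.  Returns (endpoint_a,
    endpoint_b, midpoint) in image mm, or None when no neck exists.
    """
    pp = sil.projected_points
    tip2, ost2 = pp["tip"], pp["center"]
    axis = ost2 - tip2
    s_ost = float(np.linalg.norm(axis))
    if s_ost < 1e-6:
        return None
    ahat = axis / s_ost
    nhat = np.array([-ahat[1], ahat[0]])
    poly = sil.polygon

    s_grid = np.arange(max(1.0, 0.15 * s_ost), s_ost + band_mm + 4.0, step_mm)
    widths, chords = [], []
    for s in s_grid:
        res = _width_chord(poly, tip2 + s * ahat, nhat)
        if res is None:
            widths.append(np.nan)
            chords.append(None)
        else:
            widths.append(res[0])
            chords.append((res[1], res[2]))
    w = np.asarray(widths)
    in_band = (s_grid >= s_ost - band_mm) & (s_grid <= s_ost + band_mm)

    # local minima inside the band (2% prominence over both neighbours)
    minima = []
    for i in range(1, len(s_grid) - 1):
        if not in_band[i] or not np.isfinite(w[i - 1:i + 2]).all():
            continue
        if w[i] < 0.98 * w[i - 1] and w[i] <= w[i + 1]:
            minima.append(i)
    if minima:
        i = max(minima)  # most proximal (closest to the atrial body)
    else:
        # monotone neck: stop just distal to the flare into the LA shadow
        i = None
        for k in range(len(s_grid) - 1):
            if not np.isfinite(w[k]) or not np.isfinite(w[k + 1]):
                continue
            if s_grid[k] >= s_ost - band_mm and w[k + 1] - w[k] > 0.35 * w[k]:
                i = k
                break
        if i is None:
            candidates = np.where(in_band & np.isfinite(w))[0]
            if len(candidates) == 0:
                return None
            i = int(candidates[np.argmin(np.abs(s_grid[candidates] - s_ost))])
    if chords[i] is None:
        return None
    a, b = chords[i]
    return a, b, 0.5 * (a + b)


def _farthest_boundary_point(sil: Silhouette, origin: np.ndarray,
                             direction: np.ndarray) -> np.ndarray:
    """Silhouette boundary vertex farthest from `origin` in the half-plane
    pointed to by `direction` (keeps the search on the appendage side)."""
    pts = sil.outer_boundary
    side = (pts - origin) @ direction
    cand = pts[side > 0] if np.any(side > 0) else pts
    d = np.linalg.norm(cand - origin, axis=1)
    return cand[int(np.argmax(d))]


def measure_blinded(anatomy: LAAAnatomy, zone: LandingZone, plan: ViewPlan,
                    noise: NoiseModel, rng=None, cache: dict | None = None,
                    detector: str = "silhouette") -> MeasurementRecord:
    """Measure at personalized views with landmarks re-detected from the
    silhouette (no 3D reference).  ``detector='fiducials'`` forces the
    true projected fiducials, collapsing the strategy onto Referred."""
    rng = np.random.default_rng(noise.rng_seed) if rng is None else rng
    sil_d = acquire(anatomy, zone, plan.diameter_pose, cache)
    sil_l = (sil_d if plan.combined
             else acquire(anatomy, zone, plan.length_pose, cache))

    degraded = False
    if detector == "silhouette":
        neck_d = detect_neck(sil_d)
        neck_l = neck_d if plan.combined else detect_neck(sil_l)
    else:
        neck_d = neck_l = None
    if neck_d is not None:
        q1, q2, _ = neck_d
    else:
        q1, q2 = sil_d.projected_points["D1"], sil_d.projected_points["D2"]
        degraded = detector == "silhouette"
    if neck_l is not None:
        mid_l = neck_l[2]
        tipward = sil_l.projected_points["tip"] - sil_l.projected_points["center"]
        tip2 = _farthest_boundary_point(sil_l, mid_l, tipward)
    else:
        mid_l = sil_l.projected_points["center"]
        tip2 = sil_l.projected_points["tip"]
        degraded = degraded or detector == "silhouette"

    scales_d = _replicate_scales(sil_d, noise, rng)
    diam = _measure_points(sil_d, q1, q2, scales_d, noise, rng,
                           "boundary", "boundary")
    scales_l = _replicate_scales(sil_l, noise, rng)
    length = _measure_points(sil_l, mid_l, tip2, scales_l, noise, rng,
                             "plane", "boundary")
    return MeasurementRecord(
        case_id=anatomy.case_id, strategy="blinded",
        diameter_mm=float(np.mean(diam)), length_mm=float(np.mean(length)),
        pose_diameter=plan.diameter_pose, pose_length=plan.length_pose,
        replicate_diameters=diam, replicate_lengths=length, degraded=degraded)


def measure_referred(anatomy: LAAAnatomy, zone: LandingZone, plan: ViewPlan,
                     noise: NoiseModel, rng=None,
                     cache: dict | None = None) -> MeasurementRecord:
    """Measure at personalized views with the CT fiducials marked for
    reference: landmark mis-selection is removed and only calibration
    noise remains."""
    rng = np.random.default_rng(noise.rng_seed) if rng is None else rng
    sil_d = acquire(anatomy, zone, plan.diameter_pose, cache)
    sil_l = (sil_d if plan.combined
             else acquire(anatomy, zone, plan.length_pose, cache))
    scales_d = _replicate_scales(sil_d, noise, rng)
    scales_l = _replicate_scales(sil_l, noise, rng)
    d_px = float(np.linalg.norm(sil_d.projected_points["D2"]
                                - sil_d.projected_points["D1"]))
    l_px = float(np.linalg.norm(sil_l.projected_points["tip"]
                                - sil_l.projected_points["center"]))
    diam = [s * d_px for s in scales_d]
    length = [s * l_px for s in scales_l]
    return MeasurementRecord(
        case_id=anatomy.case_id, strategy="referred",
        diameter_mm=float(np.mean(diam)), length_mm=float(np.mean(length)),
        pose_diameter=plan.diameter_pose, pose_length=plan.length_pose,
        replicate_diameters=diam, replicate_lengths=length)
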
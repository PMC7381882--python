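"""Parametric synthetic left-atrial-appendage (LAA) anatomies.

Real LAA geometry comes from segmented cardiac CT; this module generates
digital stand-ins with known ground truth.  Each anatomy is a watertight
triangle mesh (millimetres) built from swept elliptical tubes along a
parametric centerline, attached to an ellipsoidal left-atrium (LA) body,
with constructive landmarks:

* ``lupv_limbus`` — point on the LA body surface 1-2 cm posterior to the
  superior orifice rim (the left-upper-pulmonary-vein ridge),
* ``inferior_deflection`` — inferior orifice rim point,
* ``tip`` — distal end of the dominant lobe.

Six classical morphologies are emulated.  Their construction rules are
qualitative caricatures chosen to reproduce the documented measurement
error mechanisms, not patient statistics:

* ``windsock`` — single straight dominant lobe, gentle taper.
* ``cactus`` — dominant central lobe with small secondary lobes.
* ``cone`` — straight lobe with a steep monotone taper.
* ``chicken_wing`` — sharp centerline bend in the proximal/mid segment.
* ``bilobed`` — two comparable lobes from a shared proximal trunk.
* ``cauliflower`` — short appendage, lumpy wall, indistinct shoulders
  (a para-ostial bulge blurs the neck on silhouettes).

Overlapping closed components (lobes, bumps, LA body) are stored
concatenated rather than boolean-unioned: every component is watertight
on its own, shadows and plane sections are computed component-aware, so
all measured quantities are identical to those of the true union.

The canonical construction frame before ``body_orientation`` is applied:
orifice centre at the origin, appendage axis along -y (anterior), orifice
long axis along z (superior); the LA body sits posteriorly (+y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, GenerationError, ParameterError

__all__ = [
    "MorphologyLabel",
    "SELECTED_MORPHOLOGIES",
    "TABLE_MORPHOLOGY_MIX",
    "AnatomyParams",
    "ParamRanges",
    "LAAAnatomy",
    "generate_case",
    "generate_cohort",
    "export_stl",
    "import_stl",
    "cohort_manifest",
]


class MorphologyLabel(str, Enum):
    WINDSOCK = "windsock"
    CACTUS = "cactus"
    CAULIFLOWER = "cauliflower"
    CHICKEN_WING = "chicken_wing"
    CONE = "cone"
    BILOBED = "bilobed"


#: Morphologies grouped as error-prone for regression analysis.
SELECTED_MORPHOLOGIES = frozenset({
    MorphologyLabel.CONE, MorphologyLabel.BILOBED,
    MorphologyLabel.CAULIFLOWER, MorphologyLabel.CHICKEN_WING,
})

#: Default cohort morphology frequencies (28-patient study mix).
TABLE_MORPHOLOGY_MIX: dict[MorphologyLabel, float] = {
    MorphologyLabel.WINDSOCK: 15 / 28,
    MorphologyLabel.CACTUS: 4 / 28,
    MorphologyLabel.BILOBED: 3 / 28,
    MorphologyLabel.CHICKEN_WING: 3 / 28,
    MorphologyLabel.CONE: 2 / 28,
    MorphologyLabel.CAULIFLOWER: 1 / 28,
}


@dataclass(frozen=True)
class AnatomyParams:
    """Ground-truth parameters of one synthetic anatomy.

    ``orifice_long_axis_mm``/``orifice_short_axis_mm`` are full ellipse
    diameters of the orifice cross-section; ``length_mm`` is the arc
    length of the cavity centerline from orifice centre to tip;
    ``lupv_offset_mm`` is the anterior distance from the LUPV limbus to
    the superior orifice rim (1-2 cm anatomically); ``body_orientation``
    is a rotation matrix applied to the whole anatomy about the orifice
    centre.
    """

    morphology: MorphologyLabel
    orifice_long_axis_mm: float
    orifice_short_axis_mm: float
    length_mm: float
    bend_angle_deg: float = 80.0   # chicken_wing only
    lobe_count: int = 1
    taper_ratio: float = 0.65
    lupv_offset_mm: float = 15.0
    body_orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3))

    def validate(self) -> None:
        p = self
        if p.orifice_long_axis_mm <= 0 or p.orifice_short_axis_mm <= 0:
            raise ParameterError("orifice axes must be positive")
        if p.orifice_short_axis_mm > p.orifice_long_axis_mm + 1e-9:
            raise ParameterError("short axis exceeds long axis")
        if p.length_mm <= 0:
            raise ParameterError("length must be positive")
        if not 0.0 < p.taper_ratio <= 1.0:
            raise ParameterError("taper_ratio must be in (0, 1]")
        if not 10.0 <= p.lupv_offset_mm <= 20.0:
            raise ParameterError("lupv_offset_mm must be in [10, 20] mm")
        if p.lobe_count < 1:
            raise ParameterError("lobe_count must be >= 1")
        R = np.asarray(p.body_orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ParameterError("body_orientation must be a 3x3 rotation matrix")


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for cohort generation (mm / degrees)."""

    orifice_long_mm: tuple[float, float] = (14.0, 34.0)
    axis_ratio: tuple[float, float] = (0.65, 0.95)
    length_mm: tuple[float, float] = (20.0, 45.0)
    taper_ratio: tuple[float, float] = (0.5, 0.8)
    cone_taper_ratio: tuple[float, float] = (0.12, 0.3)
    bend_angle_deg: tuple[float, float] = (60.0, 100.0)
    lupv_offset_mm: tuple[float, float] = (11.0, 19.0)
    rotation_max_deg: float = 30.0          # body tilt about each patient axis
    orifice_rotation_max_deg: float = 90.0  # orifice major-axis spin (arbitrary anatomically)

    def validate(self) -> None:
        for name in ("orifice_long_mm", "axis_ratio", "length_mm",
                     "taper_ratio", "cone_taper_ratio", "bend_angle_deg",
                     "lupv_offset_mm"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ParameterError(f"empty range for {name}: ({lo}, {hi})")


@dataclass
class LAAAnatomy:
    """A synthetic LAA + LA-body anatomy with ground-truth annotations."""

    appendage_mesh: trimesh.Trimesh   # LAA tube + lobes/bumps (closed components)
    body_mesh: trimesh.Trimesh        # LA body ellipsoid
    landmarks: dict[str, np.ndarray]  # lupv_limbus, inferior_deflection, tip
    centerline: np.ndarray            # (n, 3) orifice centre -> tip
    anterior_axis: np.ndarray         # unit vector, local anterior direction
    morphology: MorphologyLabel
    truth: AnatomyParams
    branch_tips: list[np.ndarray] = field(default_factory=list)
    edge_length_mm: float = 1.0
    case_id: str = "case"
    rng_seed: int = 0

    @property
    def mesh(self) -> trimesh.Trimesh:
        """Full scene (appendage + LA body) for silhouette projection."""
        return trimesh.util.concatenate([self.appendage_mesh, self.body_mesh])

    def transformed(self, R: np.ndarray, t: np.ndarray | None = None) -> "LAAAnatomy":
        """Rigidly transformed copy (for equivariance checks)."""
        R = np.asarray(R, dtype=float)
        t = np.zeros(3) if t is None else np.asarray(t, dtype=float)

        def tf_mesh(m):
            return trimesh.Trimesh(vertices=m.vertices @ R.T + t,
                                   faces=m.faces.copy(), process=False)

        return LAAAnatomy(
            appendage_mesh=tf_mesh(self.appendage_mesh),
            body_mesh=tf_mesh(self.body_mesh),
            landmarks={k: R @ v + t for k, v in self.landmarks.items()},
            centerline=self.centerline @ R.T + t,
            anterior_axis=R @ self.anterior_axis,
            morphology=self.morphology,
            truth=self.truth,
            branch_tips=[R @ p + t for p in self.branch_tips],
            edge_length_mm=self.edge_length_mm,
            case_id=self.case_id,
            rng_seed=self.rng_seed,
        )


# ---------------------------------------------------------------------------
# swept-tube construction


def _parallel_frames(points: np.ndarray, e1_init: np.ndarray):
    """Parallel-transport orthonormal frames (e1, e2, tangent) along a path."""
    pts = np.asarray(points, dtype=float)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    e1 = np.empty_like(pts)
    e2 = np.empty_like(pts)
    v = np.asarray(e1_init, dtype=float)
    for i, t in enumerate(tangents):
        v = v - np.dot(v, t) * t
        n = np.linalg.norm(v)
        if n < 1e-9:  # degenerate start vector; pick any perpendicular
            v = np.cross(t, [1.0, 0.0, 0.0])
            if np.linalg.norm(v) < 1e-6:
                v = np.cross(t, [0.0, 1.0, 0.0])
            n = np.linalg.norm(v)
        v = v / n
        e1[i] = v
        e2[i] = np.cross(t, v)
    return e1, e2, tangents


def _sweep_tube(path: np.ndarray, a_profile: np.ndarray, b_profile: np.ndarray,
                n_theta: int, e1_init: np.ndarray) -> trimesh.Trimesh:
    """Closed swept elliptical tube with flat cap fans at both ends.

    Winding is arranged so normals point outward (positive volume).
    """
    m = len(path)
    if n_theta % 2:
        n_theta += 1
    e1, e2, _ = _parallel_frames(path, e1_init)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ct, st = np.cos(theta), np.sin(theta)
    # rings[i, j] = path[i] + a_i cos(t_j) e1_i + b_i sin(t_j) e2_i
    rings = (path[:, None, :]
             + a_profile[:, None, None] * ct[None, :, None] * e1[:, None, :]
             + b_profile[:, None, None] * st[None, :, None] * e2[:, None, :])
    verts = rings.reshape(-1, 3)
    c0 = len(verts)
    verts = np.vstack([verts, path[0], path[-1]])
    c1 = c0 + 1

    idx = np.arange(n_theta)
    jn = (idx + 1) % n_theta
    faces = []
    for i in range(m - 1):
        r0 = i * n_theta
        r1 = (i + 1) * n_theta
        faces.append(np.column_stack([r0 + idx, r0 + jn, r1 + jn]))
        faces.append(np.column_stack([r0 + idx, r1 + jn, r1 + idx]))
    faces.append(np.column_stack([np.full(n_theta, c0), jn, idx]))            # start cap
    last = (m - 1) * n_theta
    faces.append(np.column_stack([np.full(n_theta, c1), last + idx, last + jn]))  # end cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rot_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    return trimesh.transformations.rotation_matrix(
        np.deg2rad(angle_deg), axis)[:3, :3]


def _body_geometry(params: AnatomyParams) -> tuple[np.ndarray, np.ndarray]:
    """LA-body ellipsoid (centre, radii) placed so the LUPV limbus lies
    at the truth anterior offset from the superior orifice rim."""
    a0 = params.orifice_long_axis_mm / 2.0
    rx, ry, rz = 24.0, 20.0, 26.0
    zc = -4.0
    root = 1.0 - ((a0 - zc) / rz) ** 2
    if root <= 0.05:
        rz = (a0 - zc) / np.sqrt(0.95)
        root = 1.0 - ((a0 - zc) / rz) ** 2
    yc = params.lupv_offset_mm + ry * np.sqrt(root)
    return np.array([0.0, yc, zc]), np.array([rx, ry, rz])


def _neck_extension(params: AnatomyParams) -> float:
    """Proximal tube extension (mm) guaranteeing overlap with the body."""
    centre, radii = _body_geometry(params)
    front_y = centre[1] - radii[1] * np.sqrt(1.0 - (centre[2] / radii[2]) ** 2)
    return float(front_y + 6.0)


def _centerline_points(params: AnatomyParams, step: float) -> np.ndarray:
    """Sampled cavity centerline from orifice centre (origin) to tip,
    in the canonical frame; arc length equals ``params.length_mm``."""
    L = params.length_mm
    d = np.array([0.0, -1.0, 0.0])  # anterior
    if params.morphology is MorphologyLabel.CHICKEN_WING:
        # straight proximal arm, circular bend, straight distal arm
        r_bend = 5.0
        ang = np.deg2rad(params.bend_angle_deg)
        arc_len = r_bend * ang
        s_bend = min(max(10.0, 0.35 * L), max(L - arc_len - 2.0, 2.0))
        s_rest = max(L - s_bend - arc_len, 0.5)
        pts = [np.array([0.0, 0.0, 0.0])]
        n1 = max(2, int(np.ceil(s_bend / step)))
        for s in np.linspace(0, s_bend, n1)[1:]:
            pts.append(s * d)
        # bend in the (anterior, left) plane, turning toward +x
        centre = s_bend * d + r_bend * np.array([1.0, 0.0, 0.0])
        n2 = max(4, int(np.ceil(arc_len / step)))
        for phi in np.linspace(0, ang, n2)[1:]:
            pts.append(centre + r_bend * (-np.cos(phi) * np.array([1.0, 0.0, 0.0])
                                          + np.sin(phi) * d))
        d2 = np.cos(ang) * d + np.sin(ang) * np.array([1.0, 0.0, 0.0])
        start = pts[-1]
        n3 = max(2, int(np.ceil(s_rest / step)))
        for s in np.linspace(0, s_rest, n3)[1:]:
            pts.append(start + s * d2)
        return np.asarray(pts)
    if params.morphology is MorphologyLabel.BILOBED:
        # trunk to 45% depth, then the dominant lobe direction
        s_j = 0.45 * L
        lobe_dir = _rot_about(np.array([0.0, 0.0, 1.0]), 35.0) @ d
        n1 = max(2, int(np.ceil(s_j / step)))
        n2 = max(2, int(np.ceil((L - s_j) / step)))
        pts = [s * d for s in np.linspace(0, s_j, n1)]
        start = pts[-1]
        pts += [start + s * lobe_dir for s in np.linspace(0, L - s_j, n2)[1:]]
        return np.asarray(pts)
    # straight morphologies
    n = max(2, int(np.ceil(L / step)))
    return np.linspace([0, 0, 0], (L * d).tolist(), n)


def _radius_profiles(params: AnatomyParams, s: np.ndarray, ext: float,
                     rng) -> tuple[np.ndarray, np.ndarray]:
    """Semi-axis profiles a(s), b(s) along stations s (s=0 at orifice;
    negative s is the proximal extension into the LA body)."""
    L = params.length_mm
    a0 = params.orifice_long_axis_mm / 2.0
    b0 = params.orifice_short_axis_mm / 2.0
    x = np.clip(s / L, 0.0, 1.0)
    base = 1.0 + (params.taper_ratio - 1.0) * x
    # proximal trumpet flare inside the body
    prox = np.where(s < 0, 1.0 + 0.3 * (-s / ext), 1.0)
    mod = np.ones_like(x)
    if params.morphology is MorphologyLabel.CAULIFLOWER:
        # lumpy wall and a para-ostial bulge, starting distal to the
        # orifice so the ground-truth orifice section stays exact
        phase = rng.uniform(0, 2 * np.pi)
        ramp = _smoothstep((x - 0.12) / 0.18)
        mod = 1.0 + ramp * (0.16 * np.sin(2.5 * np.pi * x + phase)
                            + 0.22 * np.exp(-((x - 0.28) / 0.12) ** 2))
    a = a0 * base * prox * mod
    b = b0 * base * prox * mod
    return a, b


def _build_appendage(params: AnatomyParams, edge: float, rng):
    """Main tube + extra lobes/bumps; returns (mesh, centerline, branch_tips)."""
    L = params.length_mm
    a0 = params.orifice_long_axis_mm / 2.0
    b0 = params.orifice_short_axis_mm / 2.0
    step = max(edge, 0.5)
    n_theta = int(np.ceil(np.pi * (a0 + b0) / edge))
    n_theta = max(24, n_theta + (n_theta % 2))
    e1_init = np.array([0.0, 0.0, 1.0])  # orifice long axis: superior

    centerline = _centerline_points(params, step)
    # stations along the full swept path (proximal extension + centerline)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s_center = np.concatenate([[0.0], np.cumsum(seg)])
    ext = _neck_extension(params)
    n_ext = max(3, int(np.ceil(ext / step)))
    ext_pts = np.outer(np.linspace(-ext, 0, n_ext)[:-1], [0.0, -1.0, 0.0])
    path = np.vstack([ext_pts, centerline])
    s_path = np.concatenate([np.linspace(-ext, 0, n_ext)[:-1], s_center])
    a_prof, b_prof = _radius_profiles(params, s_path, ext, rng)
    # close the distal end smoothly toward the cap
    tipfrac = np.clip((s_path - 0.92 * L) / (0.08 * L), 0.0, 1.0)
    shrink = np.sqrt(np.clip(1.0 - tipfrac**2, 0.04, 1.0))
    a_prof = a_prof * shrink
    b_prof = b_prof * shrink

    main = _sweep_tube(path, a_prof, b_prof, n_theta, e1_init)
    parts = [main]
    branch_tips: list[np.ndarray] = []
    d = np.array([0.0, -1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])

    def _lobe(origin, direction, length, ra, rb, nth=None):
        nth = nth or max(16, int(np.ceil(2 * np.pi * ra / edge)))
        nth += nth % 2
        n = max(3, int(np.ceil(length / step)))
        pth = origin + np.outer(np.linspace(0, length, n), direction)
        xs = np.linspace(0, 1, n)
        prof = 1.0 - 0.3 * xs
        tf = np.clip((xs - 0.85) / 0.15, 0, 1)
        sh = np.sqrt(np.clip(1 - tf**2, 0.05, 1.0))
        e1l = z - np.dot(z, direction) * np.asarray(direction)
        if np.linalg.norm(e1l) < 1e-6:
            e1l = np.array([1.0, 0.0, 0.0])
        tube = _sweep_tube(pth, ra * prof * sh, rb * prof * sh, nth, e1l)
        branch_tips.append(pth[-1])
        return tube

    if params.morphology is MorphologyLabel.BILOBED:
        # secondary lobe opposite the dominant one
        origin = 0.45 * L * d
        n_extra = max(1, params.lobe_count - 1)
        for k in range(n_extra):
            ang = -40.0 - 15.0 * k
            direction = _rot_about(z, ang) @ d
            parts.append(_lobe(origin, direction, 0.45 * L,
                               0.55 * a0, 0.55 * b0))
    elif params.morphology is MorphologyLabel.CACTUS:
        for k, (frac, ang, tilt) in enumerate(
                [(0.35, 70.0, 25.0), (0.6, -65.0, -20.0)][:max(1, params.lobe_count)]):
            origin = frac * L * d
            direction = _rot_about(np.array([1.0, 0.0, 0.0]), tilt) @ (_rot_about(z, ang) @ d)
            parts.append(_lobe(origin, direction, 0.25 * L, 0.4 * a0, 0.4 * b0))
    elif params.morphology is MorphologyLabel.CAULIFLOWER:
        # surface bumps mid-to-distal
        for frac, ang in [(0.45, 0.6), (0.7, 2.8), (0.55, 4.2)]:
            c = frac * L * d
            a_here = a0 * (1 + (params.taper_ratio - 1) * frac)
            radial = np.cos(ang) * z + np.sin(ang) * np.array([1.0, 0.0, 0.0])
            rb = 0.35 * a_here
            bump = trimesh.creation.icosphere(subdivisions=2, radius=rb)
            bump.apply_translation(c + radial * a_here)
            parts.append(bump)
            branch_tips.append(c + radial * (a_here + rb))

    mesh = trimesh.util.concatenate(parts) if len(parts) > 1 else main
    return mesh, centerline, branch_tips


def _closest_surface_point(mesh: trimesh.Trimesh, point: np.ndarray) -> np.ndarray:
    """Exact nearest point on the mesh surface (brute force over faces)."""
    tris = mesh.triangles
    cand = trimesh.triangles.closest_point(tris, np.tile(point, (len(tris), 1)))
    d = np.linalg.norm(cand - point, axis=1)
    return cand[int(np.argmin(d))]


def _build_body(params: AnatomyParams, edge: float):
    """Discretized LA body with the snapped limbus landmark; returns
    (mesh, limbus)."""
    a0 = params.orifice_long_axis_mm / 2.0
    centre, radii = _body_geometry(params)
    sub = 4 if edge <= 1.5 else 3
    body = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    body = trimesh.Trimesh(vertices=body.vertices * radii + centre,
                           faces=body.faces, process=False)
    limbus_exact = np.array([0.0, params.lupv_offset_mm, a0])
    return body, _closest_surface_point(body, limbus_exact)


def generate_case(params: AnatomyParams, rng_seed: int,
                  edge_length_mm: float = 1.0) -> LAAAnatomy:
    """Build one synthetic anatomy; identical (params, seed) gives an
    identical mesh.  Retries at finer resolution if a component fails the
    watertightness check, then raises :class:`GenerationError`.
    """
    params.validate()
    for attempt, edge in enumerate([edge_length_mm, edge_length_mm / 2.0]):
        rng = np.random.default_rng(rng_seed)
        appendage, centerline, branch_tips = _build_appendage(params, edge, rng)
        body, limbus = _build_body(params, edge)
        ok = all(trimesh.Trimesh(vertices=m.vertices, faces=m.faces,
                                 process=False).is_watertight
                 for m in [appendage, body])
        if ok:
            break
    else:
        raise GenerationError("could not build a watertight anatomy")

    a0 = params.orifice_long_axis_mm / 2.0
    landmarks = {
        "lupv_limbus": limbus,
        "inferior_deflection": np.array([0.0, 0.0, -a0]),
        "tip": centerline[-1].copy(),
    }
    anatomy = LAAAnatomy(
        appendage_mesh=appendage, body_mesh=body, landmarks=landmarks,
        centerline=centerline, anterior_axis=np.array([0.0, -1.0, 0.0]),
        morphology=params.morphology, truth=params,
        branch_tips=branch_tips, edge_length_mm=edge,
        rng_seed=int(rng_seed),
    )
    R = np.asarray(params.body_orientation, dtype=float)
    if not np.allclose(R, np.eye(3)):
        anatomy = anatomy.transformed(R)
    return anatomy


def _sample_params(morph: MorphologyLabel, ranges: ParamRanges, rng) -> AnatomyParams:
    long_mm = rng.uniform(*ranges.orifice_long_mm)
    ratio = rng.uniform(*ranges.axis_ratio)
    lo, hi = ranges.length_mm
    if morph is MorphologyLabel.CAULIFLOWER:
        lo, hi = lo * 0.7, lo + 0.35 * (hi - lo)
    length = rng.uniform(lo, hi)
    taper = rng.uniform(*(ranges.cone_taper_ratio
                          if morph is MorphologyLabel.CONE
                          else ranges.taper_ratio))
    bend = rng.uniform(*ranges.bend_angle_deg)
    offset = rng.uniform(*ranges.lupv_offset_mm)
    lobes = 2 if morph in (MorphologyLabel.BILOBED, MorphologyLabel.CACTUS) else 1
    # spin of the orifice major axis about the appendage axis (canonical -y),
    # then a moderate rigid tilt of the whole anatomy
    psi = np.deg2rad(rng.uniform(-ranges.orifice_rotation_max_deg,
                                 ranges.orifice_rotation_max_deg))
    R_spin = trimesh.transformations.rotation_matrix(psi, [0, 1, 0])[:3, :3]
    ang = np.deg2rad(rng.uniform(-ranges.rotation_max_deg,
                                 ranges.rotation_max_deg, size=3))
    R = trimesh.transformations.euler_matrix(*ang, axes="sxyz")[:3, :3] @ R_spin
    return AnatomyParams(
        morphology=morph, orifice_long_axis_mm=long_mm,
        orifice_short_axis_mm=long_mm * ratio, length_mm=length,
        bend_angle_deg=bend, lobe_count=lobes, taper_ratio=taper,
        lupv_offset_mm=offset, body_orientation=R,
    )


def generate_cohort(n: int, morphology_mix: dict[MorphologyLabel, float] | None = None,
                    param_ranges: ParamRanges | None = None,
                    rng_seed: int = 0,
                    edge_length_mm: float = 1.0) -> list[LAAAnatomy]:
    """Generate ``n`` anatomies with morphologies drawn from the mix
    (default: the 28-patient study frequencies) and parameters sampled
    uniformly from ``param_ranges``."""
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    mix = dict(morphology_mix or TABLE_MORPHOLOGY_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"morphology frequencies sum to {total}, not 1")
    ranges = param_ranges or ParamRanges()
    ranges.validate()
    rng = np.random.default_rng(rng_seed)
    labels = sorted(mix, key=lambda m: m.value)
    probs = np.array([mix[m] for m in labels])
    draws = rng.choice(len(labels), size=n, p=probs)
    cohort = []
    for i, k in enumerate(draws):
        params = _sample_params(labels[k], ranges, rng)
        seed = int(rng.integers(0, 2**31 - 1))
        case = generate_case(params, seed, edge_length_mm=edge_length_mm)
        case.case_id = f"case_{i:03d}"
        cohort.append(case)
    return cohort


# ---------------------------------------------------------------------------
# STL + sidecar I/O


def export_stl(anatomy: LAAAnatomy, path: str | Path) -> Path:
    """Write the anatomy as binary STL plus a JSON landmark sidecar.

    The sidecar (``<stem>.landmarks.json``) carries the three landmarks,
    the anterior axis, the centerline and the morphology label so the
    anatomy can be re-imported losslessly for measurement.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    anatomy.mesh.export(path, file_type="stl")
    sidecar = {
        "lupv_limbus": anatomy.landmarks["lupv_limbus"].tolist(),
        "inferior_deflection": anatomy.landmarks["inferior_deflection"].tolist(),
        "tip": anatomy.landmarks["tip"].tolist(),
        "anterior_axis": anatomy.anterior_axis.tolist(),
        "centerline": np.asarray(anatomy.centerline).tolist(),
        "morphology": anatomy.morphology.value,
        "n_appendage_faces": int(len(anatomy.appendage_mesh.faces)),
    }
    path.with_suffix(".landmarks.json").write_text(json.dumps(sidecar))
    return path


def import_stl(path: str | Path, landmark_sidecar: str | Path | None = None) -> LAAAnatomy:
    """Read an STL mesh with its landmark sidecar back into an anatomy.

    Round trip preserves vertex coordinates to STL float32 precision.
    Raises :class:`FormatError` if the sidecar is missing or incomplete.
    """
    path = Path(path)
    sidecar_path = Path(landmark_sidecar) if landmark_sidecar else path.with_suffix(".landmarks.json")
    if not sidecar_path.exists():
        raise FormatError(f"landmark sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("lupv_limbus", "inferior_deflection", "tip"):
        if key not in meta:
            raise FormatError(f"sidecar missing landmark '{key}'")
    mesh = trimesh.load(path, force="mesh", process=True)
    if mesh.is_empty or len(mesh.faces) == 0:
        raise FormatError(f"no triangles parsed from {path}")
    if not mesh.is_watertight:
        raise FormatError(
            f"imported mesh is not watertight ({len(mesh.faces)} faces, "
            f"{len(trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1))} boundary edges)")
    n_app = meta.get("n_appendage_faces")
    if n_app:
        app = trimesh.Trimesh(vertices=mesh.vertices,
                              faces=mesh.faces[:n_app], process=True)
        body = trimesh.Trimesh(vertices=mesh.vertices,
                               faces=mesh.faces[n_app:], process=True)
    else:
        app, body = mesh, trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                          faces=np.zeros((0, 3), dtype=int))
    morph = MorphologyLabel(meta.get("morphology", "windsock"))
    centerline = np.asarray(meta.get("centerline", [meta["tip"]]), dtype=float)
    params = AnatomyParams(
        morphology=morph,
        orifice_long_axis_mm=1.0, orifice_short_axis_mm=1.0, length_mm=1.0)
    return LAAAnatomy(
        appendage_mesh=app, body_mesh=body,
        landmarks={k: np.asarray(meta[k], dtype=float)
                   for k in ("lupv_limbus", "inferior_deflection", "tip")},
        centerline=centerline,
        anterior_axis=np.asarray(meta.get("anterior_axis", [0, -1, 0]), dtype=float),
        morphology=morph, truth=params,
        edge_length_mm=0.0, case_id=path.stem,
    )


def cohort_manifest(cohort: list[LAAAnatomy]):
    """Cohort summary table (one row per case, ground-truth parameters)."""
    import pandas as pd

    rows = []
    for c in cohort:
        t = c.truth
        rows.append({
            "case_id": c.case_id, "morphology": c.morphology.value,
            "orifice_long_axis_mm": t.orifice_long_axis_mm,
            "orifice_short_axis_mm": t.orifice_short_axis_mm,
            "length_mm": t.length_mm, "taper_ratio": t.taper_ratio,
            "bend_angle_deg": t.bend_angle_deg,
            "lupv_offset_mm": t.lupv_offset_mm,
        })
    return pd.DataFrame(rows)
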
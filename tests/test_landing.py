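"""Landing-zone location, cross-section diameters, length, eccentricity."""

import numpy as np
import pytest
import trimesh

import laaview as lv
from laaview.anatomy import LAAAnatomy, AnatomyParams, MorphologyLabel
from laaview.errors import ParameterError
from laaview.landing import (LandingZone, _calipers, laa_length,
                             laa_length_chord, locate_landing_zone)

from conftest import rigid_rotation


def _stub_anatomy(mesh, centerline, tip=None, anterior=(0, -1, 0)):
    """Wrap a bare mesh in the anatomy container for landing operations."""
    centerline = np.asarray(centerline, dtype=float)
    return LAAAnatomy(
        appendage_mesh=mesh, body_mesh=mesh, landmarks={
            "lupv_limbus": centerline[0], "inferior_deflection": centerline[0],
            "tip": np.asarray(tip if tip is not None else centerline[-1], float)},
        centerline=centerline, anterior_axis=np.asarray(anterior, float),
        morphology=MorphologyLabel.WINDSOCK,
        truth=AnatomyParams(MorphologyLabel.WINDSOCK, 1, 1, 1))


class TestLocateLandingZone:
    def test_straight_windsock_plane_perpendicular(self, windsock, windsock_zone):
        # canonical appendage axis is -y; the plane normal should align
        normal = windsock_zone.plane_normal
        angle = np.degrees(np.arccos(abs(np.dot(normal, [0, -1, 0]))))
        assert angle < 2.0
        assert windsock_zone.perpendicularity > 0.999
        assert not windsock_zone.warning

    def test_finer_scan_agrees_within_one_step(self, windsock):
        z_coarse = locate_landing_zone(windsock, step_mm=0.5)
        z_fine = locate_landing_zone(windsock, step_mm=0.1)
        assert abs(z_coarse.lupv_offset_mm - z_fine.lupv_offset_mm) <= 0.5 + 1e-9
        assert abs(z_coarse.max_diameter_mm - z_fine.max_diameter_mm) < 0.25

    def test_rigid_equivariance(self, windsock, windsock_zone):
        R = rigid_rotation([0.3, 1.0, -0.2], 33.0)
        rotated = windsock.transformed(R)
        zr = lv.locate_landing_zone(rotated)
        assert zr.max_diameter_mm == pytest.approx(
            windsock_zone.max_diameter_mm, rel=1e-6)
        fid = {tuple(np.round(R @ p, 4))
               for p in (windsock_zone.D1, windsock_zone.D2)}
        fid_r = {tuple(np.round(p, 4)) for p in (zr.D1, zr.D2)}
        assert fid == fid_r

    def test_chicken_wing_zone_proximal_to_bend(self):
        p = AnatomyParams(MorphologyLabel.CHICKEN_WING, 24, 20, 35,
                          bend_angle_deg=85.0)
        a = lv.generate_case(p, 6)
        zone = lv.locate_landing_zone(a)
        # the bend starts at >= 10 mm depth; the cut plane must sit proximal
        t = np.diff(a.centerline, axis=0)
        t /= np.linalg.norm(t, axis=1)[:, None]
        turn = np.degrees(np.arccos(np.clip((t[:-1] * t[1:]).sum(axis=1), -1, 1)))
        bend_point = a.centerline[1 + int(np.argmax(turn > 2.0))]
        d_signed = np.dot(bend_point - zone.plane_point, zone.plane_normal)
        d_orifice = np.dot(a.centerline[0] - zone.plane_point, zone.plane_normal)
        assert np.sign(d_signed) != np.sign(d_orifice) or abs(d_orifice) < 1e-6


class TestCrossSection:
    def test_elliptical_cylinder_axes(self):
        p = AnatomyParams(MorphologyLabel.WINDSOCK, 25, 20, 30, taper_ratio=1.0)
        a = lv.generate_case(p, 1)
        zone = lv.locate_landing_zone(a)
        assert zone.max_diameter_mm == pytest.approx(25, rel=0.02)
        assert zone.min_diameter_mm == pytest.approx(20, rel=0.02)

    def test_tilted_circular_cylinder_closed_form(self):
        r, phi = 10.0, np.deg2rad(25)
        cyl = trimesh.creation.cylinder(radius=r, height=60, sections=256)
        axis = np.array([0.0, 0.0, 1.0])
        a = _stub_anatomy(cyl, [[0, 0, -30], [0, 0, 30]])
        normal = np.array([np.sin(phi), 0.0, np.cos(phi)])
        zone = LandingZone(plane_point=np.zeros(3), plane_normal=normal,
                           D1=np.zeros(3), D2=np.zeros(3), max_diameter_mm=0,
                           min_diameter_mm=0, lupv_offset_mm=15,
                           center=np.zeros(3), perpendicularity=1.0)
        max_d, min_d, _, _ = lv.cross_section_diameters(a, zone)
        assert max_d == pytest.approx(2 * r / np.cos(phi), rel=0.02)
        assert min_d == pytest.approx(2 * r, rel=0.02)

    def test_calipers_match_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = rng.integers(10, 500)
            pts2 = rng.normal(size=(n, 2)) * rng.uniform(1, 20, size=2)
            contour = np.column_stack([pts2, np.zeros(n)])
            max_d, min_d, P1, P2 = _calipers(contour, [0, 0, 1])
            d = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=2)
            assert max_d == pytest.approx(d.max(), abs=1e-9)
            assert np.linalg.norm(P1 - P2) == pytest.approx(max_d, abs=1e-9)
            assert min_d <= max_d + 1e-12


class TestLength:
    def test_straight_tube_length(self, windsock, windsock_zone):
        arc = laa_length(windsock, windsock_zone)
        chord = laa_length_chord(windsock, windsock_zone)
        assert arc == pytest.approx(30.0, rel=0.02)
        assert chord == pytest.approx(arc, rel=1e-6)  # straight: arc = chord

    def test_bent_centerline_arc_vs_chord(self):
        # right-angle polyline with two 15 mm arms
        centerline = np.array([[0, 0, 0], [0, -15, 0], [15, -15, 0]], float)
        box = trimesh.creation.box(extents=[100, 100, 100])
        a = _stub_anatomy(box, centerline)
        zone = LandingZone(plane_point=np.zeros(3), plane_normal=[0, -1, 0],
                           D1=np.zeros(3), D2=np.zeros(3), max_diameter_mm=0,
                           min_diameter_mm=0, lupv_offset_mm=15,
                           center=np.zeros(3), perpendicularity=1.0)
        assert laa_length(a, zone) == pytest.approx(30.0, abs=1e-9)
        assert laa_length_chord(a, zone) == pytest.approx(15 * np.sqrt(2), abs=1e-9)

    def test_distal_shift_shortens_by_shift(self, windsock, windsock_zone):
        z2 = LandingZone(
            plane_point=windsock_zone.plane_point + 5.0 * windsock.anterior_axis,
            plane_normal=windsock_zone.plane_normal,
            D1=windsock_zone.D1, D2=windsock_zone.D2,
            max_diameter_mm=windsock_zone.max_diameter_mm,
            min_diameter_mm=windsock_zone.min_diameter_mm,
            lupv_offset_mm=windsock_zone.lupv_offset_mm,
            center=windsock_zone.center + 5.0 * windsock.anterior_axis,
            perpendicularity=windsock_zone.perpendicularity)
        delta = laa_length(windsock, windsock_zone) - laa_length(windsock, z2)
        assert delta == pytest.approx(5.0, abs=0.5)


@pytest.mark.parametrize("max_d, min_d, expected", [
    (25.0, 20.0, (0.2, 5.0)),
    (20.0, 16.0, (0.2, 4.0)),   # same shape, smaller absolute eccentricity
    (18.0, 18.0, (0.0, 0.0)),   # circle
])
def test_eccentricity_metrics(max_d, min_d, expected):
    assert lv.eccentricity_metrics(max_d, min_d) == pytest.approx(expected)


def test_eccentricity_rejects_bad_order():
    with pytest.raises(ParameterError):
        lv.eccentricity_metrics(20.0, 25.0)


class TestGroundTruthRecovery:
    def test_control_recovers_generator_truth(self):
        cohort = lv.generate_cohort(10, rng_seed=3)
        for case in cohort:
            zone = lv.locate_landing_zone(case)
            ctrl = lv.control_measurement(case, zone)
            t = case.truth
            assert ctrl.max_diameter_mm == pytest.approx(
                t.orifice_long_axis_mm, rel=0.02), case.morphology
            assert ctrl.min_diameter_mm == pytest.approx(
                t.orifice_short_axis_mm, rel=0.02), case.morphology
            assert ctrl.length_mm == pytest.approx(
                t.length_mm, rel=0.02), case.morphology

    def test_scale_equivariance(self, windsock, windsock_zone):
        k = 1.3
        scaled = LAAAnatomy(
            appendage_mesh=trimesh.Trimesh(
                vertices=windsock.appendage_mesh.vertices * k,
                faces=windsock.appendage_mesh.faces, process=False),
            body_mesh=trimesh.Trimesh(
                vertices=windsock.body_mesh.vertices * k,
                faces=windsock.body_mesh.faces, process=False),
            landmarks={n: p * k for n, p in windsock.landmarks.items()},
            centerline=windsock.centerline * k,
            anterior_axis=windsock.anterior_axis,
            morphology=windsock.morphology, truth=windsock.truth)
        z = lv.locate_landing_zone(scaled)
        ctrl = lv.control_measurement(scaled, z)
        base = lv.control_measurement(windsock, windsock_zone)
        assert ctrl.max_diameter_mm == pytest.approx(k * base.max_diameter_mm, rel=0.01)
        assert ctrl.length_mm == pytest.approx(k * base.length_mm, rel=0.02)
        assert ctrl.eccentricity == pytest.approx(base.eccentricity, abs=0.01)
        assert ctrl.absolute_eccentricity_mm == pytest.approx(
            k * base.absolute_eccentricity_mm, rel=0.05)
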
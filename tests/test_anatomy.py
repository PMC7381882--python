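"""Synthetic anatomy generator: determinism, ground truth, morphology
contracts, STL round trips."""

import json
import struct

import numpy as np
import pytest
import trimesh

import laaview as lv
from laaview.anatomy import _closest_surface_point
from laaview.errors import FormatError, ParameterError


def _params(morph=lv.MorphologyLabel.WINDSOCK, long=25.0, short=20.0,
            length=30.0, **kw):
    return lv.AnatomyParams(morph, long, short, length, **kw)


class TestGenerateCase:
    def test_deterministic_same_seed(self):
        a = lv.generate_case(_params(), 7)
        b = lv.generate_case(_params(), 7)
        assert a.mesh.vertices.tobytes() == b.mesh.vertices.tobytes()
        assert a.mesh.faces.tobytes() == b.mesh.faces.tobytes()

    def test_circular_orifice_zero_eccentricity(self):
        a = lv.generate_case(_params(long=25, short=25), 1)
        zone = lv.locate_landing_zone(a)
        ecc, _ = lv.eccentricity_metrics(zone.max_diameter_mm, zone.min_diameter_mm)
        assert abs(ecc) <= 0.02

    def test_absolute_eccentricity_by_construction(self):
        a = lv.generate_case(_params(long=25, short=20), 1)
        zone = lv.locate_landing_zone(a)
        abs_ecc = zone.max_diameter_mm - zone.min_diameter_mm
        assert abs_ecc == pytest.approx(5.0, rel=0.1)
        assert zone.max_diameter_mm == pytest.approx(25.0, rel=0.02)

    def test_chicken_wing_arc_exceeds_chord(self):
        p = _params(lv.MorphologyLabel.CHICKEN_WING, length=35.0,
                    bend_angle_deg=90.0)
        a = lv.generate_case(p, 1)
        seg = np.linalg.norm(np.diff(a.centerline, axis=0), axis=1)
        arc = seg.sum()
        chord = np.linalg.norm(a.centerline[-1] - a.centerline[0])
        assert arc == pytest.approx(35.0, rel=0.02)
        assert chord < 35.0 * 0.98

    @pytest.mark.parametrize("morph", list(lv.MorphologyLabel))
    def test_all_morphologies_watertight_with_surface_landmarks(self, morph):
        a = lv.generate_case(_params(morph, length=28.0), 3)
        assert a.appendage_mesh.is_watertight
        assert a.body_mesh.is_watertight
        full = a.mesh
        for name, p in a.landmarks.items():
            q = _closest_surface_point(full, p)
            assert np.linalg.norm(q - p) <= 0.1, name

    def test_centerline_interior(self):
        a = lv.generate_case(_params(), 5)
        # all but the tip endpoint must be inside the appendage: the
        # outward normal at the nearest surface point faces away
        tris = a.appendage_mesh.triangles
        normals = a.appendage_mesh.face_normals
        for p in a.centerline[:-1]:
            cand = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
            d = np.linalg.norm(cand - p, axis=1)
            k = int(np.argmin(d))
            assert d[k] > 0.3  # strictly interior, off the wall
            assert np.dot(p - cand[k], normals[k]) < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            lv.generate_case(_params(long=20, short=25), 1)
        with pytest.raises(ParameterError):
            lv.generate_case(_params(length=-3), 1)
        with pytest.raises(ParameterError):
            lv.generate_case(_params(lupv_offset_mm=25.0), 1)


class TestMorphologyContracts:
    def test_chicken_wing_single_sharp_bend(self):
        a = lv.generate_case(_params(lv.MorphologyLabel.CHICKEN_WING,
                                     length=35, bend_angle_deg=80), 2)
        t = np.diff(a.centerline, axis=0)
        t = t / np.linalg.norm(t, axis=1)[:, None]
        turn = np.degrees(np.arccos(np.clip((t[:-1] * t[1:]).sum(axis=1), -1, 1)))
        assert turn.sum() == pytest.approx(80, abs=5)
        # turning is concentrated: a contiguous bend, not distributed wiggle
        assert turn.max() > 5 * np.median(turn + 1e-9)

    def test_bilobed_has_multiple_tips(self):
        a = lv.generate_case(_params(lv.MorphologyLabel.BILOBED, length=32), 2)
        assert len(a.branch_tips) + 1 >= 2

    def test_cone_tapers_monotonically(self):
        a = lv.generate_case(_params(lv.MorphologyLabel.CONE, length=30,
                                     taper_ratio=0.15), 2)
        widths = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            origin = a.centerline[0] + frac * (a.centerline[-1] - a.centerline[0])
            sec = a.appendage_mesh.section(plane_origin=origin,
                                           plane_normal=[0, -1, 0])
            pts = np.vstack(sec.discrete)
            widths.append(np.ptp(pts[:, 2]))
        assert all(w1 > w2 * 0.999 for w1, w2 in zip(widths, widths[1:]))


class TestCohort:
    def test_cohort_size_and_reproducible_histogram(self):
        cohort = lv.generate_cohort(28, rng_seed=42, edge_length_mm=3.0)
        assert len(cohort) == 28
        hist = {m: sum(c.morphology is m for c in cohort)
                for m in lv.MorphologyLabel}
        again = lv.generate_cohort(28, rng_seed=42, edge_length_mm=3.0)
        hist2 = {m: sum(c.morphology is m for c in again)
                 for m in lv.MorphologyLabel}
        assert hist == hist2
        # windsock dominates the default mix (15/28 expected frequency)
        assert hist[lv.MorphologyLabel.WINDSOCK] >= 8

    def test_single_morphology_mix(self):
        cohort = lv.generate_cohort(1, {lv.MorphologyLabel.WINDSOCK: 1.0},
                                    rng_seed=0, edge_length_mm=3.0)
        assert cohort[0].morphology is lv.MorphologyLabel.WINDSOCK

    def test_default_ranges_span_eligibility_band(self):
        cohort = lv.generate_cohort(100, rng_seed=5, edge_length_mm=4.0)
        longs = [c.truth.orifice_long_axis_mm for c in cohort]
        assert min(longs) < 17.0
        assert max(longs) > 31.0

    def test_bad_mix_rejected(self):
        with pytest.raises(ParameterError):
            lv.generate_cohort(4, {lv.MorphologyLabel.WINDSOCK: 0.5}, rng_seed=0)


def _read_binary_stl(path):
    """Independent minimal binary-STL reader (struct-based oracle)."""
    raw = path.read_bytes()
    (n,) = struct.unpack_from("<I", raw, 80)
    tris = np.zeros((n, 3, 3), dtype=np.float32)
    off = 84
    for i in range(n):
        vals = struct.unpack_from("<12fH", raw, off)
        tris[i] = np.asarray(vals[3:12], dtype=np.float32).reshape(3, 3)
        off += 50
    return tris


class TestSTLRoundTrip:
    def test_roundtrip_preserves_vertices(self, tmp_path, windsock):
        path = tmp_path / "case.stl"
        lv.export_stl(windsock, path)
        back = lv.import_stl(path)
        from scipy.spatial import cKDTree
        tree = cKDTree(back.mesh.vertices)
        d, _ = tree.query(windsock.mesh.vertices)
        assert d.max() <= 1e-4  # STL float32 precision at ~50 mm scale
        for k in ("lupv_limbus", "inferior_deflection", "tip"):
            assert np.allclose(back.landmarks[k], windsock.landmarks[k], atol=1e-4)

    def test_unit_tetrahedron_roundtrip(self, tmp_path):
        tet = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                              faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
                              process=False)
        path = tmp_path / "tet.stl"
        tet.export(path, file_type="stl")
        back = trimesh.load(path, force="mesh", process=True)
        assert np.allclose(np.unique(back.vertices, axis=0),
                           np.unique(tet.vertices, axis=0), atol=1e-6)

    def test_import_without_sidecar_fails(self, tmp_path, windsock):
        path = tmp_path / "bare.stl"
        windsock.mesh.export(path, file_type="stl")
        with pytest.raises(FormatError):
            lv.import_stl(path)

    def test_exports_parse_with_independent_reader(self, tmp_path):
        cohort = lv.generate_cohort(4, rng_seed=3, edge_length_mm=3.0)
        for case in cohort:
            path = tmp_path / f"{case.case_id}.stl"
            lv.export_stl(case, path)
            tris = _read_binary_stl(path)
            assert len(tris) == len(case.mesh.faces)
            assert np.allclose(np.sort(tris.reshape(-1, 3), axis=0),
                               np.sort(case.mesh.triangles.reshape(-1, 3).astype(
                                   np.float32), axis=0), atol=1e-3)
            meta = json.loads(path.with_suffix(".landmarks.json").read_text())
            assert set(meta) >= {"lupv_limbus", "inferior_deflection", "tip"}
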
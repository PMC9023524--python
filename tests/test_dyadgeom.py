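"""Dyad morphometry: circularity identities, coupling-ratio and
junction-distance recovery, similarity invariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadkit import dyadgeom
from dyadkit.dyadgeom import (EMScene, analyze_scene, circularity,
                              coupling_ratio, junction_z_distance)
from dyadkit.simulate import EMSimConfig, make_em_scene


def _regular_polygon(n, r=100.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestCircularity:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert circularity(sq) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_regular_ngon_monotone_to_one(self):
        vals = [circularity(_regular_polygon(n)) for n in (8, 16, 32, 64, 256, 4096)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-5)

    def test_ellipse_matches_quadrature_oracle(self):
        a, b = 200.0, 100.0
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        poly = np.column_stack([a * np.cos(t), b * np.sin(t)])
        # dense quadrature of 4*pi*A/P^2
        tt = np.linspace(0, 2 * np.pi, 400001)
        per = np.trapezoid(np.hypot(-a * np.sin(tt), b * np.cos(tt)), tt)
        oracle = 4 * math.pi * (math.pi * a * b) / per ** 2
        assert circularity(poly) == pytest.approx(oracle, rel=1e-4)

    def test_self_intersecting_raises(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="simple"):
            circularity(bowtie)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            circularity(np.array([[0, 0], [1, 0], [2, 0]], dtype=float))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=8, max_size=30))
    def test_isoperimetric_bound_on_convex_hulls(self, pts):
        from shapely.geometry import MultiPoint
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type != "Polygon" or hull.area < 1e-3:
            return
        poly = np.asarray(hull.exterior.coords)[:-1]
        assert circularity(poly) <= 1.0 + 1e-9


class TestCouplingRatio:
    def test_full_perimeter_jsr(self):
        scene = make_em_scene(EMSimConfig(jsr_arc_fraction=1.0), 0)
        assert coupling_ratio(scene.ttubule, scene.jsr) == pytest.approx(1.0)

    def test_no_jsr_returns_zero(self):
        scene = make_em_scene(EMSimConfig(jsr_arc_fraction=0.0), 0)
        assert coupling_ratio(scene.ttubule, scene.jsr) == 0.0

    @pytest.mark.parametrize("frac", [0.3, 0.6])
    def test_generated_arc_fraction_recovered(self, frac):
        for seed in range(3):
            scene = make_em_scene(EMSimConfig(jsr_arc_fraction=frac), seed)
            assert coupling_ratio(scene.ttubule, scene.jsr) == \
                pytest.approx(frac, abs=0.02)

    def test_monotone_in_dmax(self):
        scene = make_em_scene(EMSimConfig(jsr_arc_fraction=0.5), 2)
        vals = [coupling_ratio(scene.ttubule, scene.jsr, d_max_nm=d)
                for d in (13.0, 15.0, 20.0, 40.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestJunctionZDistance:
    def test_zline_through_junction_gives_zero(self):
        scene = make_em_scene(EMSimConfig(zline_distance_nm=0.0), 0)
        assert junction_z_distance(scene.ttubule, scene.jsr, scene.zline) == \
            pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("zd", [20.0, 40.0, 60.0])
    def test_generated_distance_recovered(self, zd):
        scene = make_em_scene(EMSimConfig(zline_distance_nm=zd), 1)
        assert junction_z_distance(scene.ttubule, scene.jsr, scene.zline) == \
            pytest.approx(zd, abs=2.0)

    def test_no_coupling_raises(self):
        scene = make_em_scene(EMSimConfig(jsr_arc_fraction=0.0), 0)
        with pytest.raises(ValueError, match="no junction"):
            junction_z_distance(scene.ttubule, scene.jsr, scene.zline)


class TestAnalyzeScene:
    def test_circle_full_jsr_on_junction(self):
        cfg = EMSimConfig(ellipse_semi_axes_nm=(200.0, 200.0),
                          jsr_arc_fraction=1.0, zline_distance_nm=0.0,
                          n_vertices=1024)
        m = analyze_scene(make_em_scene(cfg, 0))
        assert m.circularity == pytest.approx(1.0, abs=1e-4)
        assert m.coupling_ratio == pytest.approx(1.0)
        assert m.junction_z_distance_nm == pytest.approx(0.0, abs=1.0)

    def test_jsr_free_scene_reports_missing_distance(self):
        m = analyze_scene(make_em_scene(EMSimConfig(jsr_arc_fraction=0.0), 0))
        assert m.coupling_ratio == 0.0
        assert m.junction_z_distance_nm is None
        assert 0.9 < m.circularity <= 1.0

    def test_generator_truth_recovered(self):
        cfg = EMSimConfig(jsr_arc_fraction=0.6, zline_distance_nm=40.0)
        scene = make_em_scene(cfg, 5)
        m = analyze_scene(scene)
        assert m.circularity == pytest.approx(scene.truth["circularity"], abs=1e-9)
        assert m.coupling_ratio == pytest.approx(0.6, abs=0.02)
        assert m.junction_z_distance_nm == pytest.approx(40.0, abs=2.0)


class TestSimilarityInvariance:
    def test_rigid_motion_leaves_metrics_unchanged(self, rng):
        scene = make_em_scene(EMSimConfig(zline_distance_nm=30.0), 3)
        m0 = analyze_scene(scene)
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        shift = rng.uniform(-1000, 1000, 2)
        moved = EMScene(
            ttubule=scene.ttubule @ rot.T + shift,
            jsr=[p @ rot.T + shift for p in scene.jsr],
            zline=(scene.zline[0] @ rot.T + shift, rot @ scene.zline[1]),
        )
        m1 = analyze_scene(moved)
        assert m1.circularity == pytest.approx(m0.circularity, rel=1e-9)
        assert m1.coupling_ratio == pytest.approx(m0.coupling_ratio, abs=0.005)
        assert m1.junction_z_distance_nm == pytest.approx(
            m0.junction_z_distance_nm, abs=0.5)

    def test_uniform_scaling_scales_distance_only(self):
        scene = make_em_scene(EMSimConfig(zline_distance_nm=30.0), 3)
        s = 2.5
        scaled = EMScene(ttubule=scene.ttubule * s,
                         jsr=[p * s for p in scene.jsr],
                         zline=(scene.zline[0] * s, scene.zline[1]))
        m0 = analyze_scene(scene)
        m1 = analyze_scene(scaled, d_max_nm=dyadgeom.DEFAULT_D_MAX_NM * s)
        assert m1.circularity == pytest.approx(m0.circularity, rel=1e-9)
        assert m1.coupling_ratio == pytest.approx(m0.coupling_ratio, abs=0.005)
        assert m1.junction_z_distance_nm == pytest.approx(
            s * m0.junction_z_distance_nm, rel=0.02)


class TestSceneIO:
    def test_json_round_trip(self, tmp_path):
        scene = make_em_scene(EMSimConfig(), 4)
        p = tmp_path / "scene.json"
        scene.to_json(p)
        back = EMScene.from_json(p)
        assert np.allclose(back.ttubule, scene.ttubule)
        assert np.allclose(back.jsr[0], scene.jsr[0])
        assert np.allclose(back.zline[0], scene.zline[0])
        assert back.truth == scene.truth

    def test_ko_like_scenes_score_worse(self):
        ref = EMSimConfig()
        ko = EMSimConfig(ellipse_semi_axes_nm=(300.0, 100.0),
                         jsr_arc_fraction=0.3, zline_distance_nm=60.0)
        for seed in range(5):
            mr = analyze_scene(make_em_scene(ref, seed))
            mk = analyze_scene(make_em_scene(ko, seed + 100))
            assert mk.circularity < mr.circularity
            assert mk.coupling_ratio < mr.coupling_ratio
            assert mk.junction_z_distance_nm > mr.junction_z_distance_nm
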
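import math

import numpy as np
import pytest

from afmquant.io_formats import HeightMap
from afmquant.pipeline import analyze_frame
from afmquant.benchmark import detection_scores, match_traces
from afmquant.synthetic import TipModel, render_scene, simulate_frame
from afmquant.trace import (
    fibril_diameter,
    measure_particle,
    resolve_host,
    segment_objects,
    trace_backbone,
)
from conftest import make_trace, ridge_heightmap, scene


def _trace_single(hm, baseline=0.0):
    _, comps = segment_objects(hm)
    fibs = [c for c in comps if c.cls == "fibril"]
    assert len(fibs) == 1
    return trace_backbone(fibs[0], hm, baseline=baseline)


class TestSegmentation:
    def test_blank_map_has_no_objects(self):
        _, comps = segment_objects(HeightMap(np.zeros((64, 64)), 2.0))
        assert comps == []

    def test_fibril_and_oligomer_separated(self):
        spec = scene(
            seed=20,
            primary_fibrils={"count": 1, "length_mean_nm": 600.0,
                             "length_sd_nm": 0.0},
            oligomers={"count": 1, "diameter_mean_nm": 8.0,
                       "p_edge": 0, "p_backbone": 0, "p_substrate": 1.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        assert len(res.traces) == 1
        assert len(res.particles) == 1

    def test_fibril_only_scene_yields_no_particles(self):
        spec = scene(
            seed=21,
            field_nm=[1600, 1600],
            primary_fibrils={"count": 20, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.5, "length_mean_nm": 300.0,
                             "length_sd_nm": 40.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        assert len(res.particles) == 0
        assert len(res.traces) == 20


class TestBackboneLength:
    def test_straight_ridge_length(self):
        pts = np.array([[100.0, 300.0], [500.0, 300.0]])
        hm = ridge_heightmap(pts, 8.3, (300, 300))
        t = _trace_single(hm)
        assert t.length_nm == pytest.approx(400.0, abs=2.0)
        assert len(t.backbone_nm) >= 10
        assert len(t.apex_heights_nm) == len(t.backbone_nm)

    def test_quarter_circle_arc_length(self):
        # closed form: pi * R / 2 for R = 200 nm
        theta = np.linspace(0.0, math.pi / 2, 400)
        pts = np.stack([60 + 200 * np.cos(theta), 60 + 200 * np.sin(theta)], axis=1)
        hm = ridge_heightmap(pts, 8.3, (180, 180))
        t = _trace_single(hm)
        assert t.length_nm == pytest.approx(math.pi * 200 / 2, abs=3.0)

    def test_population_length_recovered_within_3pc(self):
        spec = scene(
            seed=22,
            field_nm=[2000, 2000],
            primary_fibrils={"count": 10, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.85, "length_mean_nm": 842.0,
                             "length_sd_nm": 133.5},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        tmap = match_traces(res, frame.truth)
        truth = {o.id: o for o in frame.truth.objects}
        meas = [t.length_nm for t in res.traces if t.id in tmap]
        true = [truth[tmap[t.id]].true_length_nm for t in res.traces if t.id in tmap]
        assert len(meas) == 10
        assert np.mean(meas) == pytest.approx(np.mean(true), rel=0.03)


class TestFibrilDiameter:
    def test_noise_free_diameter(self):
        pts = np.array([[100.0, 300.0], [500.0, 300.0]])
        hm = ridge_heightmap(pts, 8.3, (300, 300))
        t = _trace_single(hm)
        assert t.diameter_nm == pytest.approx(8.3, abs=0.1)

    def test_diameter_with_tip_and_noise(self):
        spec = scene(
            seed=23,
            artifacts={"line_offset_sigma_nm": 0.8, "tilt_nm_per_um": [4, 6],
                       "pixel_noise_sigma_nm": 0.3},
            primary_fibrils={"count": 1, "diameter_mean_nm": 8.3,
                             "length_mean_nm": 500.0, "length_sd_nm": 0.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        assert len(res.traces) == 1
        assert res.traces[0].diameter_nm == pytest.approx(8.3, abs=0.3)

    def test_corrugated_diameter_trimmed_mean(self):
        arc = np.arange(0, 601.0)
        corr = 3.0 * np.sin(2 * math.pi * arc / 80.0)
        profile = np.clip(6.5 + corr, 3.9, None)
        pts = np.array([[100.0, 600.0], [700.0, 600.0]])
        hm = ridge_heightmap(pts, 6.5, (600, 600), diam_profile=profile)
        t = _trace_single(hm)
        assert t.diameter_nm == pytest.approx(6.5, abs=0.5)

    def test_diameter_invariant_to_tip_radius(self):
        # heights, unlike widths, are tip-robust
        diams = []
        for radius in (2.0, 5.0, 10.0):
            spec = scene(
                seed=24,
                tip={"radius_nm": radius},
                primary_fibrils={"count": 1, "diameter_mean_nm": 8.3,
                                 "length_mean_nm": 500.0, "length_sd_nm": 0.0},
            )
            frame = simulate_frame(spec)
            res = analyze_frame(frame.topograph)
            diams.append(res.traces[0].diameter_nm)
        for d in diams:
            assert d == pytest.approx(8.3, abs=0.3)
        assert max(diams) - min(diams) <= 0.3


class TestParticleMeasurement:
    def test_lone_sphere_diameter(self):
        spec = scene(
            seed=25,
            substrate_sigma_nm=0.0,
            artifacts={},
            primary_fibrils={"count": 0},
            oligomers={"count": 1, "diameter_mean_nm": 8.0, "diameter_sd_nm": 0.0,
                       "p_edge": 0, "p_backbone": 0, "p_substrate": 1.0},
        )
        frame = simulate_frame(spec)  # tip only: no noise, no artifacts
        res = analyze_frame(frame.topograph)
        assert len(res.particles) == 1
        p = res.particles[0]
        assert p.diameter_nm == pytest.approx(8.0, abs=0.1)
        assert p.support_height_nm == 0.0
        assert p.n_sections == 5

    def test_sphere_on_fibril_support_subtraction(self):
        # composition oracle: 6 nm sphere atop 8 nm fibril -> apex 14, support 8
        spec = scene(
            seed=26,
            substrate_sigma_nm=0.0,
            artifacts={},
            primary_fibrils={"count": 1, "diameter_mean_nm": 8.0,
                             "diameter_sd_nm": 0.0, "length_mean_nm": 500.0,
                             "length_sd_nm": 0.0},
            oligomers={"count": 1, "diameter_mean_nm": 6.0, "diameter_sd_nm": 0.0,
                       "p_edge": 0, "p_backbone": 1.0, "p_substrate": 0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        assert len(res.particles) == 1
        p = res.particles[0]
        assert p.mean_apex_height_nm == pytest.approx(14.0, abs=0.2)
        assert p.support_height_nm == pytest.approx(8.0, abs=0.2)
        assert p.diameter_nm == pytest.approx(6.0, abs=0.2)
        assert p.host_id == res.traces[0].id

    def test_stacked_secondary_support_subtraction(self):
        spec = scene(
            seed=27,
            primary_fibrils={"count": 2, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.0, "length_mean_nm": 700.0,
                             "length_sd_nm": 0.0},
            secondary_fibrils={"count": 1, "diameter_mean_nm": 6.5,
                               "diameter_sd_nm": 0.0, "length_mean_nm": 250.0,
                               "length_sd_nm": 0.0, "stacked_on_primary": True},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        riders = [t for t in res.traces if t.host_id is not None]
        assert len(riders) == 1
        assert riders[0].diameter_nm == pytest.approx(6.5, abs=0.3)
        assert riders[0].length_nm == pytest.approx(250.0, abs=15.0)

    def test_host_tiebreak_is_deterministic_and_flagged(self):
        t_a = make_trace(trace_id="a", y_nm=100.0)
        t_b = make_trace(trace_id="b", y_nm=120.0)
        host, _, flagged = resolve_host((250.0, 110.0), [t_a, t_b], eps_nm=15.0)
        assert host.id == "a"  # equidistant: lower id wins
        assert flagged


class TestDetectionQuality:
    def test_recall_and_fdr_on_default_noise_scene(self):
        spec = scene(
            seed=28,
            field_nm=[2000, 2000],
            primary_fibrils={"count": 8, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.85, "length_mean_nm": 700.0,
                             "length_sd_nm": 100.0},
            oligomers={"count": 20, "diameter_mean_nm": 7.9, "diameter_sd_nm": 0.5,
                       "p_edge": 0.3, "p_backbone": 0.3, "p_substrate": 0.4},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        scores = detection_scores(res, frame.truth, spec.field_nm)
        assert scores["recall"] >= 0.95
        assert scores["fdr"] <= 0.05

    def test_analysis_is_deterministic(self):
        frame = simulate_frame(scene(seed=29))
        r1 = analyze_frame(frame.topograph)
        r2 = analyze_frame(frame.topograph)
        assert [t.length_nm for t in r1.traces] == [t.length_nm for t in r2.traces]
        assert [p.diameter_nm for p in r1.particles] == [
            p.diameter_nm for p in r2.particles
        ]
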
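import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmquant.classify import (
    ActivityRecord,
    RoughnessRecord,
    classify_activity,
    classify_generation,
    classify_site,
    rq_roughness,
    site_distribution,
)
from afmquant.pipeline import analyze_frame
from afmquant.benchmark import match_particles, match_traces
from afmquant.synthetic import simulate_frame
from afmquant.trace import ParticleMeasure
from conftest import make_trace, scene


def _particle(x, y, diameter=8.0, pid="p", host_id=None, arc=None):
    return ParticleMeasure(
        id=pid, centroid_nm=(x, y), n_sections=5,
        mean_apex_height_nm=diameter, support_height_nm=0.0,
        diameter_nm=diameter, host_id=host_id, arc_pos_nm=arc,
    )


class TestSiteClassifier:
    def test_far_particle_is_substrate(self):
        t = make_trace(length_nm=400.0)
        assert classify_site(_particle(250.0, 300.0), [t]) == "substrate"

    def test_near_endpoint_is_edge(self):
        # geometric oracle on a straight trace starting at x0 = 50
        t = make_trace(length_nm=400.0)
        assert classify_site(_particle(55.0, 100.0), [t]) == "edge"

    def test_mid_backbone_is_backbone(self):
        t = make_trace(length_nm=400.0)
        assert classify_site(_particle(250.0, 100.0), [t]) == "backbone"

    def test_edge_window_is_configurable(self):
        t = make_trace(length_nm=400.0)
        p = _particle(85.0, 100.0)  # 35 nm from the endpoint
        assert classify_site(p, [t], eps_edge_nm=20.0) == "backbone"
        p2 = _particle(85.0, 100.0)
        assert classify_site(p2, [t], eps_edge_nm=40.0) == "edge"

    def test_ground_truth_recovery_accuracy(self):
        spec = scene(
            seed=31,
            field_nm=[2000, 2000],
            primary_fibrils={"count": 16, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.85, "length_mean_nm": 842.0,
                             "length_sd_nm": 133.5},
            oligomers={"count": 40, "diameter_mean_nm": 7.9, "diameter_sd_nm": 0.2,
                       "p_edge": 0.8, "p_backbone": 0.2, "p_substrate": 0.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        pmap = match_particles(res, frame.truth)
        truth = {o.id: o for o in frame.truth.objects}
        pairs = [
            (p.site, truth[pmap[p.id]].placement)
            for p in res.particles
            if p.id in pmap
        ]
        assert len(pairs) >= 30
        acc = np.mean([meas == true for meas, true in pairs])
        assert acc >= 0.95


class TestRoughness:
    def test_constant_profile_rq_zero(self):
        t = make_trace(length_nm=400.0, diameter_nm=8.0)
        rec = rq_roughness(t)
        assert rec.rq_nm == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_closed_form(self):
        # Rq = A / sqrt(2); windows hold integer periods (100 nm / 50 nm);
        # cosine phase keeps the corrugation orthogonal to the linear detrend
        arc = np.arange(0, 401.0)
        apex = 8.0 + 1.0 * np.cos(2 * math.pi * arc / 50.0)
        t = make_trace(length_nm=400.0, apex=apex)
        rec = rq_roughness(t, window_nm=100.0)
        assert rec.rq_nm == pytest.approx(1.0 / math.sqrt(2), abs=0.02)

    def test_invariance_to_offset_and_ramp(self):
        arc = np.arange(0, 401.0)
        base = 1.0 * np.sin(2 * math.pi * arc / 50.0)
        r0 = rq_roughness(make_trace(length_nm=400.0, apex=8.0 + base)).rq_nm
        r_off = rq_roughness(make_trace(length_nm=400.0, apex=13.0 + base)).rq_nm
        r_ramp = rq_roughness(
            make_trace(length_nm=400.0, apex=8.0 + base + 0.01 * arc)
        ).rq_nm
        assert r_off == pytest.approx(r0, abs=1e-9)
        assert r_ramp == pytest.approx(r0, abs=0.01)

    @settings(max_examples=20, deadline=None)
    @given(amp=st.floats(0.2, 4.0))
    def test_scales_linearly_with_amplitude(self, amp):
        arc = np.arange(0, 401.0)
        s = np.sin(2 * math.pi * arc / 50.0)
        r1 = rq_roughness(make_trace(length_nm=400.0, apex=8.0 + s)).rq_nm
        r2 = rq_roughness(make_trace(length_nm=400.0, apex=8.0 + amp * s)).rq_nm
        assert r2 == pytest.approx(amp * r1, rel=1e-6)

    def test_short_trace_single_window_flagged(self):
        t = make_trace(length_nm=40.0)
        rec = rq_roughness(t)
        assert rec.flagged_short

    def test_too_few_samples_rejected(self):
        t = make_trace(length_nm=10.0)
        with pytest.raises(ValueError, match="20"):
            rq_roughness(t)


class TestGenerationClassifier:
    def test_reference_ranges(self):
        assert classify_generation(RoughnessRecord("f", 1.0, "linear", [1.0])) == "primary"
        assert classify_generation(RoughnessRecord("f", 5.0, "linear", [5.0])) == "secondary"

    def test_boundary_inclusive_upper(self):
        rec = RoughnessRecord("f", 2.35, "linear", [2.35])
        assert classify_generation(rec) == "secondary"

    @settings(max_examples=25, deadline=None)
    @given(rq=st.floats(0.0, 10.0), thr=st.floats(0.5, 5.0))
    def test_monotone_in_rq(self, rq, thr):
        lo = classify_generation(RoughnessRecord("f", rq, "linear", [rq]), thr)
        hi = classify_generation(
            RoughnessRecord("f", rq + 1.0, "linear", [rq + 1.0]), thr
        )
        order = {"primary": 0, "secondary": 1}
        assert order[lo] <= order[hi]


class TestActivityClassifier:
    def test_zero_attachments_dormant(self):
        t = make_trace(trace_id="f0")
        (rec,) = classify_activity([t], {})
        assert rec.activity == "dormant"
        assert rec.lambda_per_um == 0.0

    def test_rule_arithmetic_identifies_superspreader(self):
        # frame with lambda = {1, 1, 1, 4} per um over 1-um fibrils
        traces = [make_trace(length_nm=1000.0, trace_id=f"f{i}") for i in range(4)]
        counts = {"f0": 1, "f1": 1, "f2": 1, "f3": 4}
        recs = {r.fibril_id: r for r in classify_activity(traces, counts)}
        assert recs["f3"].activity == "superspreader"
        assert all(recs[f].activity == "active" for f in ("f0", "f1", "f2"))

    def test_rule_inert_below_three_nondormant(self):
        traces = [make_trace(length_nm=1000.0, trace_id=f"f{i}") for i in range(3)]
        recs = classify_activity(traces, {"f0": 9, "f1": 1})
        by_id = {r.fibril_id: r for r in recs}
        assert by_id["f0"].activity == "active"
        assert by_id["f2"].activity == "dormant"

    def test_permutation_invariant(self):
        traces = [make_trace(length_nm=1000.0, trace_id=f"f{i}") for i in range(5)]
        counts = {"f0": 1, "f1": 2, "f2": 0, "f3": 6, "f4": 1}
        a = {r.fibril_id: r.activity for r in classify_activity(traces, counts)}
        b = {
            r.fibril_id: r.activity
            for r in classify_activity(traces[::-1], counts)
        }
        assert a == b

    def test_designated_superspreader_recovered_from_scene(self):
        spec = scene(
            seed=32,
            field_nm=[2000, 2000],
            primary_fibrils={"count": 7, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.5, "length_mean_nm": 842.0,
                             "length_sd_nm": 80.0},
            oligomers={"count": 30, "diameter_mean_nm": 7.9, "diameter_sd_nm": 0.2,
                       "p_edge": 0.0, "p_backbone": 1.0, "p_substrate": 0.0,
                       "superspreader_host_factor": 5.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        tmap = match_traces(res, frame.truth)
        inv = {gt: tid for tid, gt in tmap.items()}
        assert "p0" in inv
        activity = {a.fibril_id: a.activity for a in res.activity}
        assert activity[inv["p0"]] == "superspreader"


class TestSiteDistribution:
    def test_on_fibril_fractions(self):
        parts = [_particle(0, 0, pid=f"e{i}") for i in range(8)]
        for p in parts:
            p.site = "edge"
        parts2 = [_particle(0, 0, pid=f"b{i}") for i in range(2)]
        for p in parts2:
            p.site = "backbone"
        dist = site_distribution(parts + parts2)
        assert dist.fractions_on_fibril == {"edge": 0.8, "backbone": 0.2}
        assert dist.counts == {"edge": 8, "backbone": 2, "substrate": 0}
        assert sum(dist.fractions_all.values()) == pytest.approx(1.0)
        assert dist.normalization_area_nm2 == 500.0

    def test_all_substrate_reports_absent_on_fibril_fractions(self):
        parts = [_particle(0, 0, pid=f"s{i}") for i in range(3)]
        for p in parts:
            p.site = "substrate"
        dist = site_distribution(parts)
        assert dist.fractions_on_fibril is None

    def test_edge_exceeds_backbone_in_embryonic_scene(self):
        spec = scene(
            seed=33,
            field_nm=[2000, 2000],
            time_min=0.5,
            primary_fibrils={"count": 14, "diameter_mean_nm": 8.3,
                             "diameter_sd_nm": 0.85, "length_mean_nm": 842.0,
                             "length_sd_nm": 133.5},
            oligomers={"count": 25, "diameter_mean_nm": 7.9, "diameter_sd_nm": 0.2,
                       "p_edge": 0.8, "p_backbone": 0.2, "p_substrate": 0.0},
        )
        frame = simulate_frame(spec)
        res = analyze_frame(frame.topograph)
        frac = res.site_dist.fractions_on_fibril
        assert frac is not None
        assert frac["edge"] > frac["backbone"]
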
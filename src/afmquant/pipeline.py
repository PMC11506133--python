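"""Frame-level orchestration: flatten -> segment -> trace -> measure -> classify."""

from __future__ import annotations

import dataclasses

import numpy as np

from . import classify as _classify
from . import preprocess, trace as _trace
from .io_formats import HeightMap


@dataclasses.dataclass
class AnalyzeParams:
    flatten_order: int = 1
    flatten_iterations: int = 2
    mask_threshold_nm: float = 1.0
    fg_threshold_nm: float = _trace.FG_THRESHOLD_NM
    min_skeleton_nm: float = _trace.MIN_SKELETON_NM
    min_elongation: float = _trace.MIN_ELONGATION
    edge_window_nm: float = _classify.EDGE_WINDOW_NM
    rq_window_nm: float = _classify.RQ_WINDOW_NM
    rq_threshold_nm: float = _classify.RQ_THRESHOLD_NM
    superspreader_factor: float = _classify.SUPERSPREADER_FACTOR
    n_sections: int = _trace.N_SECTIONS


@dataclasses.dataclass
class FrameAnalysis:
    frame_id: str
    time_min: float | None
    flattened: HeightMap
    baseline_nm: float
    traces: list[_trace.FibrilTrace]  # full traces + extracted stacked riders
    particles: list[_trace.ParticleMeasure]
    rq_records: dict[str, _classify.RoughnessRecord]
    generations: dict[str, str]  # trace id -> primary | secondary
    activity: list[_classify.ActivityRecord]
    site_dist: _classify.SiteDistribution
    n_border_particles: int

    def records(self) -> list[dict]:
        """Measurement rows in the fixed CSV schema."""
        activity_by_id = {a.fibril_id: a.activity for a in self.activity}
        rows = []
        for t in self.traces:
            gen = self.generations.get(t.id, "primary")
            rq = self.rq_records.get(t.id)
            rows.append(
                {
                    "frame_id": self.frame_id,
                    "time_min": self.time_min,
                    "object_id": t.id,
                    "class": f"{gen}_fibril",
                    "diameter_nm": t.diameter_nm,
                    "length_nm": t.length_nm,
                    "rq_nm": rq.rq_nm if rq else np.nan,
                    "site": None,
                    "activity": activity_by_id.get(t.id),
                    "host_id": t.host_id,
                }
            )
        for p in self.particles:
            rows.append(
                {
                    "frame_id": self.frame_id,
                    "time_min": self.time_min,
                    "object_id": p.id,
                    "class": "oligomer",
                    "diameter_nm": p.diameter_nm,
                    "length_nm": None,
                    "rq_nm": None,
                    "site": p.site,
                    "activity": None,
                    "host_id": p.host_id,
                }
            )
        return rows


def analyze_frame(hm: HeightMap, params: AnalyzeParams | None = None) -> FrameAnalysis:
    """Run the full measurement pipeline on one raw height map."""
    params = params or AnalyzeParams()
    flat, _ = preprocess.flatten(
        hm,
        order=params.flatten_order,
        iterations=params.flatten_iterations,
        mask_threshold_nm=params.mask_threshold_nm,
    )
    mask = preprocess.object_mask(flat, params.mask_threshold_nm)
    baseline = preprocess.substrate_baseline(flat, mask)
    _, comps = _trace.segment_objects(
        flat,
        threshold_nm=params.fg_threshold_nm,
        min_skeleton_nm=params.min_skeleton_nm,
        min_elongation=params.min_elongation,
    )

    traces: list[_trace.FibrilTrace] = []
    riders: list[_trace.FibrilTrace] = []
    particles: list[_trace.ParticleMeasure] = []
    rider_hosts: dict[str, str] = {}
    spans_by_id: dict[str, list[tuple[float, float]]] = {}

    fib_comps = [c for c in comps if c.cls == "fibril"]
    part_comps = [c for c in comps if c.cls == "particle"]
    for k, comp in enumerate(fib_comps):
        t = _trace.trace_backbone(comp, flat, baseline=baseline, trace_id=f"f{k}")
        runs = _trace.detect_elevated_runs(t)
        spans = [(r.arc0_nm, r.arc1_nm) for r in runs]
        if spans:
            t.diameter_nm = _trace.fibril_diameter(t, exclude_spans=spans)
            spans_by_id[t.id] = spans
        n_riders = 0
        for r in runs:
            if r.kind == "stacked_fibril":
                rid = f"{t.id}r{n_riders}"
                riders.append(_trace.extract_stacked_fibril(t, r, runs, rid))
                rider_hosts[rid] = t.id
                n_riders += 1
            else:
                particles.append(
                    _trace.measure_on_fibril_particle(
                        t, r, runs, flat, baseline=baseline,
                        n_sections=params.n_sections,
                        particle_id=f"{t.id}o{len(particles)}",
                    )
                )
        traces.append(t)

    n_border_particles = 0
    for k, comp in enumerate(part_comps):
        p = _trace.measure_particle(
            comp, flat, baseline=baseline, n_sections=params.n_sections,
            particle_id=f"pt{k}",
        )
        if p.touches_border:
            n_border_particles += 1
            continue
        particles.append(p)

    # roughness + generation: riders are secondary by construction
    rq_records: dict[str, _classify.RoughnessRecord] = {}
    generations: dict[str, str] = {}
    for t in traces + riders:
        try:
            rec = _classify.rq_roughness(
                t,
                window_nm=params.rq_window_nm,
                exclude_spans=spans_by_id.get(t.id),
            )
            rq_records[t.id] = rec
        except ValueError:
            rec = None
        if t.host_id is not None:
            generations[t.id] = "secondary"
            if rec is not None:
                rec.generation = "secondary"
        elif rec is not None:
            generations[t.id] = _classify.classify_generation(
                rec, threshold_nm=params.rq_threshold_nm
            )
        else:
            generations[t.id] = "primary"

    # site classification against full (non-rider) traces
    for p in particles:
        p.site = _classify.classify_site(
            p, traces, eps_edge_nm=params.edge_window_nm
        )

    # catalytic activity of primary fibrils: riders + on-fibril oligomers
    primary_traces = [t for t in traces if generations.get(t.id) == "primary"]
    attached: dict[str, int] = {}
    for rid, hid in rider_hosts.items():
        attached[hid] = attached.get(hid, 0) + 1
    for p in particles:
        if p.host_id is not None:
            attached[p.host_id] = attached.get(p.host_id, 0) + 1
    activity = _classify.classify_activity(
        primary_traces, attached, factor=params.superspreader_factor
    )

    site_dist = _classify.site_distribution(
        particles, frame_id=hm.frame_id, time_min=hm.time_min
    )
    return FrameAnalysis(
        frame_id=hm.frame_id,
        time_min=hm.time_min,
        flattened=flat,
        baseline_nm=baseline,
        traces=traces + riders,
        particles=particles,
        rq_records=rq_records,
        generations=generations,
        activity=activity,
        site_dist=site_dist,
        n_border_particles=n_border_particles,
    )
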
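"""Matching of measured objects to simulator ground truth.

Used by the validation suite and the acceptance report to score recovery:
traces are matched to true backbones by mean point-to-polyline distance,
particles to true oligomer centroids by nearest neighbour, both greedily
one-to-one.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .pipeline import FrameAnalysis
from .synthetic import GroundTruth

TRACE_MATCH_TOL_NM = 20.0
PARTICLE_MATCH_TOL_NM = 15.0


def match_traces(
    analysis: FrameAnalysis,
    truth: GroundTruth,
    tol_nm: float = TRACE_MATCH_TOL_NM,
    classes: tuple[str, ...] = ("primary_fibril", "secondary_fibril"),
) -> dict[str, str]:
    """Greedy one-to-one map: measured trace id -> ground-truth fibril id."""
    gt_fibs = [o for o in truth.objects if o.cls in classes]
    trees = {o.id: cKDTree(np.asarray(o.backbone_nm)) for o in gt_fibs}
    pairs = []
    for t in analysis.traces:
        pts = t.backbone_nm[:: max(len(t.backbone_nm) // 40, 1)]
        for o in gt_fibs:
            d, _ = trees[o.id].query(pts)
            score = float(np.mean(d))
            if score <= tol_nm:
                pairs.append((score, t.id, o.id))
    pairs.sort()
    out: dict[str, str] = {}
    used = set()
    for score, tid, oid in pairs:
        if tid in out or oid in used:
            continue
        out[tid] = oid
        used.add(oid)
    return out


def match_particles(
    analysis: FrameAnalysis,
    truth: GroundTruth,
    tol_nm: float = PARTICLE_MATCH_TOL_NM,
) -> dict[str, str]:
    """Greedy one-to-one map: measured particle id -> true oligomer id."""
    gt = [o for o in truth.objects if o.cls == "oligomer"]
    if not gt or not analysis.particles:
        return {}
    centers = np.array([o.centroid_nm for o in gt])
    pairs = []
    for p in analysis.particles:
        d = np.linalg.norm(centers - np.asarray(p.centroid_nm), axis=1)
        j = int(np.argmin(d))
        if d[j] <= tol_nm:
            pairs.append((float(d[j]), p.id, gt[j].id))
    pairs.sort()
    out: dict[str, str] = {}
    used = set()
    for _, pid, oid in pairs:
        if pid in out or oid in used:
            continue
        out[pid] = oid
        used.add(oid)
    return out


def detection_scores(
    analysis: FrameAnalysis, truth: GroundTruth, field_nm: tuple[float, float],
    border_nm: float = 30.0,
) -> dict:
    """Object-level recall and false-discovery rate, excluding border objects."""
    fx, fy = field_nm

    def interior(xy) -> bool:
        return (
            border_nm <= xy[0] <= fx - border_nm
            and border_nm <= xy[1] <= fy - border_nm
        )

    trace_map = match_traces(analysis, truth)
    part_map = match_particles(analysis, truth)
    gt_fibs = [
        o
        for o in truth.objects
        if o.cls.endswith("_fibril")
        and interior(np.asarray(o.backbone_nm).mean(axis=0))
    ]
    gt_parts = [
        o for o in truth.objects if o.cls == "oligomer" and interior(o.centroid_nm)
    ]
    matched_gt = set(trace_map.values()) | set(part_map.values())
    n_truth = len(gt_fibs) + len(gt_parts)
    n_hit = sum(1 for o in gt_fibs + gt_parts if o.id in matched_gt)
    det = [t for t in analysis.traces if not t.touches_border] + [
        p for p in analysis.particles if not p.touches_border
    ]
    det_ids = {d.id for d in det}
    n_false = sum(
        1 for d in det if d.id not in trace_map and d.id not in part_map
    )
    return {
        "recall": n_hit / n_truth if n_truth else float("nan"),
        "fdr": n_false / len(det_ids) if det_ids else 0.0,
        "n_truth": n_truth,
        "n_detected": len(det_ids),
    }
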
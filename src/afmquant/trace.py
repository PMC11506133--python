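"""Object segmentation, sub-pixel backbone tracing and morphometry.

Produces the pipeline's core measurements: fibril arc length, fibril
diameter (robust mean apex height above the local support), oligomer
diameter from sectional apex heights, and the stacked-object height
subtraction that references every object to the level it actually rests on
(substrate, or the apex of a host fibril).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

from .io_formats import HeightMap

logger = logging.getLogger(__name__)

FG_THRESHOLD_NM = 1.5  # between substrate noise and the smallest oligomers
MIN_SKELETON_NM = 50.0
MIN_ELONGATION = 3.0
RUN_PROMINENCE_NM = 2.5  # elevated-run detection on the apex profile
STACKED_MIN_RUN_NM = 50.0  # runs at least this long are stacked fibrils
SUPPORT_WINDOW_NM = 30.0
N_SECTIONS = 5


@dataclasses.dataclass
class Component:
    """One connected foreground component of a flattened height map."""

    label: int
    cls: str  # 'fibril' | 'particle'
    n_pixels: int
    touches_border: bool
    skeleton_path_px: np.ndarray  # (n, 2) row, col in full-image pixels
    skeleton_length_nm: float
    mean_width_nm: float
    centroid_px: tuple[float, float]  # (row, col), height-weighted


@dataclasses.dataclass
class FibrilTrace:
    """Ordered sub-pixel backbone of a fibril with per-point apex heights.

    ``backbone_nm`` runs end-to-end including the half-height endpoints;
    ``interior`` marks the index range safe for diameter and roughness
    statistics (clear of the end caps).
    """

    id: str
    backbone_nm: np.ndarray  # (n, 2) x, y in nm
    apex_heights_nm: np.ndarray  # (n,) height above baseline
    arc_nm: np.ndarray  # (n,) cumulative arc length
    length_nm: float
    diameter_nm: float
    pixel_size_nm: float
    host_id: str | None = None
    touches_border: bool = False
    low_confidence: bool = False

    interior: slice = dataclasses.field(default_factory=lambda: slice(0, None))

    def interior_apex(self) -> np.ndarray:
        return self.apex_heights_nm[self.interior]

    def interior_arc(self) -> np.ndarray:
        return self.arc_nm[self.interior]

    def endpoint_arc_distance(self, arc_pos: float) -> float:
        return float(min(arc_pos, self.length_nm - arc_pos))


@dataclasses.dataclass
class ParticleMeasure:
    """Oligomer measurement from 3-5 sectional profiles."""

    id: str
    centroid_nm: tuple[float, float]
    n_sections: int
    mean_apex_height_nm: float
    support_height_nm: float
    diameter_nm: float
    host_id: str | None = None
    arc_pos_nm: float | None = None  # arc coordinate on the host backbone
    site: str | None = None
    touches_border: bool = False
    host_ambiguous: bool = False


@dataclasses.dataclass
class ElevatedRun:
    """A contiguous stretch of a trace's apex profile above its base level."""

    kind: str  # 'particle' | 'stacked_fibril'
    i0: int
    i1: int  # inclusive index range into the trace arrays
    arc0_nm: float
    arc1_nm: float  # half-height-refined arc boundaries
    peak_idx: int
    peak_height_nm: float
    support_nm: float


# --------------------------------------------------------------------------
# segmentation


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through a skeleton mask, as (row, col) pixels."""
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return np.zeros((0, 2), dtype=int)
    if len(pts) == 1:
        return pts
    index = {tuple(p): i for i, p in enumerate(pts)}
    G = nx.Graph()
    G.add_nodes_from(range(len(pts)))
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    G.add_edge(i, j, weight=math.hypot(dr, dc))
    # double sweep: farthest node from an arbitrary node, then farthest again
    comp = max(nx.connected_components(G), key=len)
    start = next(iter(comp))
    dist = nx.single_source_dijkstra_path_length(G, start)
    u = max(dist, key=dist.get)
    dist_u, paths = nx.single_source_dijkstra(G, u)
    v = max(dist_u, key=dist_u.get)
    return pts[paths[v]]


def _polyline_length(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(np.asarray(pts, float), axis=0), axis=1).sum())


def segment_objects(
    hm: HeightMap,
    threshold_nm: float = FG_THRESHOLD_NM,
    min_skeleton_nm: float = MIN_SKELETON_NM,
    min_elongation: float = MIN_ELONGATION,
) -> tuple[np.ndarray, list[Component]]:
    """Threshold, label (8-connectivity) and classify foreground objects.

    Components are fibrils when their skeleton's longest path is at least
    ``min_skeleton_nm`` long and the elongation (skeleton length over mean
    width) is at least ``min_elongation``; otherwise particles.
    """
    px = hm.pixel_size_nm
    fg = hm.heights > threshold_nm
    labels = skmeasure.label(fg, connectivity=2)
    comps: list[Component] = []
    if labels.max() == 0:
        logger.warning("segment_objects: empty foreground")
        return labels, comps
    rows, cols = labels.shape
    for region in skmeasure.regionprops(labels, intensity_image=hm.heights):
        submask = region.image
        skel = skeletonize(submask)
        path = _longest_skeleton_path(skel)
        if len(path) == 0:
            rr, cc = np.unravel_index(
                np.argmax(np.where(submask, region.image_intensity, -np.inf)),
                submask.shape,
            )
            path = np.array([[rr, cc]])
        path = path + np.array(region.bbox[:2])
        skel_len = _polyline_length(path) * px
        area_nm2 = region.area * px * px
        mean_width = area_nm2 / max(skel_len, px)
        elong = skel_len / max(mean_width, 1e-9)
        cls = (
            "fibril"
            if skel_len >= min_skeleton_nm and elong >= min_elongation
            else "particle"
        )
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == rows or c1 == cols
        w = np.clip(region.image_intensity, 0.0, None) * submask
        tot = w.sum()
        if tot > 0:
            rr = float((w.sum(axis=1) * np.arange(submask.shape[0])).sum() / tot)
            cc = float((w.sum(axis=0) * np.arange(submask.shape[1])).sum() / tot)
        else:
            rr, cc = region.local_centroid
        comps.append(
            Component(
                label=region.label,
                cls=cls,
                n_pixels=int(region.area),
                touches_border=bool(touches),
                skeleton_path_px=path,
                skeleton_length_nm=skel_len,
                mean_width_nm=float(mean_width),
                centroid_px=(rr + r0, cc + c0),
            )
        )
    return labels, comps


# --------------------------------------------------------------------------
# backbone tracing


def _sample(heights: np.ndarray, coords_rc: np.ndarray) -> np.ndarray:
    """Bilinear height samples at fractional (row, col) coordinates."""
    return ndimage.map_coordinates(
        heights, [coords_rc[..., 0], coords_rc[..., 1]], order=1, mode="nearest"
    )


def _parabolic_peak(y0: np.ndarray, y1: np.ndarray, y2: np.ndarray):
    """Vertex offset in [-1, 1] and value of the parabola through 3 samples."""
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    value = y1 - 0.25 * (y0 - y2) * delta
    return delta, value


def _smooth_path(pts: np.ndarray, window: int = 9) -> np.ndarray:
    if len(pts) < window:
        return pts
    kernel = np.ones(window) / window
    out = pts.copy()
    for k in range(2):
        out[:, k] = np.convolve(
            np.pad(pts[:, k], window // 2, mode="edge"), kernel, mode="valid"
        )
    return out


def _extend_endpoint(
    heights: np.ndarray,
    px: float,
    p_px: np.ndarray,  # (row, col) of the trace end
    direction_px: np.ndarray,  # unit (row, col) pointing outward
    half_level: float,
    baseline: float,
    max_steps: int = 30,
    step: float = 0.5,
) -> np.ndarray:
    """Walk outward along the ridge to the half-apex-height crossing."""
    rows, cols = heights.shape
    prev = p_px.astype(float)
    h_prev = _sample(heights, prev[None, :])[0] - baseline
    for i in range(1, max_steps + 1):
        cand = p_px + direction_px * step * i
        if not (0 <= cand[0] <= rows - 1 and 0 <= cand[1] <= cols - 1):
            return prev
        h = _sample(heights, cand[None, :])[0] - baseline
        if h < half_level:
            frac = (h_prev - half_level) / max(h_prev - h, 1e-12)
            return prev + (cand - prev) * np.clip(frac, 0.0, 1.0)
        prev, h_prev = cand, h
    return prev


def trace_backbone(
    component: Component,
    hm: HeightMap,
    baseline: float = 0.0,
    trace_id: str | None = None,
) -> FibrilTrace:
    """Trace a fibril component to a sub-pixel backbone with apex heights.

    Skeleton points are refined to the ridge crest by a parabolic fit to the
    perpendicular height profile; endpoints are extended along the ridge to
    the half-apex-height crossing so arc length covers the full fibril.
    """
    px = hm.pixel_size_nm
    heights = hm.heights
    path = component.skeleton_path_px.astype(float)
    if len(path) < 2:
        raise ValueError("cannot trace a component with a degenerate skeleton")
    n = len(path)

    # tangents from neighbours two steps away (clamped at the ends)
    i0 = np.clip(np.arange(n) - 2, 0, n - 1)
    i1 = np.clip(np.arange(n) + 2, 0, n - 1)
    tang = path[i1] - path[i0]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.clip(norms, 1e-12, None)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    offsets = np.arange(-3.0, 3.0 + 1e-9, 0.5)  # in pixels, perpendicular
    coords = path[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    coords[..., 0] = np.clip(coords[..., 0], 0, heights.shape[0] - 1)
    coords[..., 1] = np.clip(coords[..., 1], 0, heights.shape[1] - 1)
    prof = _sample(heights, coords)  # (n, m)
    jmax = np.clip(np.argmax(prof, axis=1), 1, len(offsets) - 2)
    rows_idx = np.arange(n)
    y0 = prof[rows_idx, jmax - 1]
    y1 = prof[rows_idx, jmax]
    y2 = prof[rows_idx, jmax + 1]
    delta, peak = _parabolic_peak(y0, y1, y2)
    off = offsets[jmax] + delta * 0.5
    refined = path + off[:, None] * normal
    refined = _smooth_path(refined)
    apex = peak - baseline

    # trim the end-cap region from the statistics-safe interior
    apex_med = float(np.median(apex))
    trim = int(math.ceil((apex_med / 2.0) / px)) + 2
    if n - 2 * trim < 10:
        trim = max((n - 10) // 2, 0)

    # endpoint extension to the half-height crossing
    def _end_dir(last: np.ndarray, inner: np.ndarray) -> np.ndarray:
        d = last - inner
        nn = np.linalg.norm(d)
        return d / nn if nn > 0 else np.array([0.0, 0.0])

    k = min(4, n - 1)
    lvl0 = float(np.median(apex[: max(6, trim + 1)])) / 2.0
    lvl1 = float(np.median(apex[-max(6, trim + 1):])) / 2.0
    e_start = _extend_endpoint(
        heights, px, refined[0], _end_dir(refined[0], refined[k]), lvl0, baseline
    )
    e_end = _extend_endpoint(
        heights, px, refined[-1], _end_dir(refined[-1], refined[-1 - k]), lvl1, baseline
    )

    pts = np.concatenate([[e_start], refined, [e_end]])
    apex_all = np.concatenate(
        [
            [_sample(heights, e_start[None, :])[0] - baseline],
            apex,
            [_sample(heights, e_end[None, :])[0] - baseline],
        ]
    )
    # to physical coordinates: x = col * px, y = row * px
    xy = np.stack([pts[:, 1] * px, pts[:, 0] * px], axis=1)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    interior = slice(trim + 1, len(xy) - trim - 1)

    trace = FibrilTrace(
        id=trace_id or f"f{component.label}",
        backbone_nm=xy,
        apex_heights_nm=apex_all,
        arc_nm=arc,
        length_nm=float(arc[-1]),
        diameter_nm=float("nan"),
        pixel_size_nm=px,
        touches_border=component.touches_border,
        interior=interior,
    )
    trace.diameter_nm = fibril_diameter(trace)
    return trace


# --------------------------------------------------------------------------
# diameter, elevated runs, support subtraction


def fibril_diameter(
    trace: FibrilTrace,
    support_nm: float = 0.0,
    exclude_spans: list[tuple[float, float]] | None = None,
    trim_fraction: float = 0.1,
) -> float:
    """Trimmed mean (central 80%) of apex heights above the local support.

    ``exclude_spans`` removes arc intervals occupied by adsorbed objects so
    riders do not bias their host's diameter.
    """
    apex = trace.interior_apex()
    arc = trace.interior_arc()
    if exclude_spans:
        keep = np.ones(len(arc), dtype=bool)
        for a0, a1 in exclude_spans:
            keep &= ~((arc >= a0 - 4.0) & (arc <= a1 + 4.0))
        apex = apex[keep]
    if len(apex) < 10:
        trace.low_confidence = True
        if len(apex) == 0:
            return float("nan")
    vals = np.sort(apex - support_nm)
    k = int(len(vals) * trim_fraction)
    core = vals[k : len(vals) - k] if len(vals) > 2 * k else vals
    return float(np.mean(core))


def detect_elevated_runs(
    trace: FibrilTrace,
    prominence_nm: float = RUN_PROMINENCE_NM,
    stacked_min_nm: float = STACKED_MIN_RUN_NM,
    merge_gap_nm: float = 6.0,
) -> list[ElevatedRun]:
    """Find adsorbed objects as elevated runs in a trace's apex profile.

    The base level is the 25th percentile of the interior apex heights
    (robust to long riders); contiguous stretches more than
    ``prominence_nm`` above it are objects: arc extent >= ``stacked_min_nm``
    means a stacked secondary fibril, shorter means an adsorbed particle.
    Boundaries are refined to the half-height crossing.

    The detection threshold additionally scales with the profile's own
    lower-side spread so that the peaks of a strongly corrugated fibril are
    not mistaken for adsorbed objects (spread is estimated from the 10th-50th
    percentile range, which sparse genuine bumps do not inflate).
    """
    apex = trace.apex_heights_nm
    arc = trace.arc_nm
    interior = trace.interior_apex()
    base = float(np.percentile(interior, 25))
    p10, p50 = np.percentile(interior, [10, 50])
    spread = float(p50 - p10) / 1.16  # Gaussian-consistent scale estimate
    above = apex > base + max(prominence_nm, 3.0 * spread)
    runs: list[list[int]] = []
    i = 0
    n = len(apex)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if runs and arc[i] - arc[runs[-1][1]] < merge_gap_nm:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    out: list[ElevatedRun] = []
    for i0, i1 in runs:
        seg = apex[i0 : i1 + 1]
        peak_rel = int(np.argmax(seg))
        height = float(np.median(seg)) if len(seg) >= 5 else float(seg.max())
        half = base + (height - base) / 2.0
        # half-height refinement of the run boundaries
        a0 = arc[i0]
        if i0 > 0 and apex[i0 - 1] < half <= apex[i0]:
            f = (half - apex[i0 - 1]) / max(apex[i0] - apex[i0 - 1], 1e-12)
            a0 = arc[i0 - 1] + f * (arc[i0] - arc[i0 - 1])
        a1 = arc[i1]
        if i1 < n - 1 and apex[i1 + 1] < half <= apex[i1]:
            f = (half - apex[i1 + 1]) / max(apex[i1] - apex[i1 + 1], 1e-12)
            a1 = arc[i1 + 1] + f * (arc[i1] - arc[i1 + 1])
        extent = a1 - a0
        kind = "stacked_fibril" if extent >= stacked_min_nm else "particle"
        out.append(
            ElevatedRun(
                kind=kind,
                i0=i0,
                i1=i1,
                arc0_nm=float(a0),
                arc1_nm=float(a1),
                peak_idx=i0 + peak_rel,
                peak_height_nm=float(seg.max()),
                support_nm=base,
            )
        )
    return out


def run_support(
    trace: FibrilTrace,
    run: ElevatedRun,
    all_runs: list[ElevatedRun],
    window_nm: float = SUPPORT_WINDOW_NM,
    guard_nm: float = 6.0,
) -> float:
    """Host support level: median apex in a 30 nm arc window around a run,
    excluding every elevated run.

    ``guard_nm`` keeps the window clear of the tip-broadened flanks that
    extend beyond the half-height run boundaries.
    """
    arc = trace.arc_nm
    apex = trace.apex_heights_nm
    sel = ((arc >= run.arc0_nm - window_nm) & (arc < run.arc0_nm - guard_nm)) | (
        (arc > run.arc1_nm + guard_nm) & (arc <= run.arc1_nm + window_nm)
    )
    for other in all_runs:
        sel &= ~((arc >= other.arc0_nm - guard_nm) & (arc <= other.arc1_nm + guard_nm))
    # keep clear of the trace's end caps
    sel[: trace.interior.start] = False
    if trace.interior.stop is not None:
        sel[trace.interior.stop :] = False
    if sel.sum() >= 3:
        return float(np.median(apex[sel]))
    return run.support_nm


def resolve_host(
    centroid_nm: tuple[float, float],
    traces: list[FibrilTrace],
    eps_nm: float,
) -> tuple[FibrilTrace | None, float, bool]:
    """Nearest-backbone host assignment with a deterministic tie-break.

    Returns (host trace or None, arc position of the closest backbone point,
    ambiguity flag).  Ambiguity: two hosts within the on-fibril window; the
    nearest backbone wins, ties go to the lower id and are flagged.
    """
    c = np.asarray(centroid_nm)
    candidates = []
    for t in traces:
        d = np.linalg.norm(t.backbone_nm - c, axis=1)
        j = int(np.argmin(d))
        candidates.append((float(d[j]), t.id, t, float(t.arc_nm[j])))
    if not candidates:
        return None, 0.0, False
    within = sorted([cand for cand in candidates if cand[0] <= eps_nm])
    if not within:
        return None, 0.0, False
    flagged = len(within) > 1 and (within[1][0] - within[0][0]) < 1e-9
    best = within[0]
    return best[2], best[3], flagged or len(within) > 1


# --------------------------------------------------------------------------
# particle measurement


def _section_apex(
    heights: np.ndarray,
    center_px: np.ndarray,  # (row, col)
    half_len_px: float,
    angle: float,
    baseline: float,
) -> float:
    """Apex of one sectional profile, parabola-refined at the maximum.

    Samples cubically on a local patch: bilinear interpolation would shave
    ~0.1 nm off the curved apex of a sphere at 2 nm pixels.
    """
    m = int(math.ceil(half_len_px)) + 3
    r0 = max(int(center_px[0]) - m, 0)
    c0 = max(int(center_px[1]) - m, 0)
    patch = heights[r0 : int(center_px[0]) + m + 1, c0 : int(center_px[1]) + m + 1]
    d = np.array([math.sin(angle), math.cos(angle)])
    t = np.arange(-half_len_px, half_len_px + 1e-9, 0.5)
    coords = (center_px - (r0, c0))[None, :] + t[:, None] * d[None, :]
    coords[:, 0] = np.clip(coords[:, 0], 0, patch.shape[0] - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, patch.shape[1] - 1)
    prof = ndimage.map_coordinates(
        patch, [coords[:, 0], coords[:, 1]], order=3, mode="nearest"
    )
    j = int(np.clip(np.argmax(prof), 1, len(prof) - 2))
    _, peak = _parabolic_peak(prof[j - 1], prof[j], prof[j + 1])
    return float(peak - baseline)


def _refine_center(
    heights: np.ndarray, center_px: np.ndarray, radius_px: float = 2.0
) -> np.ndarray:
    """Shift a particle centre onto the local height maximum (sub-pixel).

    Sections through an off-apex centre underestimate a sphere's apex by
    ~r^2/d; a quarter-pixel grid search removes that bias.
    """
    m = int(math.ceil(radius_px)) + 3
    r0 = max(int(center_px[0]) - m, 0)
    c0 = max(int(center_px[1]) - m, 0)
    patch = heights[r0 : int(center_px[0]) + m + 1, c0 : int(center_px[1]) + m + 1]
    # localise on a lightly smoothed patch so the centre tracks the bump,
    # not the pixel-noise maximum
    patch = ndimage.gaussian_filter(patch, 0.8, mode="nearest")
    off = np.arange(-radius_px, radius_px + 1e-9, 0.25)
    rr, cc = np.meshgrid(off, off, indexing="ij")
    coords_r = np.clip(center_px[0] - r0 + rr, 0, patch.shape[0] - 1)
    coords_c = np.clip(center_px[1] - c0 + cc, 0, patch.shape[1] - 1)
    vals = ndimage.map_coordinates(
        patch, [coords_r.ravel(), coords_c.ravel()], order=3, mode="nearest"
    )
    k = int(np.argmax(vals))
    return np.array(
        [center_px[0] + rr.ravel()[k], center_px[1] + cc.ravel()[k]]
    )


def measure_particle(
    component: Component,
    hm: HeightMap,
    baseline: float = 0.0,
    n_sections: int = N_SECTIONS,
    particle_id: str | None = None,
) -> ParticleMeasure:
    """Measure a substrate particle from sectional profiles.

    ``n_sections`` equally-spaced sections pass through the height-weighted
    centroid; the mean of their apex heights minus the support height (zero
    on the substrate) is the diameter (height equals diameter in a sphere).
    """
    if not 3 <= n_sections <= 5:
        raise ValueError("n_sections must be within [3, 5]")
    px = hm.pixel_size_nm
    center = _refine_center(hm.heights, np.asarray(component.centroid_px, float))
    r_eq_px = math.sqrt(component.n_pixels / math.pi)
    half_len = r_eq_px + 3.0
    angles = [k * math.pi / n_sections for k in range(n_sections)]
    apexes = [
        _section_apex(hm.heights, center, half_len, a, baseline) for a in angles
    ]
    mean_apex = float(np.mean(apexes))
    return ParticleMeasure(
        id=particle_id or f"pt{component.label}",
        centroid_nm=(center[1] * px, center[0] * px),
        n_sections=n_sections,
        mean_apex_height_nm=mean_apex,
        support_height_nm=0.0,
        diameter_nm=mean_apex,
        touches_border=component.touches_border,
    )


def measure_on_fibril_particle(
    trace: FibrilTrace,
    run: ElevatedRun,
    all_runs: list[ElevatedRun],
    hm: HeightMap,
    baseline: float = 0.0,
    n_sections: int = N_SECTIONS,
    particle_id: str | None = None,
) -> ParticleMeasure:
    """Measure an adsorbed oligomer found as a short elevated run.

    The support height comes from the host apex around the run
    (:func:`run_support`); the diameter is mean sectional apex minus support
    — the stacked-object height subtraction.
    """
    px = hm.pixel_size_nm
    xy = trace.backbone_nm[run.peak_idx]
    center_px = _refine_center(hm.heights, np.array([xy[1] / px, xy[0] / px]))
    half_len = max((run.arc1_nm - run.arc0_nm) / 2.0 + 2.0, 3.0 * px) / px
    angles = [k * math.pi / n_sections for k in range(n_sections)]
    apexes = [
        _section_apex(hm.heights, center_px, half_len, a, baseline) for a in angles
    ]
    mean_apex = float(np.mean(apexes))
    support = run_support(trace, run, all_runs)
    arc_pos = float(trace.arc_nm[run.peak_idx])
    return ParticleMeasure(
        id=particle_id or f"{trace.id}_b{run.i0}",
        centroid_nm=(float(xy[0]), float(xy[1])),
        n_sections=n_sections,
        mean_apex_height_nm=mean_apex,
        support_height_nm=float(support),
        diameter_nm=mean_apex - float(support),
        host_id=trace.id,
        arc_pos_nm=arc_pos,
        touches_border=False,
    )


def extract_stacked_fibril(
    trace: FibrilTrace,
    run: ElevatedRun,
    all_runs: list[ElevatedRun],
    rider_id: str,
) -> FibrilTrace:
    """Materialise a stacked secondary fibril from a long elevated run."""
    sel = (trace.arc_nm >= run.arc0_nm) & (trace.arc_nm <= run.arc1_nm)
    idx = np.where(sel)[0]
    support = run_support(trace, run, all_runs)
    backbone = trace.backbone_nm[idx]
    apex = trace.apex_heights_nm[idx]
    arc = trace.arc_nm[idx] - trace.arc_nm[idx[0]]
    pad = max(int(round(4.0 / max(trace.pixel_size_nm, 1e-9))), 2)
    ninterior = len(idx)
    lo = min(pad, max((ninterior - 10) // 2, 0))
    rider = FibrilTrace(
        id=rider_id,
        backbone_nm=backbone,
        apex_heights_nm=apex,
        arc_nm=arc,
        length_nm=float(run.arc1_nm - run.arc0_nm),
        diameter_nm=float("nan"),
        pixel_size_nm=trace.pixel_size_nm,
        host_id=trace.id,
        touches_border=trace.touches_border,
        interior=slice(lo, ninterior - lo if ninterior - 2 * lo >= 10 else None),
    )
    rider.diameter_nm = fibril_diameter(rider, support_nm=float(support))
    return rider
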
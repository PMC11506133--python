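"""Adsorption-site, fibril-generation and catalytic-activity classifiers.

Three classification rules recur throughout the analysis:

* adsorption site of a particle — edge (terminal region of a backbone),
  backbone (elsewhere on a fibril) or substrate;
* fibril generation — primary vs secondary, fingerprinted by the RMS
  roughness (Rq) of the backbone apex profile (the two populations occupy
  disjoint Rq ranges, ~0.4-2.2 nm vs ~2.5-8.5 nm);
* catalytic activity of a primary fibril — dormant (no adsorbed secondary
  objects), superspreader (linear density of adsorbed objects at least
  3x the frame median of non-dormant fibrils), otherwise active.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trace import FibrilTrace, ParticleMeasure, resolve_host

EDGE_WINDOW_NM = 20.0  # arc distance from an endpoint counted as "edge"
RQ_WINDOW_NM = 100.0
RQ_THRESHOLD_NM = 2.35  # midpoint of the 2.2 / 2.5 nm gap between classes
SUPERSPREADER_FACTOR = 3.0
NORMALIZATION_AREA_NM2 = 500.0  # recorded verbatim as reported; not a rescale


@dataclasses.dataclass
class SiteDistribution:
    """Per-frame counts and normalized fractions of adsorption sites."""

    counts: dict[str, int]
    fractions_all: dict[str, float]
    fractions_on_fibril: dict[str, float] | None  # None when nothing on-fibril
    frame_id: str = "frame"
    time_min: float | None = None
    normalization_area_nm2: float = NORMALIZATION_AREA_NM2


@dataclasses.dataclass
class RoughnessRecord:
    fibril_id: str
    rq_nm: float
    detrend: str
    window_rq_nm: list[float]
    generation: str | None = None
    flagged_short: bool = False


@dataclasses.dataclass
class ActivityRecord:
    fibril_id: str
    attached_count: int
    backbone_length_nm: float
    lambda_per_um: float
    activity: str  # dormant | active | superspreader


def classify_site(
    particle: ParticleMeasure,
    traces: list[FibrilTrace],
    eps_on_nm: float | None = None,
    eps_edge_nm: float = EDGE_WINDOW_NM,
) -> str:
    """Classify a particle's adsorption site.

    Farther than ``eps_on_nm`` from every backbone -> substrate; otherwise
    edge when the arc distance to the nearest backbone endpoint is at most
    ``eps_edge_nm``, else backbone.  The default on-fibril window is the
    host half-width plus the particle radius plus one pixel.
    """
    if particle.host_id is not None:
        host = next((t for t in traces if t.id == particle.host_id), None)
        if host is not None and particle.arc_pos_nm is not None:
            d_end = host.endpoint_arc_distance(particle.arc_pos_nm)
            return "edge" if d_end <= eps_edge_nm else "backbone"
    if not traces:
        return "substrate"
    if eps_on_nm is None:
        half_width = float(np.nanmedian([t.diameter_nm for t in traces])) / 2.0
        px = traces[0].pixel_size_nm
        eps_on_nm = half_width + particle.diameter_nm / 2.0 + px
    host, arc_pos, ambiguous = resolve_host(particle.centroid_nm, traces, eps_on_nm)
    if host is None:
        return "substrate"
    particle.host_id = host.id
    particle.arc_pos_nm = arc_pos
    particle.host_ambiguous = ambiguous
    return "edge" if host.endpoint_arc_distance(arc_pos) <= eps_edge_nm else "backbone"


def rq_roughness(
    trace: FibrilTrace,
    window_nm: float = RQ_WINDOW_NM,
    detrend: str = "linear",
    exclude_spans: list[tuple[float, float]] | None = None,
) -> RoughnessRecord:
    """Windowed, detrended RMS roughness along a fibril backbone.

    The apex-height sequence is split into arc-length windows (default
    100 nm; at least 3 windows whenever the trace allows); each window is
    linearly detrended and contributes Rq = sqrt(mean(deviation^2)).  The
    record carries the mean of the window values.

    ``exclude_spans`` drops arc intervals occupied by adsorbed objects so
    the fingerprint reflects the fibril surface, not its cargo.
    """
    if detrend not in ("linear", "none"):
        raise ValueError("detrend must be 'linear' or 'none'")
    apex = trace.interior_apex()
    arc = trace.interior_arc()
    if exclude_spans:
        keep = np.ones(len(arc), dtype=bool)
        for a0, a1 in exclude_spans:
            keep &= ~((arc >= a0 - 4.0) & (arc <= a1 + 4.0))
        apex = apex[keep]
        arc = arc[keep]
    if len(apex) < 20:
        raise ValueError("rq_roughness requires at least 20 apex samples")
    total = arc[-1] - arc[0]
    flagged = False
    if total >= 3 * window_nm:
        n_win = int(total // window_nm)
    elif total >= 60.0:
        n_win = 3
    else:
        n_win = 1
        flagged = True
    edges = arc[0] + np.linspace(0.0, total, n_win + 1)
    window_rq: list[float] = []
    for a0, a1 in zip(edges[:-1], edges[1:]):
        sel = (arc >= a0) & (arc <= a1)
        if sel.sum() < 5:
            continue
        y = apex[sel]
        if detrend == "linear":
            x = arc[sel]
            coef = np.polynomial.polynomial.polyfit(x - x.mean(), y, 1)
            y = y - np.polynomial.polynomial.polyval(x - x.mean(), coef)
        else:
            y = y - y.mean()
        window_rq.append(float(np.sqrt(np.mean(y**2))))
    if not window_rq:
        raise ValueError("no usable roughness window")
    return RoughnessRecord(
        fibril_id=trace.id,
        rq_nm=float(np.mean(window_rq)),
        detrend=detrend,
        window_rq_nm=window_rq,
        flagged_short=flagged,
    )


def classify_generation(
    record: RoughnessRecord, threshold_nm: float = RQ_THRESHOLD_NM
) -> str:
    """Secondary iff Rq >= threshold (boundary inclusive-upper by contract)."""
    generation = "secondary" if record.rq_nm >= threshold_nm else "primary"
    record.generation = generation
    return generation


def classify_activity(
    traces: list[FibrilTrace],
    attached_counts: dict[str, int],
    factor: float = SUPERSPREADER_FACTOR,
) -> list[ActivityRecord]:
    """Dormant / active / superspreader labels for primary fibrils.

    ``attached_counts`` maps a primary trace id to its number of adsorbed
    secondary objects (oligomers plus stacked secondary fibrils).  The
    linear density lambda is objects per micrometre of backbone; a fibril is
    a superspreader when lambda >= ``factor`` x the median lambda of
    non-dormant fibrils in the frame (rule inert below 3 non-dormant
    fibrils).  Labels are permutation-invariant to fibril order.
    """
    recs = []
    lambdas = {}
    for t in traces:
        count = int(attached_counts.get(t.id, 0))
        lam = count / max(t.length_nm / 1000.0, 1e-9)
        lambdas[t.id] = lam
        recs.append(
            ActivityRecord(
                fibril_id=t.id,
                attached_count=count,
                backbone_length_nm=t.length_nm,
                lambda_per_um=lam,
                activity="dormant" if count == 0 else "active",
            )
        )
    non_dormant = sorted(
        r.lambda_per_um for r in recs if r.attached_count > 0
    )
    if len(non_dormant) >= 3:
        med = float(np.median(non_dormant))
        for r in recs:
            if r.attached_count > 0 and r.lambda_per_um >= factor * med:
                r.activity = "superspreader"
    return recs


def site_distribution(
    particles: list[ParticleMeasure],
    frame_id: str = "frame",
    time_min: float | None = None,
) -> SiteDistribution:
    """Counts and normalized fractions per adsorption-site class.

    On-fibril fractions (edge vs backbone) are reported separately and are
    absent — not 0/0 — when no particle sits on a fibril.
    """
    counts = {"edge": 0, "backbone": 0, "substrate": 0}
    for p in particles:
        if p.site in counts:
            counts[p.site] += 1
    total = sum(counts.values())
    fractions_all = {
        k: (v / total if total else 0.0) for k, v in counts.items()
    }
    on_fib = counts["edge"] + counts["backbone"]
    fractions_on = (
        {"edge": counts["edge"] / on_fib, "backbone": counts["backbone"] / on_fib}
        if on_fib
        else None
    )
    return SiteDistribution(
        counts=counts,
        fractions_all=fractions_all,
        fractions_on_fibril=fractions_on,
        frame_id=frame_id,
        time_min=time_min,
    )
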
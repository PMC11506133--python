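"""Synthetic topograph simulator.

Renders ground-truth scenes of fibrils and oligomers on a substrate, then
applies tip convolution (grayscale dilation) and scan artifacts, producing
realistic height maps whose every object has a known geometry.  All
downstream measurement code is validated against these scenes.

Geometry conventions (ideal, pre-tip surface):

* a fibril of diameter ``d`` contributes a cylindrical ridge whose apex is
  ``d`` above its support (the upper envelope of a cylinder resting on the
  support plane), with flat end caps at the backbone endpoints;
* an oligomer of diameter ``d`` contributes the upper envelope of a sphere
  resting on its support: apex ``d`` above support, footprint radius ``d/2``;
* overlapping objects combine by upper envelope (pointwise max);
* corrugated fibrils carry a longitudinal diameter modulation
  ``d(s) = d + c(s)`` whose RMS equals ``amplitude / sqrt(2)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import HeightMap

__all__ = [
    "TipModel",
    "FibrilPopulation",
    "OligomerPopulation",
    "ArtifactSpec",
    "SceneSpec",
    "GroundTruthObject",
    "GroundTruth",
    "PlacementError",
    "render_scene",
    "place_oligomers",
    "sample_site_classes",
    "apply_tip",
    "erode_tip",
    "tip_structure",
    "add_scan_artifacts",
    "simulate_frame",
]

ARC_STEP_NM = 1.0  # spacing of backbone arc samples used for rasterisation
MIN_RENDER_DIAMETER_NM = 1.0  # corrugation dips are clipped here
EDGE_PLACEMENT_MAX_NM = 12.0  # edge oligomers sit within this arc of an end
BACKBONE_MARGIN_NM = 32.0  # backbone oligomers keep this arc from the ends


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without violating the rules."""


# --------------------------------------------------------------------------
# specs


@dataclasses.dataclass
class TipModel:
    """Probe shape as a structuring function s(dx, dy) <= 0, s(0,0) = 0."""

    shape: str = "paraboloid"  # or "sphere_cone"
    apex_radius_nm: float = 2.0
    half_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("paraboloid", "sphere_cone"):
            raise ValueError(f"unknown tip shape {self.shape!r}")
        if self.apex_radius_nm <= 0:
            raise ValueError("apex_radius_nm must be > 0")
        if self.shape == "sphere_cone" and not self.half_angle_deg:
            raise ValueError("sphere_cone tip requires half_angle_deg")

    def profile(self, rho: np.ndarray) -> np.ndarray:
        """Tip height drop -z(rho) at lateral distance rho from the apex."""
        rho = np.asarray(rho, dtype=float)
        R = self.apex_radius_nm
        if self.shape == "paraboloid":
            return -(rho**2) / (2.0 * R)
        alpha = math.radians(self.half_angle_deg)
        rho_t = R * math.cos(alpha)
        sphere = -(R - np.sqrt(np.clip(R**2 - rho**2, 0.0, None)))
        cone = -((rho - rho_t) / math.tan(alpha) + R * (1.0 - math.sin(alpha)))
        return np.where(rho <= rho_t, sphere, cone)

    def support_radius(self, depth_nm: float) -> float:
        """Lateral radius at which the tip has dropped by ``depth_nm``."""
        R = self.apex_radius_nm
        if self.shape == "paraboloid":
            return math.sqrt(2.0 * R * depth_nm)
        alpha = math.radians(self.half_angle_deg)
        cap_depth = R * (1.0 - math.sin(alpha))
        if depth_nm <= cap_depth:
            return math.sqrt(max(0.0, 2 * R * depth_nm - depth_nm**2))
        return R * math.cos(alpha) + (depth_nm - cap_depth) * math.tan(alpha)

    @classmethod
    def from_dict(cls, d: dict) -> "TipModel":
        return cls(
            shape=d.get("shape", "paraboloid"),
            apex_radius_nm=float(d.get("radius_nm", d.get("apex_radius_nm", 2.0))),
            half_angle_deg=d.get("half_angle_deg"),
        )


@dataclasses.dataclass
class FibrilPopulation:
    count: int = 0
    diameter_mean_nm: float = 8.3
    diameter_sd_nm: float = 0.0
    length_mean_nm: float = 842.0
    length_sd_nm: float = 0.0
    persistence_nm: float = 5000.0
    corrugation_amplitude_mean_nm: float = 0.0
    corrugation_amplitude_sd_nm: float = 0.0
    corrugation_wavelength_nm: float = 80.0
    stacked_on_primary: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.diameter_mean_nm <= 0:
            raise ValueError("diameters must be > 0")
        for name in ("diameter_sd_nm", "length_sd_nm", "corrugation_amplitude_sd_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "FibrilPopulation":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class OligomerPopulation:
    count: int = 0
    diameter_mean_nm: float = 7.9
    diameter_sd_nm: float = 0.0
    p_edge: float = 0.0
    p_backbone: float = 0.0
    p_substrate: float = 1.0
    superspreader_host_factor: float | None = None

    def __post_init__(self) -> None:
        probs = (self.p_edge, self.p_backbone, self.p_substrate)
        if any(p < 0 for p in probs):
            raise ValueError("placement probabilities must be >= 0")
        if self.count > 0 and abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError("placement probabilities must sum to 1")
        if self.diameter_mean_nm <= 0:
            raise ValueError("diameters must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "OligomerPopulation":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class ArtifactSpec:
    line_offset_sigma_nm: float = 0.0
    tilt_nm_per_um: tuple[float, float] = (0.0, 0.0)  # (x, y)
    pixel_noise_sigma_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.line_offset_sigma_nm < 0 or self.pixel_noise_sigma_nm < 0:
            raise ValueError("sigmas must be >= 0")
        self.tilt_nm_per_um = tuple(float(t) for t in self.tilt_nm_per_um)

    @classmethod
    def from_dict(cls, d: dict) -> "ArtifactSpec":
        return cls(
            line_offset_sigma_nm=float(d.get("line_offset_sigma_nm", 0.0)),
            tilt_nm_per_um=tuple(d.get("tilt_nm_per_um", (0.0, 0.0))),
            pixel_noise_sigma_nm=float(d.get("pixel_noise_sigma_nm", 0.0)),
        )


@dataclasses.dataclass
class SceneSpec:
    """Full configuration of one simulated frame.  ``seed`` is mandatory."""

    seed: int
    field_nm: tuple[float, float] = (1000.0, 1000.0)  # (x extent, y extent)
    pixel_size_nm: float = 2.0
    substrate_sigma_nm: float = 0.0
    primary_fibrils: FibrilPopulation = dataclasses.field(
        default_factory=lambda: FibrilPopulation(count=0)
    )
    secondary_fibrils: FibrilPopulation = dataclasses.field(
        default_factory=lambda: FibrilPopulation(count=0, stacked_on_primary=True)
    )
    oligomers: OligomerPopulation = dataclasses.field(
        default_factory=lambda: OligomerPopulation(count=0)
    )
    tip: TipModel = dataclasses.field(default_factory=TipModel)
    artifacts: ArtifactSpec = dataclasses.field(default_factory=ArtifactSpec)
    time_min: float | None = None
    frame_id: str = "frame"
    min_separation_nm: float = 40.0  # backbone-to-backbone clearance

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if np.isscalar(self.field_nm):
            self.field_nm = (float(self.field_nm), float(self.field_nm))
        self.field_nm = (float(self.field_nm[0]), float(self.field_nm[1]))
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.substrate_sigma_nm < 0:
            raise ValueError("substrate_sigma_nm must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            int(round(self.field_nm[1] / self.pixel_size_nm)),
            int(round(self.field_nm[0] / self.pixel_size_nm)),
        )

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "SceneSpec":
        d = dict(d)
        if seed is not None:
            d["seed"] = seed
        if "seed" not in d:
            raise ValueError("seed is mandatory")
        return cls(
            seed=int(d["seed"]),
            field_nm=d.get("field_nm", (1000.0, 1000.0)),
            pixel_size_nm=float(d.get("pixel_size_nm", 2.0)),
            substrate_sigma_nm=float(d.get("substrate_sigma_nm", 0.0)),
            primary_fibrils=FibrilPopulation.from_dict(d.get("primary_fibrils", {})),
            secondary_fibrils=FibrilPopulation.from_dict(
                {"stacked_on_primary": True, **d.get("secondary_fibrils", {})}
            ),
            oligomers=OligomerPopulation.from_dict(d.get("oligomers", {})),
            tip=TipModel.from_dict(d.get("tip", {})),
            artifacts=ArtifactSpec.from_dict(d.get("artifacts", {})),
            time_min=d.get("time_min"),
            frame_id=str(d.get("frame_id", "frame")),
            min_separation_nm=float(d.get("min_separation_nm", 40.0)),
        )


# --------------------------------------------------------------------------
# ground truth


@dataclasses.dataclass
class GroundTruthObject:
    id: str
    cls: str  # primary_fibril | secondary_fibril | oligomer
    true_diameter_nm: float
    true_length_nm: float | None = None
    backbone_nm: np.ndarray | None = None  # (n, 2) x,y in nm
    centroid_nm: tuple[float, float] | None = None
    placement: str | None = None  # edge | backbone | substrate (oligomers)
    host_id: str | None = None
    host_arc_nm: float | None = None  # oligomer contact arc position on host
    true_rq_nm: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.backbone_nm is not None:
            d["backbone_nm"] = np.asarray(self.backbone_nm).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthObject":
        d = dict(d)
        if d.get("backbone_nm") is not None:
            d["backbone_nm"] = np.asarray(d["backbone_nm"], dtype=float)
        if d.get("centroid_nm") is not None:
            d["centroid_nm"] = tuple(d["centroid_nm"])
        return cls(**d)


@dataclasses.dataclass
class GroundTruth:
    objects: list[GroundTruthObject]
    frame_id: str = "frame"
    time_min: float | None = None
    seed: int | None = None

    def of_class(self, cls: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.cls == cls]

    def by_id(self, oid: str) -> GroundTruthObject:
        for o in self.objects:
            if o.id == oid:
                return o
        raise KeyError(oid)

    def to_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "time_min": self.time_min,
            "seed": self.seed,
            "objects": [o.to_dict() for o in self.objects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            objects=[GroundTruthObject.from_dict(o) for o in d["objects"]],
            frame_id=d.get("frame_id", "frame"),
            time_min=d.get("time_min"),
            seed=d.get("seed"),
        )


# --------------------------------------------------------------------------
# backbone and corrugation generation


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _persistent_walk(rng, start, theta0, length_nm, persistence_nm, ds=2.0):
    """Smoothed random-walk polyline of the given arc length (nm coords)."""
    n = max(int(round(length_nm / ds)), 2)
    sigma = math.sqrt(ds / max(persistence_nm, 1e-6))
    theta = theta0 + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma, n - 1))])
    steps = np.stack([np.cos(theta), np.sin(theta)], axis=1) * ds
    pts = np.concatenate([[start], start + np.cumsum(steps, axis=0)])
    # trim to the exact arc length
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    keep = s <= length_nm + 1e-9
    return pts[keep]


def arc_resample(points: np.ndarray, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length spacing ``ds``.

    Returns (samples, arc) where arc[i] is the arc-length coordinate of
    samples[i]; the final point of the polyline is always included.
    """
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    arc = np.arange(0.0, total, ds)
    if total - (arc[-1] if len(arc) else 0.0) > 1e-9:
        arc = np.concatenate([arc, [total]])
    x = np.interp(arc, s, points[:, 0])
    y = np.interp(arc, s, points[:, 1])
    return np.stack([x, y], axis=1), arc


def _corrugation_profile(rng, arc, amplitude, wavelength) -> np.ndarray:
    """Sinusoid + filtered noise, rescaled so RMS = amplitude / sqrt(2)."""
    if amplitude <= 0 or len(arc) < 4:
        return np.zeros(len(arc))
    phase = rng.uniform(0.0, 2.0 * math.pi)
    c = np.sin(2.0 * math.pi * arc / wavelength + phase)
    noise = rng.normal(0.0, 1.0, len(arc))
    sigma_pts = max(wavelength / 4.0 / max(arc[1] - arc[0], 1e-9), 1.0)
    noise = ndimage.gaussian_filter1d(noise, sigma_pts, mode="reflect")
    nrm = noise.std()
    if nrm > 0:
        c = c + 0.3 * noise / nrm
    c = c - c.mean()
    rms = math.sqrt(float(np.mean(c**2)))
    target = amplitude / math.sqrt(2.0)
    return c * (target / rms)


@dataclasses.dataclass
class _RenderedFibril:
    """Internal record used during rasterisation."""

    id: str
    cls: str
    samples: np.ndarray  # (n, 2) nm
    arc: np.ndarray  # (n,) nm
    diam: np.ndarray  # (n,) nm, corrugation included
    support: np.ndarray  # (n,) nm, 0 on substrate or host apex profile
    base_diameter: float
    host_id: str | None = None
    host_arc0: float | None = None  # rider start arc on the host
    rider_spans: list = dataclasses.field(default_factory=list)

    @property
    def length_nm(self) -> float:
        return float(self.arc[-1])

    def apex(self) -> np.ndarray:
        return self.support + self.diam

    def true_rq(self) -> float:
        d = self.diam - self.diam.mean()
        return float(np.sqrt(np.mean(d**2)))


def _place_fibril_population(
    rng,
    pop: FibrilPopulation,
    spec: SceneSpec,
    existing: list[_RenderedFibril],
    prefix: str,
    cls: str,
    max_attempts: int = 500,
) -> list[_RenderedFibril]:
    """Place free-standing fibrils with mutual backbone clearance."""
    fx, fy = spec.field_nm
    placed: list[_RenderedFibril] = []
    for i in range(pop.count):
        dia = _truncated_normal(
            rng,
            pop.diameter_mean_nm,
            pop.diameter_sd_nm,
            max(3.0, pop.diameter_mean_nm - 3 * pop.diameter_sd_nm),
            pop.diameter_mean_nm + 3 * pop.diameter_sd_nm,
        )
        margin = dia / 2 + 14.0
        max_len = math.hypot(fx, fy) - 2 * margin
        length = _truncated_normal(
            rng,
            pop.length_mean_nm,
            pop.length_sd_nm,
            max(60.0, pop.length_mean_nm - 3 * pop.length_sd_nm),
            min(pop.length_mean_nm + 3 * pop.length_sd_nm, max_len),
        )
        others = existing + placed
        tree = (
            cKDTree(np.concatenate([f.samples for f in others]))
            if others
            else None
        )
        ok = None
        for attempt in range(max_attempts):
            start = np.array(
                [rng.uniform(margin, fx - margin), rng.uniform(margin, fy - margin)]
            )
            # neatly arranged submonolayers pack long fibrils near-nematically;
            # bias most attempts towards an existing fibril's direction
            others_dirs = [
                f.samples[-1] - f.samples[0] for f in existing + placed
            ]
            if others_dirs and attempt % 4 != 0:
                ref = others_dirs[int(rng.integers(len(others_dirs)))]
                theta0 = math.atan2(ref[1], ref[0]) + rng.normal(0.0, 0.35)
                if rng.uniform() < 0.5:
                    theta0 += math.pi
            else:
                theta0 = rng.uniform(0.0, 2.0 * math.pi)
            pts = _persistent_walk(rng, start, theta0, length, pop.persistence_nm)
            if (
                pts[:, 0].min() < margin
                or pts[:, 0].max() > fx - margin
                or pts[:, 1].min() < margin
                or pts[:, 1].max() > fy - margin
            ):
                continue
            if tree is not None:
                dmin, _ = tree.query(pts, k=1)
                if dmin.min() < spec.min_separation_nm:
                    continue
            ok = pts
            break
        if ok is None:
            raise PlacementError(
                f"could not place fibril {len(placed) + 1}/{pop.count} "
                f"({cls}) after {max_attempts} attempts; "
                "reduce count or enlarge the field"
            )
        samples, arc = arc_resample(ok, ARC_STEP_NM)
        corr = _corrugation_profile(
            rng,
            arc,
            _truncated_normal(
                rng,
                pop.corrugation_amplitude_mean_nm,
                pop.corrugation_amplitude_sd_nm,
                max(0.0, pop.corrugation_amplitude_mean_nm - 2 * pop.corrugation_amplitude_sd_nm),
                pop.corrugation_amplitude_mean_nm + 2 * pop.corrugation_amplitude_sd_nm,
            )
            if pop.corrugation_amplitude_mean_nm > 0
            else 0.0,
            pop.corrugation_wavelength_nm,
        )
        floor = max(MIN_RENDER_DIAMETER_NM, min(4.0, 0.6 * dia))
        diam = np.clip(dia + corr, floor, None)
        placed.append(
            _RenderedFibril(
                id=f"{prefix}{len(placed)}",
                cls=cls,
                samples=samples,
                arc=arc,
                diam=diam,
                support=np.zeros(len(arc)),
                base_diameter=dia,
            )
        )
    return placed


def _place_stacked_secondaries(
    rng,
    pop: FibrilPopulation,
    primaries: list[_RenderedFibril],
    max_attempts: int = 500,
) -> list[_RenderedFibril]:
    """Stack secondary fibrils colinearly on sub-intervals of primary hosts."""
    if pop.count > 0 and not primaries:
        raise PlacementError("stacked secondary fibrils require primary fibrils")
    placed: list[_RenderedFibril] = []
    end_margin = 30.0
    for i in range(pop.count):
        dia = _truncated_normal(
            rng,
            pop.diameter_mean_nm,
            pop.diameter_sd_nm,
            max(3.0, pop.diameter_mean_nm - 3 * pop.diameter_sd_nm),
            pop.diameter_mean_nm + 3 * pop.diameter_sd_nm,
        )
        length = _truncated_normal(
            rng,
            pop.length_mean_nm,
            pop.length_sd_nm,
            max(60.0, pop.length_mean_nm - 3 * pop.length_sd_nm),
            pop.length_mean_nm + 3 * pop.length_sd_nm,
        )
        ok = None
        for _ in range(max_attempts):
            host = primaries[int(rng.integers(len(primaries)))]
            room = host.length_nm - 2 * end_margin - length
            if room <= 0:
                continue
            a0 = end_margin + rng.uniform(0.0, room)
            # one rider per host interval; keep riders apart
            span = (a0 - 40.0, a0 + length + 40.0)
            if any(
                s0 < span[1] and span[0] < s1 for (s0, s1) in host.rider_spans
            ):
                continue
            ok = (host, a0)
            break
        if ok is None:
            raise PlacementError(
                f"could not place stacked secondary {len(placed) + 1}/{pop.count}; "
                "hosts too short or too crowded"
            )
        host, a0 = ok
        sel = (host.arc >= a0) & (host.arc <= a0 + length)
        samples = host.samples[sel]
        arc = host.arc[sel] - host.arc[sel][0]
        support = host.diam[sel].copy()  # rider sits on the host apex
        corr = _corrugation_profile(
            rng,
            arc,
            _truncated_normal(
                rng,
                pop.corrugation_amplitude_mean_nm,
                pop.corrugation_amplitude_sd_nm,
                max(0.0, pop.corrugation_amplitude_mean_nm - 2 * pop.corrugation_amplitude_sd_nm),
                pop.corrugation_amplitude_mean_nm + 2 * pop.corrugation_amplitude_sd_nm,
            )
            if pop.corrugation_amplitude_mean_nm > 0
            else 0.0,
            pop.corrugation_wavelength_nm,
        )
        floor = max(MIN_RENDER_DIAMETER_NM, min(4.0, 0.6 * dia))
        diam = np.clip(dia + corr, floor, None)
        host.rider_spans.append((a0, a0 + length))
        placed.append(
            _RenderedFibril(
                id=f"s{len(placed)}",
                cls="secondary_fibril",
                samples=samples,
                arc=arc,
                diam=diam,
                support=support,
                base_diameter=dia,
                host_id=host.id,
                host_arc0=a0,
            )
        )
    return placed


# --------------------------------------------------------------------------
# oligomer placement


def sample_site_classes(
    rng, n: int, p_edge: float, p_backbone: float, p_substrate: float
) -> list[str]:
    """Draw adsorption-site classes i.i.d. from the configured probabilities."""
    classes = np.array(["edge", "backbone", "substrate"])
    idx = rng.choice(3, size=n, p=[p_edge, p_backbone, p_substrate])
    return list(classes[idx])


def _host_weights(pop: OligomerPopulation, n_hosts: int) -> np.ndarray:
    w = np.ones(n_hosts)
    if pop.superspreader_host_factor is not None and n_hosts > 0:
        w[0] = float(pop.superspreader_host_factor)
    return w / w.sum()


def place_oligomers(
    spec: SceneSpec,
    fibrils: Sequence[_RenderedFibril],
    rng: np.random.Generator,
    max_attempts: int = 400,
) -> list[GroundTruthObject]:
    """Assign oligomer placements (edge / backbone / substrate).

    Edge oligomers sit within :data:`EDGE_PLACEMENT_MAX_NM` of a backbone
    endpoint (at most one per endpoint); backbone oligomers occupy arc slots
    separated by 20-100 nm drawn from the observed inter-oligomer spacing
    range; substrate oligomers keep clear of every fibril footprint.
    """
    pop = spec.oligomers
    if pop.count == 0:
        return []
    hosts = [f for f in fibrils if f.cls == "primary_fibril"]
    if (pop.p_edge + pop.p_backbone) > 0 and not hosts:
        raise PlacementError("on-fibril placement requested but no fibrils present")

    site_classes = sample_site_classes(
        rng, pop.count, pop.p_edge, pop.p_backbone, pop.p_substrate
    )
    weights = _host_weights(pop, len(hosts))

    # per-host occupancy bookkeeping
    edge_used: dict[str, set] = {h.id: set() for h in hosts}
    slots: dict[str, list[float]] = {}
    for h in hosts:
        slot_list = []
        s = BACKBONE_MARGIN_NM + rng.uniform(0.0, 20.0)
        while s < h.length_nm - BACKBONE_MARGIN_NM:
            if not any(s0 - 16.0 < s < s1 + 16.0 for (s0, s1) in h.rider_spans):
                slot_list.append(s)
            s += rng.uniform(20.0, 100.0)
        slots[h.id] = slot_list

    fx, fy = spec.field_nm
    placements: list[GroundTruthObject] = []
    substrate_xy: list[np.ndarray] = []
    substrate_r: list[float] = []
    fib_tree = (
        cKDTree(np.concatenate([f.samples for f in fibrils])) if fibrils else None
    )
    fib_halfwidth = (
        max(float(f.diam.max()) for f in fibrils) / 2.0 if fibrils else 0.0
    )

    for i, site in enumerate(site_classes):
        dia = _truncated_normal(
            rng,
            pop.diameter_mean_nm,
            pop.diameter_sd_nm,
            max(3.0, pop.diameter_mean_nm - 3 * pop.diameter_sd_nm),
            pop.diameter_mean_nm + 3 * pop.diameter_sd_nm,
        )
        oid = f"o{i}"
        if site == "substrate":
            pos = None
            for _ in range(max_attempts):
                margin = dia / 2 + 6.0
                cand = np.array(
                    [rng.uniform(margin, fx - margin), rng.uniform(margin, fy - margin)]
                )
                if fib_tree is not None:
                    d, _ = fib_tree.query(cand)
                    if d < fib_halfwidth + dia / 2 + 10.0:
                        continue
                if substrate_xy:
                    dd = np.linalg.norm(np.asarray(substrate_xy) - cand, axis=1)
                    rr = np.asarray(substrate_r) + dia / 2 + 12.0
                    if np.any(dd < rr):
                        continue
                pos = cand
                break
            if pos is None:
                raise PlacementError(
                    f"could not place substrate oligomer {oid}; field too crowded"
                )
            substrate_xy.append(pos)
            substrate_r.append(dia / 2)
            placements.append(
                GroundTruthObject(
                    id=oid,
                    cls="oligomer",
                    true_diameter_nm=dia,
                    centroid_nm=(float(pos[0]), float(pos[1])),
                    placement="substrate",
                )
            )
            continue

        placed = False
        for _ in range(max_attempts):
            h = hosts[int(rng.choice(len(hosts), p=weights))]
            if site == "edge":
                free_ends = [e for e in (0, 1) if e not in edge_used[h.id]]
                if not free_ends:
                    continue
                end = free_ends[int(rng.integers(len(free_ends)))]
                off = rng.uniform(2.0, EDGE_PLACEMENT_MAX_NM)
                arc_pos = off if end == 0 else h.length_nm - off
                edge_used[h.id].add(end)
            else:
                if not slots[h.id]:
                    continue
                k = int(rng.integers(len(slots[h.id])))
                arc_pos = slots[h.id].pop(k)
            j = int(np.searchsorted(h.arc, arc_pos))
            j = min(j, len(h.arc) - 1)
            xy = h.samples[j]
            placements.append(
                GroundTruthObject(
                    id=oid,
                    cls="oligomer",
                    true_diameter_nm=dia,
                    centroid_nm=(float(xy[0]), float(xy[1])),
                    placement=site,
                    host_id=h.id,
                    host_arc_nm=float(arc_pos),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {site} oligomer {oid}: all host sites occupied"
            )
    return placements


# --------------------------------------------------------------------------
# rasterisation


def _raster_fibril(heights: np.ndarray, f: _RenderedFibril, px: float) -> None:
    """Max-composite one fibril ridge into the height grid (in place)."""
    rmax = float(f.diam.max()) / 2.0
    lo = np.floor((f.samples.min(axis=0) - rmax) / px).astype(int)
    hi = np.ceil((f.samples.max(axis=0) + rmax) / px).astype(int)
    lo = np.maximum(lo, 0)
    hi_c = min(hi[0] + 1, heights.shape[1])
    hi_r = min(hi[1] + 1, heights.shape[0])
    if hi_c <= lo[0] or hi_r <= lo[1]:
        return
    cols = np.arange(lo[0], hi_c)
    rows = np.arange(lo[1], hi_r)
    xx, yy = np.meshgrid(cols * px, rows * px)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    tree = cKDTree(f.samples)
    dist, idx = tree.query(pts, k=1, distance_upper_bound=rmax + ARC_STEP_NM)
    valid = np.isfinite(dist)
    if not valid.any():
        return
    dist = dist[valid]
    idx = idx[valid]
    pv = pts[valid]
    half = f.diam[idx] / 2.0
    inside = dist <= half
    # flat end caps: drop contributions axially beyond the backbone endpoints
    n_last = len(f.samples) - 1
    for end_idx, tangent_sign in ((0, -1.0), (n_last, 1.0)):
        at_end = idx == end_idx
        if not at_end.any():
            continue
        nb = max(1, min(3, n_last))
        t = f.samples[end_idx] - f.samples[end_idx - int(tangent_sign) * nb]
        t = t / (np.linalg.norm(t) + 1e-12)
        axial = (pv[at_end] - f.samples[end_idx]) @ t
        cut = inside[at_end]
        cut &= axial <= ARC_STEP_NM * 0.75
        inside[at_end] = cut
    if not inside.any():
        return
    r = dist[inside]
    hh = half[inside]
    z = f.support[idx[inside]] + hh + np.sqrt(np.clip(hh**2 - r**2, 0.0, None))
    flat_rows = (pv[inside][:, 1] / px).round().astype(int)
    flat_cols = (pv[inside][:, 0] / px).round().astype(int)
    flat = flat_rows * heights.shape[1] + flat_cols
    np.maximum.at(heights.ravel(), flat, z)


def _raster_oligomer(
    heights: np.ndarray, center: np.ndarray, dia: float, support: float, px: float
) -> None:
    r0 = dia / 2.0
    lo = np.floor((center - r0) / px).astype(int)
    hi = np.ceil((center + r0) / px).astype(int)
    lo = np.maximum(lo, 0)
    hi_c = min(hi[0] + 1, heights.shape[1])
    hi_r = min(hi[1] + 1, heights.shape[0])
    if hi_c <= lo[0] or hi_r <= lo[1]:
        return
    cols = np.arange(lo[0], hi_c)
    rows = np.arange(lo[1], hi_r)
    xx, yy = np.meshgrid(cols * px, rows * px)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    mask = r2 <= r0**2
    z = support + r0 + np.sqrt(np.clip(r0**2 - r2, 0.0, None))
    patch = heights[lo[1] : hi_r, lo[0] : hi_c]
    np.copyto(patch, np.maximum(patch, z), where=mask)


def render_scene(spec: SceneSpec) -> tuple[HeightMap, GroundTruth]:
    """Render the ideal (pre-tip, artifact-free) surface plus ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    rows, cols = spec.grid_shape
    heights = np.zeros((rows, cols))

    # sequential placement can dead-end in crowded scenes; restart the whole
    # arrangement a few times before reporting the shortfall
    last_err: PlacementError | None = None
    for _restart in range(8):
        try:
            primaries = _place_fibril_population(
                rng, spec.primary_fibrils, spec, [], "p", "primary_fibril"
            )
            if spec.secondary_fibrils.stacked_on_primary:
                secondaries = _place_stacked_secondaries(
                    rng, spec.secondary_fibrils, primaries
                )
            else:
                secondaries = _place_fibril_population(
                    rng, spec.secondary_fibrils, spec, primaries, "s",
                    "secondary_fibril",
                )
            fibrils = primaries + secondaries
            oligomers = place_oligomers(spec, fibrils, rng)
            break
        except PlacementError as err:
            last_err = err
    else:
        raise last_err

    px = spec.pixel_size_nm
    for f in fibrils:
        _raster_fibril(heights, f, px)
    host_by_id = {f.id: f for f in fibrils}
    for o in oligomers:
        support = 0.0
        if o.placement != "substrate":
            h = host_by_id[o.host_id]
            j = min(int(np.searchsorted(h.arc, o.host_arc_nm)), len(h.arc) - 1)
            support = float(h.diam[j])
        _raster_oligomer(heights, np.asarray(o.centroid_nm), o.true_diameter_nm, support, px)

    objects = [
        GroundTruthObject(
            id=f.id,
            cls=f.cls,
            true_diameter_nm=f.base_diameter,
            true_length_nm=f.length_nm,
            backbone_nm=f.samples[:: max(1, int(4 // ARC_STEP_NM))].copy(),
            host_id=f.host_id,
            true_rq_nm=f.true_rq(),
        )
        for f in fibrils
    ] + oligomers
    hm = HeightMap(
        heights=heights,
        pixel_size_nm=px,
        time_min=spec.time_min,
        frame_id=spec.frame_id,
    )
    truth = GroundTruth(
        objects=objects, frame_id=spec.frame_id, time_min=spec.time_min, seed=spec.seed
    )
    return hm, truth


# --------------------------------------------------------------------------
# tip convolution and scan artifacts


def tip_structure(tip: TipModel, pixel_size_nm: float, depth_nm: float) -> np.ndarray:
    """Structuring-function array s(dx, dy) <= 0 covering the given depth."""
    r_nm = max(tip.support_radius(max(depth_nm, 1e-3)), pixel_size_nm)
    r_px = max(int(math.ceil(r_nm / pixel_size_nm)), 1)
    ax = np.arange(-r_px, r_px + 1) * pixel_size_nm
    rho = np.hypot(*np.meshgrid(ax, ax))
    return tip.profile(rho)


def apply_tip(hm: HeightMap, tip: TipModel) -> HeightMap:
    """Tip-sample dilation: g(p) = max_q [f(q) + s(p - q)].

    Pointwise g >= f; apex heights of isolated convex bumps are preserved,
    which is why all sizing downstream relies on heights rather than widths.
    """
    depth = float(hm.heights.max() - hm.heights.min()) + 1.0
    s = tip_structure(tip, hm.pixel_size_nm, depth)
    dilated = ndimage.grey_dilation(hm.heights, structure=s, mode="nearest")
    return hm.copy_with(dilated)


def erode_tip(hm: HeightMap, tip: TipModel) -> HeightMap:
    """Erosion by the same tip; used for certified surface reconstruction."""
    depth = float(hm.heights.max() - hm.heights.min()) + 1.0
    s = tip_structure(tip, hm.pixel_size_nm, depth)
    eroded = ndimage.grey_erosion(hm.heights, structure=s, mode="nearest")
    return hm.copy_with(eroded)


def add_scan_artifacts(
    hm: HeightMap, spec: SceneSpec, rng: np.random.Generator
) -> HeightMap:
    """Add per-scanline offsets, a tilt plane, substrate roughness and noise."""
    art = spec.artifacts
    rows, cols = hm.heights.shape
    px = hm.pixel_size_nm
    out = hm.heights.copy()
    if art.line_offset_sigma_nm > 0:
        out += rng.normal(0.0, art.line_offset_sigma_nm, rows)[:, None]
    tx, ty = art.tilt_nm_per_um
    if tx or ty:
        x_um = (np.arange(cols) * px)[None, :] / 1000.0
        y_um = (np.arange(rows) * px)[:, None] / 1000.0
        out = out + tx * x_um + ty * y_um
    if spec.substrate_sigma_nm > 0:
        rough = rng.normal(0.0, 1.0, (rows, cols))
        rough = ndimage.gaussian_filter(rough, 3.0, mode="reflect")
        sd = rough.std()
        if sd > 0:
            out += rough * (spec.substrate_sigma_nm / sd)
    if art.pixel_noise_sigma_nm > 0:
        out += rng.normal(0.0, art.pixel_noise_sigma_nm, (rows, cols))
    return hm.copy_with(out)


@dataclasses.dataclass
class SimulatedFrame:
    ideal: HeightMap
    topograph: HeightMap
    truth: GroundTruth


def simulate_frame(spec: SceneSpec) -> SimulatedFrame:
    """Render, tip-convolve and add artifacts; fully determined by spec.seed."""
    ideal, truth = render_scene(spec)
    dilated = apply_tip(ideal, spec.tip)
    art_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    topo = add_scan_artifacts(dilated, spec, art_rng)
    return SimulatedFrame(ideal=ideal, topograph=topo, truth=truth)
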
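import numpy as np
import pytest

from afmquant.io_formats import HeightMap
from afmquant.synthetic import (
    SceneSpec,
    _RenderedFibril,
    _raster_fibril,
    arc_resample,
)
from afmquant.trace import FibrilTrace


def ridge_heightmap(
    points_nm: np.ndarray,
    diameter_nm: float,
    shape_px: tuple[int, int],
    pixel_size_nm: float = 2.0,
    diam_profile: np.ndarray | None = None,
) -> HeightMap:
    """Ideal noise-free map containing one cylindrical ridge along a polyline."""
    samples, arc = arc_resample(np.asarray(points_nm, dtype=float), 1.0)
    diam = (
        np.full(len(arc), diameter_nm)
        if diam_profile is None
        else np.asarray(diam_profile, dtype=float)
    )
    fib = _RenderedFibril(
        id="r0",
        cls="primary_fibril",
        samples=samples,
        arc=arc,
        diam=diam,
        support=np.zeros(len(arc)),
        base_diameter=diameter_nm,
    )
    heights = np.zeros(shape_px)
    _raster_fibril(heights, fib, pixel_size_nm)
    return HeightMap(heights, pixel_size_nm)


def make_trace(
    length_nm: float = 400.0,
    diameter_nm: float = 8.0,
    apex: np.ndarray | None = None,
    step_nm: float = 1.0,
    trace_id: str = "t0",
    y_nm: float = 100.0,
    x0_nm: float = 50.0,
) -> FibrilTrace:
    """Straight synthetic trace along +x with a given apex profile."""
    n = int(round(length_nm / step_nm)) + 1
    arc = np.arange(n) * step_nm
    backbone = np.stack([x0_nm + arc, np.full(n, y_nm)], axis=1)
    apex_arr = (
        np.full(n, diameter_nm) if apex is None else np.asarray(apex, dtype=float)
    )
    assert len(apex_arr) == n
    return FibrilTrace(
        id=trace_id,
        backbone_nm=backbone,
        apex_heights_nm=apex_arr,
        arc_nm=arc,
        length_nm=float(arc[-1]),
        diameter_nm=diameter_nm,
        pixel_size_nm=2.0,
    )


def scene(seed: int = 1, **overrides) -> SceneSpec:
    """Small default-noise scene spec with keyword overrides."""
    cfg = {
        "field_nm": [1200, 1200],
        "pixel_size_nm": 2.0,
        "substrate_sigma_nm": 0.12,
        "primary_fibrils": {
            "count": 2,
            "diameter_mean_nm": 8.3,
            "diameter_sd_nm": 0.0,
            "length_mean_nm": 500.0,
            "length_sd_nm": 50.0,
        },
        "oligomers": {"count": 0},
        "artifacts": {
            "line_offset_sigma_nm": 0.8,
            "tilt_nm_per_um": [4.0, 6.0],
            "pixel_noise_sigma_nm": 0.25,
        },
    }
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return SceneSpec.from_dict(cfg, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
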
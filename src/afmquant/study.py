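"""Multi-frame studies driven by YAML fixture configs.

A fixture file holds a ``scenes:`` list; each entry is a SceneSpec mapping
plus ``name`` and ``replicates``.  Per-frame seeds are derived from the
study seed, the scene index and the replicate index, so one integer seed
reproduces the whole study bit-for-bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .benchmark import match_particles, match_traces
from .io_formats import read_yaml
from .pipeline import AnalyzeParams, FrameAnalysis, analyze_frame
from .synthetic import GroundTruth, SceneSpec, simulate_frame


@dataclasses.dataclass
class FrameResult:
    scene_name: str
    spec: SceneSpec
    analysis: FrameAnalysis
    truth: GroundTruth
    trace_map: dict[str, str]
    particle_map: dict[str, str]


def load_fixture(path, seed: int) -> list[tuple[str, SceneSpec]]:
    """Expand a fixture YAML into per-frame SceneSpecs with derived seeds."""
    cfg = read_yaml(path)
    scenes = cfg.get("scenes")
    if not scenes:
        raise ValueError(f"no scenes in {path}")
    out = []
    for si, sc in enumerate(scenes):
        sc = dict(sc)
        name = sc.pop("name", f"scene{si}")
        reps = int(sc.pop("replicates", 1))
        for rep in range(reps):
            child = np.random.SeedSequence([int(seed), si, rep])
            frame_seed = int(child.generate_state(1)[0])
            sc_frame = dict(sc)
            sc_frame["frame_id"] = f"{name}_{rep:02d}"
            out.append((name, SceneSpec.from_dict(sc_frame, seed=frame_seed)))
    return out


def run_scene(
    spec: SceneSpec, params: AnalyzeParams | None = None, scene_name: str = ""
) -> FrameResult:
    frame = simulate_frame(spec)
    analysis = analyze_frame(frame.topograph, params)
    return FrameResult(
        scene_name=scene_name or spec.frame_id,
        spec=spec,
        analysis=analysis,
        truth=frame.truth,
        trace_map=match_traces(analysis, frame.truth),
        particle_map=match_particles(analysis, frame.truth),
    )


def run_fixture(
    path, seed: int, params: AnalyzeParams | None = None,
    scene_filter: str | None = None,
) -> list[FrameResult]:
    results = []
    for name, spec in load_fixture(path, seed):
        if scene_filter is not None and name != scene_filter:
            continue
        results.append(run_scene(spec, params, scene_name=name))
    return results


def records_frame(results: list[FrameResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.extend(r.analysis.records())
    from .io_formats import MEASUREMENT_COLUMNS

    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
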
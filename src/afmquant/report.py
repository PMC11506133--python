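"""Population statistics and time-course summaries of measurement tables.

Means are reported with the population standard deviation (divide by n),
matching the "mean ± SD" convention of the summaries this reproduces.
Time always comes from frame metadata, never from filenames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTHS = {"diameter_nm": 0.5, "length_nm": 100.0, "rq_nm": 0.25}

#: default phase boundaries in minutes (embryonic / growth / endpoint)
PHASE_EDGES_MIN = (10.0, 120.0, 240.0)


@dataclasses.dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    bin_edges: list[float]
    bin_counts: list[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GrowthCurve:
    metric: str
    times_min: list[float]
    means: list[float]
    sds: list[float]
    ns: list[int]
    increasing: bool  # monotonicity flag — computed, never asserted

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_population(
    values, bin_width: float = 0.5
) -> SummaryStats:
    """Mean, population SD and fixed-width histogram of a value population."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return SummaryStats(n=0, mean=float("nan"), sd=float("nan"),
                            bin_edges=[], bin_counts=[])
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return SummaryStats(
        n=int(len(vals)),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        bin_edges=[float(e) for e in edges],
        bin_counts=[int(c) for c in counts],
    )


def growth_curve(
    points: list[tuple[float, SummaryStats]], metric: str
) -> GrowthCurve:
    """Ordered (time, mean, SD, n) table from per-timepoint summaries.

    Duplicate time points within a trial are an error; at least 2 time
    points are required.  The monotonicity flag is computed, not asserted.
    """
    times = [float(t) for t, _ in points]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time_min within a trial")
    if len(times) < 2:
        raise ValueError("growth curve requires at least 2 time points")
    order = np.argsort(times)
    means = [points[i][1].mean for i in order]
    return GrowthCurve(
        metric=metric,
        times_min=[times[i] for i in order],
        means=means,
        sds=[points[i][1].sd for i in order],
        ns=[points[i][1].n for i in order],
        increasing=bool(np.all(np.diff(means) > 0)),
    )


def growth_curves(
    df: pd.DataFrame,
    metric: str,
    object_class: str,
    trial_col: str | None = None,
    bin_width: float | None = None,
) -> list[GrowthCurve]:
    """Growth curves from a measurement table, one per trial.

    Records are pooled per (trial, time) into a population summary first;
    trials are kept separate, never pooled together.
    """
    bw = bin_width or DEFAULT_BIN_WIDTHS.get(metric, 0.5)
    sel = df[(df["class"] == object_class) & df[metric].notna()]
    groups = [(None, sel)] if trial_col is None else list(sel.groupby(trial_col))
    curves = []
    for trial, g in groups:
        points = [
            (float(t), summarize_population(v.to_numpy(dtype=float), bin_width=bw))
            for t, v in g.groupby("time_min")[metric]
        ]
        name = metric if trial is None else f"{metric}[{trial}]"
        curves.append(growth_curve(points, name))
    return curves


def summarize_study(df: pd.DataFrame) -> dict:
    """Per-(time, class) population statistics plus growth-curve tables."""
    out: dict = {"populations": {}, "growth_curves": {}}
    for (time_min, cls), g in df.groupby(["time_min", "class"], dropna=False):
        key = f"t={time_min}|{cls}"
        entry = {}
        for metric, bw in DEFAULT_BIN_WIDTHS.items():
            vals = g[metric].dropna()
            if len(vals):
                entry[metric] = summarize_population(vals, bin_width=bw).to_dict()
        out["populations"][key] = {"n_records": int(len(g)), **entry}
    for cls, metric in [("oligomer", "diameter_nm"), ("secondary_fibril", "length_nm")]:
        sub = df[(df["class"] == cls) & df["time_min"].notna() & df[metric].notna()]
        if sub["time_min"].nunique() >= 2:
            out["growth_curves"][f"{cls}:{metric}"] = [
                c.to_dict() for c in growth_curves(sub, metric, cls)
            ]
    return out
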
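"""Growth-trajectory fitting and per-compartment elongation rates.

Growth rates (µm/h, tips/h, ...) are ordinary-least-squares slopes of a
metric's time course fitted per cell and then aggregated across cells
(mean ± s.d. and s.e.m.), mirroring biological replication rather than a
pooled regression.  Compartment elongation rates are measured over a fixed
interval as path-length increase of individual terminal compartments,
optionally scaled by filament diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometrics
from .swc import ROOT_MARKER, TimeSeries, TracedTree

__all__ = [
    "GrowthRateEstimate",
    "ElongationRate",
    "metric_timecourse",
    "fit_growth_rate",
    "compartment_elongation",
]


@dataclass
class GrowthRateEstimate:
    """Per-cell OLS slopes of one metric and their group statistics."""

    metric: str
    per_cell_slopes: list[float]
    group_mean: float
    group_sd: float
    group_sem: float
    n_cells: int


@dataclass
class ElongationRate:
    """Elongation of one terminal rhizoid compartment over an interval."""

    compartment_id: int
    rate: float  # µm/min
    interval: float  # minutes
    diameter: float  # µm
    scaled_rate: float  # 1/min, rate / diameter


def metric_timecourse(series: TimeSeries, metric: str) -> list[tuple[float, float]]:
    """One (time, value) row per frame for a named morphometric."""
    if metric not in morphometrics.MorphometryRecord.field_names():
        raise ValueError(f"unknown metric {metric!r}")
    out = []
    for t, tree in series.frames:
        rec = morphometrics.summarize(tree)
        out.append((t, float(getattr(rec, metric))))
    return out


def fit_growth_rate(cells: list[TimeSeries], metric: str) -> GrowthRateEstimate:
    """Group growth rate of a metric: per-cell OLS slope, then mean ± s.d./s.e.m.

    Cells with fewer than 3 frames are skipped with a warning.
    """
    slopes: list[float] = []
    for i, series in enumerate(cells):
        if len(series) < 3:
            warnings.warn(
                f"cell {series.cell_id!r} has {len(series)} frames (<3); skipped",
                stacklevel=2,
            )
            continue
        tc = metric_timecourse(series, metric)
        t = np.array([a for a, _ in tc])
        v = np.array([b for _, b in tc])
        ok = np.isfinite(v)
        if ok.sum() < 3:
            warnings.warn(
                f"cell {series.cell_id!r} has <3 finite {metric} values; skipped",
                stacklevel=2,
            )
            continue
        slope = np.polyfit(t[ok], v[ok], 1)[0]
        slopes.append(float(slope))
    if not slopes:
        raise ValueError("no cell had enough frames to fit a slope")
    arr = np.array(slopes)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GrowthRateEstimate(
        metric=metric,
        per_cell_slopes=slopes,
        group_mean=float(arr.mean()),
        group_sd=sd,
        group_sem=sd / np.sqrt(arr.size),
        n_cells=int(arr.size),
    )


def _subtree_path_length(tree: TracedTree, node_id: int) -> tuple[float, list[int]]:
    """Total path length of, and node ids in, the subtree below a node."""
    kids = tree.children_map()
    total = 0.0
    members = [node_id]
    stack = [node_id]
    while stack:
        cur = stack.pop()
        here = tree.coords[tree.row_of(cur)]
        for c in kids[cur]:
            total += float(np.linalg.norm(tree.coords[tree.row_of(c)] - here))
            members.append(c)
            stack.append(c)
    return total, members


def compartment_elongation(
    series: TimeSeries, interval: float = 30.0, time_tol: float = 1e-6
) -> list[ElongationRate]:
    """Elongation rates of terminal compartments over a fixed interval.

    For every frame pair separated by ``interval`` minutes and every tip of
    the earlier frame that has not branched by the later frame, the rate is
    the path length grown downstream of that tip divided by the interval
    (path length, not Euclidean displacement, because filaments curve).
    The compartment diameter is twice the mean radius of its nodes;
    ``scaled_rate`` divides the rate by it.  Requires stable node identity.
    """
    if not series.id_stability:
        raise ValueError("compartment elongation requires stable node identity")
    interval_h = interval / 60.0
    rates: list[ElongationRate] = []
    for i, (t0, tree0) in enumerate(series.frames):
        later = None
        for t1, tree1 in series.frames[i + 1 :]:
            if abs((t1 - t0) - interval_h) <= time_tol:
                later = tree1
                break
        if later is None:
            continue
        kids0 = tree0.children_map()
        ids1 = {int(x) for x in later.ids}
        kids1 = later.children_map()
        root0 = tree0.root_id
        for nid, ch in kids0.items():
            if ch or nid == root0:
                continue  # only tips of the earlier frame
            if nid not in ids1:
                continue
            if len(kids1[nid]) >= 2:
                continue  # tip branched during the interval: not one compartment
            grown, members = _subtree_path_length(later, nid)
            radii = [float(later.radii[later.row_of(m)]) for m in members]
            diameter = 2.0 * float(np.mean(radii)) if radii else 0.0
            rate = grown / interval
            rates.append(
                ElongationRate(
                    compartment_id=int(nid),
                    rate=rate,
                    interval=interval,
                    diameter=diameter,
                    scaled_rate=rate / diameter if diameter > 0 else float("nan"),
                )
            )
    return rates
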
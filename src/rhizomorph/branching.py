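"""Branch-event detection and apical/lateral classification.

Between consecutive frames of a time series, any node that has two or more
children in the later frame but fewer than two (or did not exist) in the
earlier frame marks a new branch event.  Each event is classified:

* **apical** — the branch formed at the rhizoid tip, parallel to the
  established rhizoidal axis: path distance from the insertion point to the
  tip of its parent filament (at the earlier frame) <= ``d_tip`` AND the
  angle between the new branch's initial direction and the parent
  filament's local axis <= ``theta_par``;
* **lateral** — anything else (a branch inserted distal to the tip,
  establishing a new rhizoidal axis).

The two thresholds are the only free parameters and are exposed
everywhere; the defaults are ``d_tip = 1 µm`` and ``theta_par = 30°``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphometrics import ANGLE_MIN_OFFSET, _daughter_direction
from .swc import ROOT_MARKER, TimeSeries, TracedTree

__all__ = [
    "BranchEvent",
    "MatchingError",
    "D_TIP_DEFAULT",
    "THETA_PAR_DEFAULT",
    "detect_branch_events",
    "classify_branch",
    "branch_ratio",
    "match_frames",
]

D_TIP_DEFAULT = 1.0  # µm
THETA_PAR_DEFAULT = 30.0  # degrees
AXIS_WINDOW = 2.0  # µm of upstream path defining the parent filament's local axis

APICAL = "apical"
LATERAL = "lateral"


class MatchingError(Exception):
    """Frames could not be matched node-for-node."""


@dataclass
class BranchEvent:
    """A newly appeared branch, with its insertion geometry."""

    time: float
    parent_node_id: int
    distance_to_tip: float
    axis_angle: float
    branch_class: str | None = None


def classify_branch(
    event: BranchEvent,
    d_tip: float = D_TIP_DEFAULT,
    theta_par: float = THETA_PAR_DEFAULT,
) -> str:
    """Apical iff the branch is both at the tip and parallel to the axis."""
    if event.distance_to_tip <= d_tip and event.axis_angle <= theta_par:
        return APICAL
    return LATERAL


def branch_ratio(events) -> tuple[float, float, dict[str, int]]:
    """(lateral_fraction, apical_fraction, counts); NaN fractions if empty."""
    counts = {LATERAL: 0, APICAL: 0}
    for ev in events:
        counts[ev.branch_class] += 1
    n = counts[LATERAL] + counts[APICAL]
    if n == 0:
        return float("nan"), float("nan"), counts
    return counts[LATERAL] / n, counts[APICAL] / n, counts


def match_frames(earlier: TracedTree, later: TracedTree, tol: float = 1.0) -> dict[int, int]:
    """Match earlier-frame nodes to later-frame nodes by position.

    Greedy nearest-neighbour within ``tol`` µm.  Raises
    :class:`MatchingError` when a match is ambiguous (two earlier nodes
    claim the same later node, or two later nodes lie within ``tol`` of one
    earlier node) rather than guessing.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(later.coords)
    mapping: dict[int, int] = {}
    claimed: dict[int, int] = {}
    for r, nid in enumerate(earlier.ids):
        hits = tree.query_ball_point(earlier.coords[r], tol)
        if len(hits) > 1:
            raise MatchingError(
                f"node {int(nid)}: {len(hits)} later-frame candidates within {tol} µm"
            )
        if not hits:
            continue
        target = int(later.ids[hits[0]])
        if target in claimed:
            raise MatchingError(
                f"later-frame node {target} claimed by nodes {claimed[target]} and {int(nid)}"
            )
        claimed[target] = int(nid)
        mapping[int(nid)] = target
    return mapping


def _contains_old(tree: TracedTree, old_ids: set[int]) -> dict[int, bool]:
    """For every node of ``tree``: does its subtree contain an old node?"""
    kids = tree.children_map()
    result: dict[int, bool] = {}
    # iterative post-order over the rooted tree
    stack: list[tuple[int, bool]] = [(tree.root_id, False)]
    while stack:
        nid, processed = stack.pop()
        if processed:
            result[nid] = (nid in old_ids) or any(result[c] for c in kids[nid])
        else:
            stack.append((nid, True))
            stack.extend((c, False) for c in kids[nid])
    return result


def _upstream_axis(tree: TracedTree, node_id: int, window: float = AXIS_WINDOW) -> np.ndarray | None:
    """Unit direction of the ``window`` µm of path upstream of a node."""
    here = tree.coords[tree.row_of(node_id)]
    cur = node_id
    acc = 0.0
    while True:
        pid = int(tree.parent_ids[tree.row_of(cur)])
        if pid == ROOT_MARKER:
            break
        step = float(
            np.linalg.norm(tree.coords[tree.row_of(cur)] - tree.coords[tree.row_of(pid)])
        )
        acc += step
        cur = pid
        if acc >= window:
            break
    v = here - tree.coords[tree.row_of(cur)]
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else None


def _distance_to_old_tip(
    tree: TracedTree, start_id: int, old_ids: set[int], contains_old: dict[int, bool]
) -> float:
    """Path distance from a node to the tip (as of the earlier frame) of the
    filament it sits on, walking downstream through pre-existing structure.

    At a pre-existing bifurcation the straightest continuation is followed.
    """
    kids = tree.children_map()
    dist = 0.0
    cur = start_id
    prev_dir: np.ndarray | None = None
    while True:
        nxt = [c for c in kids[cur] if contains_old[c]]
        if not nxt:
            return dist
        if len(nxt) == 1:
            choice = nxt[0]
        else:
            # follow the straightest continuation of the incoming direction
            if prev_dir is None:
                prev_dir = _upstream_axis(tree, cur) or np.array([1.0, 0.0, 0.0])
            best, best_cos = nxt[0], -2.0
            here = tree.coords[tree.row_of(cur)]
            for c in nxt:
                v = tree.coords[tree.row_of(c)] - here
                n = np.linalg.norm(v)
                if n < 1e-12:
                    continue
                cosang = float(np.dot(prev_dir, v / n))
                if cosang > best_cos:
                    best, best_cos = c, cosang
            choice = best
        here = tree.coords[tree.row_of(cur)]
        there = tree.coords[tree.row_of(choice)]
        seg = there - here
        n = np.linalg.norm(seg)
        dist += float(n)
        if n > 1e-12:
            prev_dir = seg / n
        cur = choice


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def detect_branch_events(
    series: TimeSeries,
    d_tip: float = D_TIP_DEFAULT,
    theta_par: float = THETA_PAR_DEFAULT,
    min_offset: float = ANGLE_MIN_OFFSET,
) -> list[BranchEvent]:
    """Detect and classify new branch events across a time series.

    Requires stable node identity (``series.id_stability``); otherwise
    frames are matched by nearest neighbour first (ambiguity aborts).
    Geometry is measured at the event's first appearance: the new branch's
    chord direction against the parent filament's local upstream axis, and
    the downstream path distance to where the filament's tip stood in the
    earlier frame.  When every daughter of a new branch point is new (a tip
    split), the branch direction is the bisector of the new daughters.
    """
    if len(series) < 2:
        return []
    events: list[BranchEvent] = []
    for (t0, tree0), (t1, tree1) in zip(series.frames, series.frames[1:]):
        if series.id_stability:
            mapping = {int(i): int(i) for i in tree0.ids}
        else:
            mapping = match_frames(tree0, tree1)
        old_ids = set(mapping.values())
        # child counts of the earlier frame, keyed by later-frame ids
        kids0: dict[int, int] = {}
        for pid in tree0.parent_ids:
            if pid != ROOT_MARKER and int(pid) in mapping:
                key = mapping[int(pid)]
                kids0[key] = kids0.get(key, 0) + 1
        kids1 = tree1.children_map()
        contains_old = _contains_old(tree1, old_ids)
        for nid, ch in kids1.items():
            if len(ch) < 2 or nid == tree1.root_id:
                continue
            if kids0.get(nid, 0) >= 2:
                continue  # already a branch point in the earlier frame
            # geometry at first appearance
            new_daughters = [c for c in ch if not contains_old[c]]
            continuations = [c for c in ch if contains_old[c]]
            axis = _upstream_axis(tree1, nid)
            dirs = [
                d
                for d in (
                    _daughter_direction(tree1, nid, c, min_offset=min_offset)
                    for c in (new_daughters if new_daughters else ch)
                )
                if d is not None
            ]
            if axis is None or not dirs:
                continue
            if continuations:
                branch_dir = dirs[0]
            else:
                # tip split: the daughters straddle the established axis
                bis = np.sum(dirs, axis=0)
                n = np.linalg.norm(bis)
                branch_dir = bis / n if n > 1e-12 else dirs[0]
            dist = _distance_to_old_tip(tree1, nid, old_ids, contains_old)
            ev = BranchEvent(
                time=t1,
                parent_node_id=int(nid),
                distance_to_tip=dist,
                axis_angle=_angle_between(branch_dir, axis),
            )
            ev.branch_class = classify_branch(ev, d_tip=d_tip, theta_par=theta_par)
            events.append(ev)
    return events
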
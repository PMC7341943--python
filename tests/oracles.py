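"""Naive brute-force reference implementations used as independent oracles.

These deliberately avoid the package's vectorised code paths: plain Python
loops over Node objects, shapely for hull areas.  They are only suitable
for small trees.
"""

from __future__ import annotations

import math

from rhizomorph.swc import ROOT_MARKER, THALLUS, TracedTree

_EPS = 1e-12


def _dist(a, b) -> float:
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def _by_id(tree: TracedTree) -> dict:
    return {n.id: n for n in tree.nodes}


def _children(tree: TracedTree) -> dict:
    ch = {n.id: [] for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != ROOT_MARKER:
            ch[n.parent_id].append(n.id)
    return ch


def naive_total_length(tree: TracedTree) -> float:
    nodes = _by_id(tree)
    total = 0.0
    for n in tree.nodes:
        if n.parent_id == ROOT_MARKER or n.structure_label == THALLUS:
            continue
        d = _dist(n, nodes[n.parent_id])
        if d > _EPS:
            total += d
    return total


def naive_tips_bifurcations(tree: TracedTree) -> tuple[int, int]:
    ch = _children(tree)
    root = next(n.id for n in tree.nodes if n.parent_id == ROOT_MARKER)
    tips = sum(1 for n in tree.nodes if n.id != root and not ch[n.id])
    bifs = sum(1 for n in tree.nodes if n.id != root and len(ch[n.id]) >= 2)
    return tips, bifs


def naive_rgu_ratio(tree: TracedTree) -> float:
    tips, _ = naive_tips_bifurcations(tree)
    length = naive_total_length(tree)
    if tips == 0:
        return 0.0 if length == 0 else float("nan")
    return length / tips


def naive_surface_area(tree: TracedTree, include_thallus: bool = False) -> float:
    nodes = _by_id(tree)
    total = 0.0
    for n in tree.nodes:
        if n.parent_id == ROOT_MARKER or n.structure_label == THALLUS:
            continue
        p = nodes[n.parent_id]
        L = _dist(n, p)
        if L <= _EPS:
            continue
        slant = math.sqrt(L**2 + (p.radius - n.radius) ** 2)
        total += math.pi * (p.radius + n.radius) * slant
    if include_thallus:
        root = next(n for n in tree.nodes if n.parent_id == ROOT_MARKER)
        total += 4.0 * math.pi * root.radius**2
    return total


def naive_max_euclidean(tree: TracedTree) -> float:
    root = next(n for n in tree.nodes if n.parent_id == ROOT_MARKER)
    return max(_dist(root, n) for n in tree.nodes)


def naive_cover_area(tree: TracedTree) -> float:
    from shapely.geometry import MultiPoint

    pts = {(n.x, n.y) for n in tree.nodes}
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint(list(pts)).convex_hull.area)


def naive_bifurcation_angles(tree: TracedTree, min_offset: float = 0.5) -> list[float]:
    nodes = _by_id(tree)
    ch = _children(tree)
    root = next(n.id for n in tree.nodes if n.parent_id == ROOT_MARKER)

    def direction(bp_id, daughter_id):
        origin = nodes[bp_id]
        cur, prev, acc = daughter_id, bp_id, 0.0
        while True:
            acc += _dist(nodes[cur], nodes[prev])
            if acc >= min_offset or len(ch[cur]) != 1:
                break
            prev, cur = cur, ch[cur][0]
        v = (
            nodes[cur].x - origin.x,
            nodes[cur].y - origin.y,
            nodes[cur].z - origin.z,
        )
        norm = math.sqrt(sum(c * c for c in v))
        if norm <= _EPS:
            return None
        return tuple(c / norm for c in v)

    angles = []
    for nid, kids in ch.items():
        if nid == root or len(kids) < 2:
            continue
        dirs = [d for d in (direction(nid, k) for k in kids) if d is not None]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                dot = max(-1.0, min(1.0, sum(a * b for a, b in zip(dirs[i], dirs[j]))))
                angles.append(math.degrees(math.acos(dot)))
    return angles
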
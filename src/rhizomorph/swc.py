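"""SWC reading/writing and the core traced-tree data model.

A traced rhizoid system is a rooted geometric tree: the thallus (cell body)
at the root, threadlike rhizoids emanating from it, optionally through an
apophysis (the basal swelling).  The interchange format is standard SWC:
seven whitespace-separated columns per node —

    id  type  x  y  z  radius  parent

with ``#`` comment lines.  Coordinates and radii are micrometres.  SWC type
codes have no fungal vocabulary, so they are mapped onto the chytrid cell
plan: 1 -> thallus, 5 -> apophysis, 3 -> rhizoid, anything else -> unknown
(measured as rhizoid).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "THALLUS",
    "APOPHYSIS",
    "RHIZOID",
    "UNKNOWN",
    "ROOT_MARKER",
    "Node",
    "TracedTree",
    "TimeSeries",
    "SWCError",
    "SWCParseError",
    "TreeStructureError",
    "read_swc",
    "write_swc",
    "read_series",
    "write_series",
    "project_xy",
]

THALLUS = "thallus"
APOPHYSIS = "apophysis"
RHIZOID = "rhizoid"
UNKNOWN = "unknown"

ROOT_MARKER = -1

# SWC type code <-> structure label (1 = soma in the neuron convention,
# reused for the thallus; 5 = fork point, reused for the apophysis).
_CODE_TO_LABEL = {1: THALLUS, 5: APOPHYSIS, 3: RHIZOID}
_LABEL_TO_CODE = {THALLUS: 1, APOPHYSIS: 5, RHIZOID: 3, UNKNOWN: 0}


class SWCError(Exception):
    """Base class for SWC I/O and structure errors."""


class SWCParseError(SWCError):
    """A line of an SWC file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TreeStructureError(SWCError):
    """The node table does not describe a single rooted tree."""


@dataclass(frozen=True)
class Node:
    """One traced point: position, radius and structural label."""

    id: int
    structure_label: str
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class TracedTree:
    """A validated rooted tree of traced nodes (one rhizoid system).

    Nodes are stored internally as flat arrays (ids, labels, coordinates,
    radii, parent ids) so that morphometric operations vectorise; the
    :class:`Node` view is materialised on demand.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node`, in any order.
    cell_id
        Free-text identifier of the cell.
    frame_time
        Acquisition time in hours, if this tree is a frame of a time series.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        cell_id: str = "cell",
        frame_time: float | None = None,
    ):
        nodes = list(nodes)
        if not nodes:
            raise TreeStructureError("a traced tree needs at least one node")
        ids = np.array([n.id for n in nodes], dtype=np.int64)
        labels = np.array([n.structure_label for n in nodes], dtype=object)
        coords = np.array([[n.x, n.y, n.z] for n in nodes], dtype=float)
        radii = np.array([n.radius for n in nodes], dtype=float)
        parents = np.array([n.parent_id for n in nodes], dtype=np.int64)
        self._init_from_arrays(ids, labels, coords, radii, parents, cell_id, frame_time)

    @classmethod
    def from_arrays(
        cls,
        ids: np.ndarray,
        labels: np.ndarray,
        coords: np.ndarray,
        radii: np.ndarray,
        parent_ids: np.ndarray,
        cell_id: str = "cell",
        frame_time: float | None = None,
    ) -> "TracedTree":
        """Build a tree directly from column arrays (copies them)."""
        self = object.__new__(cls)
        self._init_from_arrays(
            np.asarray(ids, dtype=np.int64).copy(),
            np.asarray(labels, dtype=object).copy(),
            np.asarray(coords, dtype=float).copy(),
            np.asarray(radii, dtype=float).copy(),
            np.asarray(parent_ids, dtype=np.int64).copy(),
            cell_id,
            frame_time,
        )
        return self

    def _init_from_arrays(self, ids, labels, coords, radii, parents, cell_id, frame_time):
        self.ids = ids
        self.labels = labels
        self.coords = coords
        self.radii = radii
        self.parent_ids = parents
        self.cell_id = cell_id
        self.frame_time = frame_time
        self._validate()
        self._children: dict[int, list[int]] | None = None

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        ids = self.ids
        if ids.size != np.unique(ids).size:
            raise TreeStructureError("duplicate node ids")
        if not np.all(np.isfinite(self.coords)):
            raise TreeStructureError("non-finite coordinates")
        if np.any(self.radii < 0):
            raise TreeStructureError("negative radius")
        self._row_of = {int(i): r for r, i in enumerate(ids)}
        roots = np.flatnonzero(self.parent_ids == ROOT_MARKER)
        if roots.size != 1:
            raise TreeStructureError(
                f"expected exactly one root (parent {ROOT_MARKER}), found {roots.size}"
            )
        self._root_row = int(roots[0])
        for pid in self.parent_ids:
            if pid != ROOT_MARKER and int(pid) not in self._row_of:
                raise TreeStructureError(f"dangling parent reference: {int(pid)}")
        # connectivity / acyclicity: BFS from the root must reach every node
        kids: dict[int, list[int]] = {}
        for row, pid in enumerate(self.parent_ids):
            if pid != ROOT_MARKER:
                kids.setdefault(self._row_of[int(pid)], []).append(row)
        seen = np.zeros(ids.size, dtype=bool)
        stack = [self._root_row]
        seen[self._root_row] = True
        while stack:
            r = stack.pop()
            for c in kids.get(r, ()):
                seen[c] = True
                stack.append(c)
        if not seen.all():
            raise TreeStructureError("graph is not a single connected rooted tree (cycle or island)")

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return int(self.ids.size)

    @property
    def n_nodes(self) -> int:
        return len(self)

    @property
    def root_id(self) -> int:
        return int(self.ids[self._root_row])

    @property
    def root_position(self) -> np.ndarray:
        return self.coords[self._root_row]

    def row_of(self, node_id: int) -> int:
        return self._row_of[int(node_id)]

    def node(self, node_id: int) -> Node:
        r = self.row_of(node_id)
        return Node(
            id=int(self.ids[r]),
            structure_label=str(self.labels[r]),
            x=float(self.coords[r, 0]),
            y=float(self.coords[r, 1]),
            z=float(self.coords[r, 2]),
            radius=float(self.radii[r]),
            parent_id=int(self.parent_ids[r]),
        )

    @property
    def nodes(self) -> list[Node]:
        return [self.node(int(i)) for i in self.ids]

    def children_map(self) -> dict[int, list[int]]:
        """id -> list of child ids (cached)."""
        if self._children is None:
            m: dict[int, list[int]] = {int(i): [] for i in self.ids}
            for r, pid in enumerate(self.parent_ids):
                if pid != ROOT_MARKER:
                    m[int(pid)].append(int(self.ids[r]))
            self._children = m
        return self._children

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(parent_rows, child_rows) for every parent-child edge."""
        child_rows = np.flatnonzero(self.parent_ids != ROOT_MARKER)
        parent_rows = np.array(
            [self._row_of[int(p)] for p in self.parent_ids[child_rows]], dtype=np.int64
        )
        return parent_rows, child_rows

    def edge_lengths(self) -> np.ndarray:
        p, c = self.edges()
        return np.linalg.norm(self.coords[c] - self.coords[p], axis=1)

    def node_table(self) -> "np.ndarray":
        """Sorted-by-id structured view used for equality checks."""
        order = np.argsort(self.ids)
        return (
            self.ids[order],
            self.labels[order],
            self.coords[order],
            self.radii[order],
            self.parent_ids[order],
        )

    def topological_rows(self) -> list[int]:
        """Row indices in parent-before-child (DFS pre-)order."""
        kids: dict[int, list[int]] = {}
        for r, pid in enumerate(self.parent_ids):
            if pid != ROOT_MARKER:
                kids.setdefault(self._row_of[int(pid)], []).append(r)
        order: list[int] = []
        stack = [self._root_row]
        while stack:
            r = stack.pop()
            order.append(r)
            stack.extend(reversed(kids.get(r, ())))
        return order


@dataclass
class TimeSeries:
    """Timestamped sequence of :class:`TracedTree` snapshots of one cell.

    ``id_stability`` asserts that node ids refer to the same physical point
    across frames (guaranteed for simulator output).
    """

    frames: list[tuple[float, TracedTree]]
    id_stability: bool = True
    cell_id: str = "cell"

    def __post_init__(self):
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.frames]

    @property
    def trees(self) -> list[TracedTree]:
        return [tr for _, tr in self.frames]


# -- file I/O ---------------------------------------------------------------


def read_swc(path: str | Path, cell_id: str | None = None) -> TracedTree:
    """Parse an SWC file into a validated :class:`TracedTree`.

    Node lines may appear in any order (two-pass parse).  A header comment
    of the form ``# frame_time_h: <hours>`` is honoured.
    """
    path = Path(path)
    frame_time = None
    nodes: list[Node] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*frame_time_h:\s*([-+0-9.eE]+)", line)
                if m:
                    frame_time = float(m.group(1))
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"expected 7 fields, got {len(fields)}", line_number=lineno
                )
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), line_number=lineno) from None
            if nid <= 0:
                raise SWCParseError(f"node id must be positive, got {nid}", line_number=lineno)
            nodes.append(
                Node(
                    id=nid,
                    structure_label=_CODE_TO_LABEL.get(code, UNKNOWN),
                    x=x,
                    y=y,
                    z=z,
                    radius=radius,
                    parent_id=parent,
                )
            )
    return TracedTree(nodes, cell_id=cell_id or path.stem, frame_time=frame_time)


def write_swc(tree: TracedTree, path: str | Path) -> None:
    """Write standard 7-column SWC, parents before children.

    The header records the unit convention and, when known, the frame time.
    """
    path = Path(path)
    lines = ["# units: micrometres"]
    if tree.frame_time is not None:
        lines.append(f"# frame_time_h: {tree.frame_time:g}")
    lines.append(f"# cell_id: {tree.cell_id}")
    lines.append("# id type x y z radius parent")
    for r in tree.topological_rows():
        code = _LABEL_TO_CODE.get(str(tree.labels[r]), 0)
        x, y, z = (float(v) for v in tree.coords[r])
        # repr round-trips float64 exactly, so read(write(tree)) is the identity
        lines.append(
            f"{int(tree.ids[r])} {code} {x!r} {y!r} {z!r} "
            f"{float(tree.radii[r])!r} {int(tree.parent_ids[r])}"
        )
    path.write_text("\n".join(lines) + "\n")


_SERIES_RE = re.compile(r"^(?P<cell>.+)_t(?P<time>[0-9]+(?:\.[0-9]+)?)\.swc$")


def write_series(series: TimeSeries, out_dir: str | Path) -> list[Path]:
    """Write one ``<cell>_t<hours>.swc`` file per frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, tree in series.frames:
        p = out_dir / f"{series.cell_id}_t{t:g}.swc"
        if tree.frame_time is None:
            tree = TracedTree.from_arrays(
                tree.ids, tree.labels, tree.coords, tree.radii, tree.parent_ids,
                cell_id=tree.cell_id, frame_time=t,
            )
        write_swc(tree, p)
        paths.append(p)
    return paths


def read_series(directory: str | Path, id_stability: bool = True) -> TimeSeries:
    """Read a per-frame SWC directory named ``<cell>_t<hours>.swc``."""
    directory = Path(directory)
    frames = []
    cell = "cell"
    for p in sorted(directory.glob("*.swc")):
        m = _SERIES_RE.match(p.name)
        if not m:
            continue
        cell = m.group("cell")
        t = float(m.group("time"))
        frames.append((t, read_swc(p, cell_id=cell)))
    if not frames:
        raise FileNotFoundError(f"no <cell>_t<hours>.swc frames found in {directory}")
    frames.sort(key=lambda ft: ft[0])
    return TimeSeries(frames=frames, id_stability=id_stability, cell_id=cell)


def project_xy(tree: TracedTree) -> np.ndarray:
    """Project every parent-child edge onto the XY plane.

    Returns an ``(n_edges, 2, 2)`` array of 2-D segment endpoints (z is the
    optical axis and is discarded, as for a maximum-intensity projection).
    A single-node tree yields an empty ``(0, 2, 2)`` array.
    """
    p, c = tree.edges()
    segs = np.empty((p.size, 2, 2), dtype=float)
    segs[:, 0, :] = tree.coords[p, :2]
    segs[:, 1, :] = tree.coords[c, :2]
    return segs
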
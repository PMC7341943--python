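"""Stochastic rhizoid-growth simulator.

Generates synthetic traced time series (SWC-ready ``TracedTree`` frames with
stable node identity) plus a ground-truth branch-event log, emulating the
growth statistics reported for *Rhizoclosmatium globosum* rhizoids:

* the total system elongates at a constant budget ``V`` (µm/h) shared
  across all active tips — total length is linear in time while individual
  tips decelerate as the tip count rises;
* branch events arrive as a Poisson process at rate ``λ`` per system per
  hour — tip production is linear in time;
* each event is lateral with probability ``p_lat`` (inserted at a
  length-uniform random point on the existing filament, at an in-plane
  angle drawn from a truncated normal) or apical (a tip splits, daughters
  at ±angle/2 about the established axis);
* tip headings random-walk with a per-step angular noise ("persistence").

Growth is planar (z = 0) by default, matching cells developing along the
glass bottom of a dish.  The carbon-replete preset uses the published
rates (110.8 µm/h elongation, 4.6 branches/h, 81.4° ± 6.3 branch angle);
the starved and bead presets encode the searching and feeding phenotype
shifts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .swc import RHIZOID, ROOT_MARKER, THALLUS, TracedTree, TimeSeries

__all__ = [
    "Bead",
    "GrowthParams",
    "BranchEventRecord",
    "EventLog",
    "SubsystemMetrics",
    "simulate",
    "preset",
    "bead_contact_split",
    "PRESET_NAMES",
]

PRESET_NAMES = ("replete", "starved", "bead")

BRANCH_LATERAL = "branch_lateral"
BRANCH_APICAL = "branch_apical"


@dataclass(frozen=True)
class Bead:
    """A spherical chitin microbead (experimental particulate organic matter)."""

    centre: tuple[float, float, float]
    radius: float


@dataclass
class GrowthParams:
    """Simulator configuration.

    Parameters
    ----------
    elongation_budget
        V, total system elongation per hour (µm/h), shared across tips.
    branch_rate
        λ, Poisson branch-event rate per system (events/h).
    lateral_prob
        Probability that an event is a lateral insertion (else apical split).
    angle_mu, angle_sigma
        Branch insertion angle distribution (degrees), truncated to (0, 180).
    tip_persistence
        Standard deviation (degrees) of the per-step heading noise of each tip.
    diameter
        Rhizoid filament diameter (µm); written as the node radius.
    dt, duration, frame_interval
        Integration step, total simulated time and frame spacing (hours).
    bead
        Optional microbead; edges/tips within ``contact_tolerance`` of its
        surface branch at ``contact_branch_rate`` and elongate with weight
        ``contact_tip_weight`` (the feeding regime), the rest keep the base
        parameters.
    initial_heading
        Germ-tube azimuth in degrees; None draws it uniformly.
    """

    elongation_budget: float = 110.8
    branch_rate: float = 4.6
    lateral_prob: float = 0.85
    angle_mu: float = 81.4
    angle_sigma: float = 6.3
    tip_persistence: float = 2.0
    diameter: float = 1.0
    thallus_radius: float = 2.5
    dt: float = 0.01
    duration: float = 10.0
    frame_interval: float = 1.0
    seed: int = 0
    bead: Bead | None = None
    contact_branch_rate: float = 9.2
    contact_tip_weight: float = 0.4
    contact_tolerance: float = 2.0
    initial_heading: float | None = None
    preset_name: str | None = None

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("elongation_budget", "branch_rate", "dt", "duration"):
            if not getattr(self, name) > 0:
                bad.append(name)
        if not (0.0 <= self.lateral_prob <= 1.0):
            bad.append("lateral_prob")
        if not (0.0 < self.angle_mu < 180.0):
            bad.append("angle_mu")
        if self.angle_sigma < 0:
            bad.append("angle_sigma")
        if self.tip_persistence < 0:
            bad.append("tip_persistence")
        if self.diameter <= 0:
            bad.append("diameter")
        if self.frame_interval <= 0:
            bad.append("frame_interval")
        elif abs(self.frame_interval / self.dt - round(self.frame_interval / self.dt)) > 1e-9:
            bad.append("frame_interval (must be a multiple of dt)")
        if self.bead is not None and self.bead.radius <= 0:
            bad.append("bead.radius")
        if bad:
            raise ValueError(f"invalid growth parameters: {', '.join(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.bead is not None:
            d["bead"] = {"centre": list(self.bead.centre), "radius": self.bead.radius}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GrowthParams":
        data = dict(data)
        if "preset" in data:
            base = preset(data.pop("preset"))
            merged = base.to_dict()
            merged.update(data)
            data = merged
        bead = data.get("bead")
        if isinstance(bead, dict):
            data["bead"] = Bead(centre=tuple(bead["centre"]), radius=float(bead["radius"]))
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown growth parameters: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "GrowthParams":
        """Load from a key-value YAML configuration file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def preset(name: str) -> GrowthParams:
    """Named parameter presets for the three studied growth conditions.

    ``replete``
        Exogenous-carbon feeding growth at the published rates.
    ``starved``
        Carbon starvation: halved branching rate and wider insertion angle
        at a maintained elongation budget — the long, sparse searching
        phenotype.
    ``bead``
        A searching cell that has contacted a chitin microbead: rhizoid in
        contact with the particle branches densely and elongates slowly
        (feeding) while the free rhizoid keeps the searching parameters.
    """
    if name == "replete":
        return GrowthParams(preset_name="replete")
    if name == "starved":
        return GrowthParams(branch_rate=2.3, angle_mu=95.0, preset_name="starved")
    if name == "bead":
        return GrowthParams(
            branch_rate=2.3,
            angle_mu=95.0,
            bead=Bead(centre=(20.0, 0.0, 0.0), radius=8.0),
            contact_branch_rate=9.2,
            contact_tip_weight=0.4,
            contact_tolerance=2.0,
            initial_heading=0.0,
            preset_name="bead",
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


@dataclass(frozen=True)
class BranchEventRecord:
    """Ground-truth record of one inserted branch."""

    time: float
    kind: str  # branch_lateral | branch_apical
    node_id: int  # id of the branch point the event created/split
    angle_deg: float


class EventLog:
    """Ordered ground-truth log of all branch insertions of one run."""

    def __init__(self, events: Iterable[BranchEventRecord] = ()):  # noqa: D107
        self.events: list[BranchEventRecord] = list(events)

    def append(self, ev: BranchEventRecord) -> None:
        self.events.append(ev)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[BranchEventRecord]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([asdict(e) for e in self.events])


class _Tip:
    __slots__ = ("node_row", "pos", "theta", "extended")

    def __init__(self, node_row: int, pos: np.ndarray, theta: float, extended: bool):
        self.node_row = node_row
        self.pos = pos
        self.theta = theta
        self.extended = extended


class _State:
    """Mutable growth state: flat node table plus edge list and tips."""

    def __init__(self, params: GrowthParams):
        self.params = params
        self.xs = [0.0]
        self.ys = [0.0]
        self.zs = [0.0]
        self.radii = [params.thallus_radius]
        self.parent_row = [ROOT_MARKER]
        self.edge_child: list[int] = []  # child row of each edge
        self.edge_len: list[float] = []
        self._edge_of_child: dict[int, int] = {}
        self.tips: list[_Tip] = []
        # incremental bead-contact bookkeeping (bead mode only)
        if params.bead is not None:
            self.bead_centre = np.asarray(params.bead.centre, dtype=float)
            self.contact_r = params.bead.radius + params.contact_tolerance
            self.edge_contact: list[bool] | None = []
        else:
            self.edge_contact = None

    def _midpoint_contact(self, p: int, c: int) -> bool:
        mx = 0.5 * (self.xs[p] + self.xs[c]) - self.bead_centre[0]
        my = 0.5 * (self.ys[p] + self.ys[c]) - self.bead_centre[1]
        mz = 0.5 * (self.zs[p] + self.zs[c]) - self.bead_centre[2]
        return mx * mx + my * my + mz * mz <= self.contact_r**2

    def add_node(self, pos: np.ndarray, parent_row: int, radius: float) -> int:
        row = len(self.xs)
        self.xs.append(float(pos[0]))
        self.ys.append(float(pos[1]))
        self.zs.append(float(pos[2]))
        self.radii.append(radius)
        self.parent_row.append(parent_row)
        parent_pos = np.array(
            [self.xs[parent_row], self.ys[parent_row], self.zs[parent_row]]
        )
        idx = len(self.edge_child)
        self.edge_child.append(row)
        self.edge_len.append(float(np.linalg.norm(pos - parent_pos)))
        self._edge_of_child[row] = idx
        if self.edge_contact is not None:
            self.edge_contact.append(self._midpoint_contact(parent_row, row))
        return row

    def split_edge(self, edge_idx: int, frac: float) -> tuple[int, float]:
        """Insert a node at ``frac`` along an edge; returns (row, axis azimuth)."""
        c = self.edge_child[edge_idx]
        p = self.parent_row[c]
        p_pos = np.array([self.xs[p], self.ys[p], self.zs[p]])
        c_pos = np.array([self.xs[c], self.ys[c], self.zs[c]])
        m_pos = p_pos + frac * (c_pos - p_pos)
        L = self.edge_len[edge_idx]
        # new midpoint node, child of p
        row = len(self.xs)
        self.xs.append(float(m_pos[0]))
        self.ys.append(float(m_pos[1]))
        self.zs.append(float(m_pos[2]))
        self.radii.append(self.params.diameter / 2.0)
        self.parent_row.append(p)
        m_idx = len(self.edge_child)
        self.edge_child.append(row)
        self.edge_len.append(frac * L)
        self._edge_of_child[row] = m_idx
        # reattach c below the midpoint
        self.parent_row[c] = row
        self.edge_len[edge_idx] = (1.0 - frac) * L
        if self.edge_contact is not None:
            self.edge_contact.append(self._midpoint_contact(p, row))
            self.edge_contact[edge_idx] = self._midpoint_contact(row, c)
        axis = math.atan2(c_pos[1] - p_pos[1], c_pos[0] - p_pos[0])
        return row, axis

    def snapshot(self, t: float, cell_id: str) -> TracedTree:
        n = len(self.xs)
        labels = np.empty(n, dtype=object)
        labels[:] = RHIZOID
        labels[0] = THALLUS
        parent_ids = np.array(
            [ROOT_MARKER if p == ROOT_MARKER else p + 1 for p in self.parent_row],
            dtype=np.int64,
        )
        return TracedTree.from_arrays(
            ids=np.arange(1, n + 1, dtype=np.int64),
            labels=labels,
            coords=np.stack(
                [np.array(self.xs), np.array(self.ys), np.array(self.zs)], axis=1
            ),
            radii=np.array(self.radii, dtype=float),
            parent_ids=parent_ids,
            cell_id=cell_id,
            frame_time=t,
        )


def _sample_angle(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Normal(mu, sigma) truncated to (0, 180) degrees, by rejection."""
    if sigma == 0:
        return mu
    for _ in range(1000):
        a = rng.normal(mu, sigma)
        if 0.0 < a < 180.0:
            return a
    return mu  # pathological sigma; fall back to the mode


def simulate(params: GrowthParams) -> tuple[TimeSeries, EventLog]:
    """Run the growth model; returns hourly-ish frames and the event log.

    Node identity is stable across frames: existing nodes never move, tips
    grow by appending nodes, and lateral insertions subdivide an edge
    without altering its geometry.  The same seed reproduces the run
    bit-exactly (single generator, fixed draw order: initial heading, then
    per step heading noise in tip order followed by branch arrivals).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    st = _State(params)
    cell_id = f"sim{params.seed}"

    theta0 = (
        math.radians(params.initial_heading)
        if params.initial_heading is not None
        else rng.uniform(0.0, 2.0 * math.pi)
    )
    st.tips.append(_Tip(node_row=0, pos=np.zeros(3), theta=theta0, extended=False))

    n_steps = int(round(params.duration / params.dt))
    frame_every = int(round(params.frame_interval / params.dt))
    kappa = math.radians(params.tip_persistence)
    radius = params.diameter / 2.0
    log = EventLog()

    frames: list[tuple[float, TracedTree]] = [(0.0, st.snapshot(0.0, cell_id))]

    bead = params.bead
    if bead is not None:
        bead_centre = np.asarray(bead.centre, dtype=float)
        contact_r = bead.radius + params.contact_tolerance

    def tip_in_contact(tip: _Tip) -> bool:
        return bool(np.linalg.norm(tip.pos - bead_centre) <= contact_r)

    def spawn_event(t_now: float, eligible_edges: np.ndarray | None, eligible_contact: bool | None):
        """One branch arrival: lateral insertion or apical split."""
        if rng.random() < params.lateral_prob:
            if eligible_edges is None:
                idx_pool = np.arange(len(st.edge_len))
            else:
                idx_pool = eligible_edges
            if idx_pool.size == 0:
                return
            lens = np.array(st.edge_len, dtype=float)[idx_pool]
            total = lens.sum()
            if total <= 0:
                return
            pick = min(
                int(np.searchsorted(np.cumsum(lens), rng.random() * total)), lens.size - 1
            )
            edge_idx = int(idx_pool[pick])
            frac = rng.random()
            row, axis = st.split_edge(edge_idx, frac)
            ang = _sample_angle(rng, params.angle_mu, params.angle_sigma)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pos = np.array([st.xs[row], st.ys[row], st.zs[row]])
            st.tips.append(
                _Tip(node_row=row, pos=pos, theta=axis + sign * math.radians(ang), extended=False)
            )
            log.append(BranchEventRecord(t_now, BRANCH_LATERAL, row + 1, ang))
        else:
            pool = [tp for tp in st.tips if tp.extended]
            if bead is not None and eligible_contact is not None:
                pool = [tp for tp in pool if tip_in_contact(tp) == eligible_contact]
            if not pool:
                return
            tp = pool[int(rng.integers(len(pool)))]
            ang = _sample_angle(rng, params.angle_mu, params.angle_sigma)
            half = math.radians(ang) / 2.0
            new = _Tip(node_row=tp.node_row, pos=tp.pos.copy(), theta=tp.theta + half, extended=False)
            tp.theta -= half
            tp.extended = False  # both daughters are pending until they extend
            st.tips.append(new)
            log.append(BranchEventRecord(t_now, BRANCH_APICAL, tp.node_row + 1, ang))

    for k in range(n_steps):
        # elongation: budget V*dt shared across tips (weighted in bead mode)
        ntips = len(st.tips)
        if bead is not None:
            tp_pos = np.array([tp.pos for tp in st.tips])
            d2 = ((tp_pos - bead_centre) ** 2).sum(axis=1)
            weights = np.where(d2 <= contact_r**2, params.contact_tip_weight, 1.0)
        else:
            weights = np.ones(ntips)
        noise = rng.normal(0.0, kappa, size=ntips) if kappa > 0 else np.zeros(ntips)
        budget = params.elongation_budget * params.dt
        wsum = weights.sum()
        for i, tp in enumerate(st.tips):
            step = budget * weights[i] / wsum
            tp.theta += noise[i]
            new_pos = tp.pos + step * np.array(
                [math.cos(tp.theta), math.sin(tp.theta), 0.0]
            )
            tp.node_row = st.add_node(new_pos, tp.node_row, radius)
            tp.pos = new_pos
            tp.extended = True

        t_now = (k + 1) * params.dt
        # branch arrivals (skipped on the final step so that every logged
        # branch has extended by at least one node in the last frame)
        if k < n_steps - 1:
            if bead is None:
                for _ in range(rng.poisson(params.branch_rate * params.dt)):
                    spawn_event(t_now, None, None)
            else:
                n_contact = rng.poisson(params.contact_branch_rate * params.dt)
                n_free = rng.poisson(params.branch_rate * params.dt)
                for _ in range(n_contact):
                    mask = np.array(st.edge_contact, dtype=bool)
                    spawn_event(t_now, np.flatnonzero(mask), True)
                for _ in range(n_free):
                    mask = np.array(st.edge_contact, dtype=bool)
                    spawn_event(t_now, np.flatnonzero(~mask), False)

        if (k + 1) % frame_every == 0:
            frames.append((t_now, st.snapshot(t_now, cell_id)))

    series = TimeSeries(frames=frames, id_stability=True, cell_id=cell_id)
    return series, log


@dataclass
class SubsystemMetrics:
    """Morphometrics of an edge subset of one tree (e.g. bead-contact part)."""

    n_edges: int
    total_length: float
    n_tips: int
    rgu_ratio: float
    max_euclidean: float
    cover_area: float
    edge_child_ids: np.ndarray


def _subsystem(tree: TracedTree, child_rows: np.ndarray, lengths: np.ndarray) -> SubsystemMetrics:
    from .morphometrics import cover_area as _hull_area

    length = float(lengths.sum())
    # a tip belongs to the subsystem of its incoming edge
    kids = tree.children_map()
    tip_count = 0
    for r in child_rows:
        nid = int(tree.ids[r])
        if not kids[nid]:
            tip_count += 1
    if child_rows.size:
        d = np.linalg.norm(tree.coords[child_rows] - tree.root_position, axis=1)
        reach = float(d.max())
        pts = np.unique(tree.coords[child_rows][:, :2], axis=0)
        if pts.shape[0] >= 3:
            from scipy.spatial import ConvexHull, QhullError

            try:
                hull_area = float(ConvexHull(pts).volume)
            except QhullError:
                hull_area = 0.0
        else:
            hull_area = 0.0
    else:
        reach = 0.0
        hull_area = 0.0
    return SubsystemMetrics(
        n_edges=int(child_rows.size),
        total_length=length,
        n_tips=tip_count,
        rgu_ratio=(length / tip_count) if tip_count else float("nan"),
        max_euclidean=reach,
        cover_area=hull_area,
        edge_child_ids=tree.ids[child_rows].copy(),
    )


def bead_contact_split(
    tree: TracedTree, bead: Bead, contact_tolerance: float = 2.0
) -> tuple[SubsystemMetrics, SubsystemMetrics]:
    """Partition a rhizoid system into bead-contact and free subsystems.

    An edge is in contact iff its midpoint lies within
    ``bead.radius + contact_tolerance`` of the bead centre.  Returns
    measurable summaries (length, tips, ratio-RGU, reach, cover area) for
    (contact, free), mirroring the contact/no-contact comparison of
    particle-colonising cells.
    """
    if bead is None:
        raise ValueError("no bead defined")
    p, c = tree.edges()
    lengths = np.linalg.norm(tree.coords[c] - tree.coords[p], axis=1)
    keep = (tree.labels[c] != THALLUS) & (lengths > 1e-12)
    p, c, lengths = p[keep], c[keep], lengths[keep]
    mids = 0.5 * (tree.coords[p] + tree.coords[c])
    d = np.linalg.norm(mids - np.asarray(bead.centre, dtype=float), axis=1)
    contact = d <= bead.radius + contact_tolerance
    return (
        _subsystem(tree, c[contact], lengths[contact]),
        _subsystem(tree, c[~contact], lengths[~contact]),
    )


def save_run(
    series: TimeSeries, log: EventLog, params: GrowthParams, out_dir: str | Path
) -> None:
    """Write SWC frames, events.csv and run-metadata JSON for one run."""
    from .swc import write_series

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_series(series, out_dir)
    log.to_dataframe().to_csv(out_dir / "events.csv", index=False)
    meta = {"params": params.to_dict(), "n_frames": len(series), "n_events": len(log)}
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2) + "\n")
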
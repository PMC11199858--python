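"""Time-evolving link tracing around seed areas.

Signals propagate at a constant conduction velocity (default 1 m/s, i.e.
1 mm/ms, typical of unmyelinated local circuits) and incur a fixed synaptic
delay (default 2 ms, equivalent to 2 mm of extra path length) at every relay
node.  Tracing from a seed therefore orders links into expanding shells of
first, second, ... synaptic neighbours by arrival time

    t = (cumulative path length) / velocity + (order - 1) * synaptic delay.

Display filters mirror the usual 3-D visualisation defaults — only links of
weight > 1 and length < 5 mm are kept — and are fully configurable; counts
of filtered-out links are reported.  Out-traces follow links away from the
seeds; in-traces follow them backwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import Partition
from .connectome import Connectome

__all__ = ["TraceConfig", "TraceEvent", "Trace", "trace", "local_cluster", "export_viz"]

# colour key per module, following the convention of atlas-coloured figures
MODULE_COLOURS = [
    "yellow",
    "light-green",
    "red",
    "salmon",
    "green",
    "yellow-brown",
    "lime",
    "pink",
    "blue",
    "orange",
    "purple",
    "cyan",
]
ORPHAN_COLOUR = "grey"


@dataclass
class TraceConfig:
    """Parameters of a temporal trace.

    velocity is in mm/ms (1.0 = 1 m/s); ``min_weight`` and ``max_length_mm``
    are strict display cutoffs (weight > min_weight, length < max_length_mm);
    ``max_order`` bounds the number of synaptic hops.
    """

    seeds: tuple[str, ...] = ()
    velocity: float = 1.0
    synaptic_delay_ms: float = 2.0
    max_order: int = 2
    min_weight: float = 1.0
    max_length_mm: float = 5.0
    direction: str = "out"

    def __post_init__(self) -> None:
        if isinstance(self.seeds, str):
            self.seeds = (self.seeds,)
        self.seeds = tuple(self.seeds)
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.min_weight < 0 or self.max_length_mm < 0:
            raise ValueError("cutoffs must be >= 0")
        if self.direction not in ("in", "out"):
            raise ValueError("direction must be 'in' or 'out'")


@dataclass(frozen=True)
class TraceEvent:
    """One link activation: the link (source -> target), its weight and
    length, the synaptic order of activation and the arrival time in ms."""

    arrival_ms: float
    order: int
    source: str
    target: str
    weight: float
    length_mm: float


@dataclass
class Trace:
    """Result of a trace: time-ordered events plus bookkeeping."""

    events: list[TraceEvent]
    seeds: tuple[str, ...]
    config: TraceConfig
    first_arrival: dict[str, float]  # node -> earliest arrival (seeds: 0)
    n_excluded_weight: int = 0
    n_excluded_length: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "arrival_ms": e.arrival_ms,
                    "order": e.order,
                    "source": e.source,
                    "target": e.target,
                    "weight": e.weight,
                    "length_mm": e.length_mm,
                }
                for e in self.events
            ]
        )


def trace(c: Connectome, cfg: TraceConfig) -> Trace:
    """Trace time-evolving links outward (or inward) from the seed areas.

    Order-1 events are the qualifying links of the seeds; order-k events are
    qualifying links of nodes first reached at order k-1, with arrival time
    = path length / velocity + (k-1) synaptic delays.  Each link keeps its
    earliest arrival, each node its earliest reach time; events are sorted
    by arrival, ties broken by (order, source, target).
    """
    if c.D is None:
        raise ValueError("connectome has no distance matrix; run compute_distances first")
    for s in cfg.seeds:
        if s not in c.labels:
            raise KeyError(f"unknown seed {s!r}")
    if not cfg.seeds:
        raise ValueError("no seeds given")

    n = c.n_nodes
    W = c.W if cfg.direction == "out" else c.W.T
    D = c.D
    seeds_idx = [c.index(s) for s in cfg.seeds]

    # qualifying-link mask and filter bookkeeping over the traced frontier
    n_excl_w = 0
    n_excl_l = 0

    INF = np.inf
    plen = np.full(n, INF)  # min path length (mm) to reach node
    order_reached = np.full(n, -1, dtype=int)
    for i in seeds_idx:
        plen[i] = 0.0
        order_reached[i] = 0
    frontier = list(seeds_idx)
    best_link: dict[tuple[int, int], tuple[float, int]] = {}  # (u,v)->(arrival, order)

    for k in range(1, cfg.max_order + 1):
        new_plen = plen.copy()
        next_frontier: set[int] = set()
        for u in frontier:
            for v in np.nonzero(W[u])[0]:
                w = W[u, v]
                ell = D[u, v]
                if w <= cfg.min_weight:
                    n_excl_w += 1
                    continue
                if ell >= cfg.max_length_mm:
                    n_excl_l += 1
                    continue
                path = plen[u] + ell
                arrival = path / cfg.velocity + (k - 1) * cfg.synaptic_delay_ms
                key = (u, v)
                if key not in best_link or arrival < best_link[key][0] - 1e-12:
                    best_link[key] = (arrival, k)
                if path < new_plen[v] - 1e-12:
                    new_plen[v] = path
                    if order_reached[v] < 0:
                        order_reached[v] = k
                    next_frontier.add(v)
        plen = new_plen
        frontier = sorted(next_frontier)
        if not frontier:
            break

    events = []
    for (u, v), (arrival, k) in best_link.items():
        su, tv = (u, v) if cfg.direction == "out" else (v, u)
        events.append(
            TraceEvent(
                arrival_ms=float(arrival),
                order=k,
                source=c.labels[su],
                target=c.labels[tv],
                weight=float(W[u, v]),
                length_mm=float(D[u, v]),
            )
        )
    events.sort(key=lambda e: (e.arrival_ms, e.order, e.source, e.target))

    first_arrival: dict[str, float] = {c.labels[i]: 0.0 for i in seeds_idx}
    for e in events:
        head = e.target if cfg.direction == "out" else e.source
        if head not in first_arrival or e.arrival_ms < first_arrival[head]:
            first_arrival[head] = e.arrival_ms
    return Trace(
        events=events,
        seeds=cfg.seeds,
        config=cfg,
        first_arrival=first_arrival,
        n_excluded_weight=n_excl_w,
        n_excluded_length=n_excl_l,
    )


def local_cluster(tr: Trace, radius_ms: float) -> set[str]:
    """Nodes first reached within ``radius_ms``, plus the seeds."""
    out = set(tr.seeds)
    for lab, t in tr.first_arrival.items():
        if t <= radius_ms:
            out.add(lab)
    return out


def export_viz(
    c: Connectome,
    events_or_links,
    partition: Partition | None = None,
    prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build node/edge tables for external 3-D viewers.

    The node table carries label, coordinates, module id and a colour key;
    the edge table carries source, target, weight, length and — depending on
    input — arrival time (a :class:`Trace`) or link flow (a ranked-link
    frame).  When ``prefix`` is given the tables are also written as
    ``{prefix}_nodes.csv/json`` and ``{prefix}_edges.csv/json``.
    """
    modules = {}
    if partition is not None:
        modules = partition.as_dict()
    node_rows = []
    for i, lab in enumerate(c.labels):
        m = modules.get(lab, -1)
        colour = ORPHAN_COLOUR if m < 0 else MODULE_COLOURS[m % len(MODULE_COLOURS)]
        xyz = c.coords[i] if c.coords is not None else (np.nan,) * 3
        node_rows.append(
            {
                "label": lab,
                "x_mm": float(xyz[0]),
                "y_mm": float(xyz[1]),
                "z_mm": float(xyz[2]),
                "module": int(m),
                "colour": colour,
            }
        )
    nodes = pd.DataFrame(node_rows)

    edge_rows = []
    if isinstance(events_or_links, Trace):
        for e in events_or_links.events:
            edge_rows.append(
                {
                    "source": e.source,
                    "target": e.target,
                    "weight": e.weight,
                    "length_mm": e.length_mm,
                    "arrival_ms": e.arrival_ms,
                    "order": e.order,
                    "source_module": modules.get(e.source, -1),
                    "target_module": modules.get(e.target, -1),
                }
            )
    elif isinstance(events_or_links, pd.DataFrame):
        for _, row in events_or_links.iterrows():
            s, t = row["source"], row["target"]
            i, j = c.index(s), c.index(t)
            rec = {
                "source": s,
                "target": t,
                "weight": float(c.W[i, j]),
                "length_mm": float(c.D[i, j]) if c.D is not None else np.nan,
                "source_module": modules.get(s, -1),
                "target_module": modules.get(t, -1),
            }
            if "link_flow" in row:
                rec["link_flow"] = float(row["link_flow"])
            edge_rows.append(rec)
    elif events_or_links:
        raise TypeError("events_or_links must be a Trace, a link DataFrame, or empty")
    edges = pd.DataFrame(edge_rows)

    if prefix is not None:
        nodes.to_csv(f"{prefix}_nodes.csv", index=False)
        edges.to_csv(f"{prefix}_edges.csv", index=False)
        with open(f"{prefix}_nodes.json", "w") as fh:
            json.dump(nodes.to_dict(orient="records"), fh, indent=1)
        with open(f"{prefix}_edges.json", "w") as fh:
            json.dump(edges.to_dict(orient="records"), fh, indent=1)
    return nodes, edges
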
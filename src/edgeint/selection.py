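"""V2 + top-down stage: path selection and attentional gain control.

Border-ownership circuits are not simulated mechanistically; the module
implements the computation such circuits are taken to perform — deciding
which edges participate in the integration for a given target:

* **wide** attentional spotlight: the target is compared to the common
  background along the shortest path in the region adjacency graph, so
  for a row of Gelb papers only each paper's own border with the
  surround (or with the insulating frame) is used and inter-paper
  borders are excluded;
* **narrow** spotlight: the target is compared to each of its
  immediately adjacent regions via one single-step pseudo-path per
  boundary component ("the four borders" of an interior Gelb paper).

Instruction-dependent edge interpretation (reflectance vs illumination)
and sharpness-based exclusion of candidate illumination gradients are
applied as multiplicative gains in [0, 1] on each edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .contrast import Edge, EdgeSet
from .stimuli import RegionMap

__all__ = [
    "RegionGraph",
    "IntegrationPath",
    "SpotlightSpec",
    "build_region_graph",
    "select_paths",
    "apply_gain_field",
    "mask_edge",
]


@dataclass
class SpotlightSpec:
    """Top-down attentional state.

    mode
        ``'wide'`` (compare to common background), ``'narrow'`` (compare
        to immediate neighbours), or ``'custom'`` (wide-style paths with
        a spatial gain mask).
    mask
        Optional per-pixel gain in [0, 1] (same grid as the stimulus);
        sampled at each edge's boundary centroid.
    edge_interpretation
        Per-edge-id interpretation, ``'reflectance'`` or
        ``'illumination'``; edges not listed use
        ``default_interpretation``.
    g_illum
        Residual gain for edges interpreted as illumination edges.  The
        ideal observer excludes them entirely (0); real observers may
        leave a partial contribution.
    g_gradient
        Residual gain for gradient-classified (blurry) edges; default 0
        excludes candidate illumination gradients from integration.
    """

    mode: str = "wide"
    mask: Optional[np.ndarray] = None
    edge_interpretation: dict[int, str] = field(default_factory=dict)
    default_interpretation: str = "reflectance"
    g_illum: float = 0.0
    g_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("wide", "narrow", "custom"):
            raise ValueError("mode must be wide, narrow or custom")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=float)
            if m.min() < 0 or m.max() > 1:
                raise ValueError("spotlight mask values must lie in [0, 1]")
            self.mask = m
        for v in (self.g_illum, self.g_gradient):
            if not 0.0 <= v <= 1.0:
                raise ValueError("gains must lie in [0, 1]")
        for interp in list(self.edge_interpretation.values()) + [self.default_interpretation]:
            if interp not in ("reflectance", "illumination"):
                raise ValueError("interpretation must be reflectance or illumination")

    def interpretation_of(self, edge_id: int) -> str:
        return self.edge_interpretation.get(edge_id, self.default_interpretation)


@dataclass
class RegionGraph:
    """Region adjacency graph: one node per region, one arc per edge.

    Parallel arcs (several connected boundary components between the
    same region pair) are kept distinct, keyed by edge id.
    """

    graph: nx.MultiGraph
    background_label: int

    def __post_init__(self) -> None:
        if self.background_label not in self.graph:
            raise ValueError("background label is not a node of the graph")
        if not nx.is_connected(self.graph):
            raise ValueError("region adjacency graph is disconnected")

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def neighbors(self, label: int) -> list[int]:
        return sorted(self.graph.neighbors(label))

    def edges_between(self, a: int, b: int) -> list[int]:
        """Edge ids of every boundary component joining regions a and b."""
        if not self.graph.has_edge(a, b):
            return []
        return sorted(self.graph[a][b], key=lambda k: -self.graph[a][b][k]["length"])

    def incident_edges(self, label: int) -> list[int]:
        """Edge ids of every boundary component of a region, sorted by id."""
        return sorted(k for _, _, k in self.graph.edges(label, keys=True))


@dataclass
class IntegrationPath:
    """Ordered walk through the region graph ending at the target.

    ``regions[0]`` is the path origin (the common background for wide
    mode; the adjacent local background for narrow pseudo-paths) and
    ``edge_ids[j]`` is the boundary crossed between ``regions[j]`` and
    ``regions[j+1]``.
    """

    regions: list[int]
    edge_ids: list[int]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if len(self.regions) < 2 or len(self.edge_ids) != len(self.regions) - 1:
            raise ValueError("path must cross at least one edge")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("path repeats a region")

    @property
    def target(self) -> int:
        return self.regions[-1]

    def steps(self) -> list[tuple[int, int, int]]:
        """(from_region, to_region, edge_id) triples toward the target."""
        return [
            (self.regions[j], self.regions[j + 1], self.edge_ids[j])
            for j in range(len(self.edge_ids))
        ]


def build_region_graph(regions: RegionMap, edges: EdgeSet) -> RegionGraph:
    """Assemble the region adjacency multigraph from extracted edges."""
    g = nx.MultiGraph()
    g.add_nodes_from(int(l) for l in regions.region_labels())
    for e in edges:
        g.add_edge(
            e.region_a,
            e.region_b,
            key=e.id,
            length=e.boundary_length_deg(edges.pitch),
        )
    return RegionGraph(graph=g, background_label=regions.background_label)


def _best_edge(graph: RegionGraph, a: int, b: int) -> int:
    """Boundary component with the greatest shared border length."""
    ids = graph.edges_between(a, b)
    if not ids:
        raise ValueError(f"regions {a} and {b} are not adjacent")
    return ids[0]


def select_paths(
    graph: RegionGraph, target: int, spotlight: SpotlightSpec
) -> list[IntegrationPath]:
    """Select the integration paths for a target region.

    Wide (and custom) mode returns the single shortest path from the
    common background to the target; among equally short paths the one
    whose edges share the greatest total boundary length is taken.
    Narrow mode returns one single-step pseudo-path per boundary
    component of the target, each treating the adjacent region as a
    local background.
    """
    bg = graph.background_label
    if target == bg:
        raise ValueError("target must differ from the background region")
    if target not in graph.graph:
        raise ValueError(f"unknown target region {target}")

    if spotlight.mode == "narrow":
        paths = []
        for eid in graph.incident_edges(target):
            for u, v, k in graph.graph.edges(target, keys=True):
                if k == eid:
                    other = v if u == target else u
                    paths.append(
                        IntegrationPath(regions=[other, target], edge_ids=[eid], pseudo=True)
                    )
                    break
        if not paths:
            raise ValueError("target has no boundaries")
        return paths

    candidates = list(nx.all_shortest_paths(graph.graph, bg, target))
    scored = []
    for seq in candidates:
        eids = [_best_edge(graph, seq[j], seq[j + 1]) for j in range(len(seq) - 1)]
        total = sum(graph.graph[seq[j]][seq[j + 1]][eids[j]]["length"] for j in range(len(eids)))
        scored.append((total, tuple(seq), eids))
    scored.sort(key=lambda t: (-t[0], t[1]))
    total, seq, eids = scored[0]
    return [IntegrationPath(regions=list(seq), edge_ids=eids)]


def _edge_centroid(edge: Edge) -> np.ndarray:
    mid = (edge.pixels_a + edge.pixels_b) / 2.0
    return mid.mean(axis=0)


def apply_gain_field(edges: EdgeSet, spotlight: SpotlightSpec) -> EdgeSet:
    """Set every edge's top-down gain from the spotlight state.

    gain = (spatial mask at the boundary centroid)
         × (1 for reflectance edges, ``g_illum`` for illumination edges)
         × (1 for sharp edges, ``g_gradient`` for gradients),
    clamped to [0, 1].  Recomputed from scratch, so the operation is
    idempotent for a fixed spotlight.
    """
    out = edges.copy()
    for e in out:
        g = 1.0
        if spotlight.mask is not None:
            r, c = np.round(_edge_centroid(e)).astype(int)
            r = int(np.clip(r, 0, spotlight.mask.shape[0] - 1))
            c = int(np.clip(c, 0, spotlight.mask.shape[1] - 1))
            g *= float(spotlight.mask[r, c])
        if spotlight.interpretation_of(e.id) == "illumination":
            g *= spotlight.g_illum
        if e.sharpness == "gradient":
            g *= spotlight.g_gradient
        e.gain = float(np.clip(g, 0.0, 1.0))
    return out


def mask_edge(edges: EdgeSet, edge_id: int) -> EdgeSet:
    """Return a copy with one edge's gain forced to zero.

    Models flicker-masking/contour-adaptation experiments in which an
    edge's neural response is fatigued away before integration.
    """
    out = edges.copy()
    if edge_id not in {e.id for e in out}:
        raise KeyError(f"unknown edge id {edge_id}")
    out[edge_id].gain = 0.0
    return out


def paths_to_frame(paths: list[IntegrationPath], edges: EdgeSet) -> pd.DataFrame:
    """Serialise selected paths (path id, step, edge, direction, gain)."""
    rows = []
    for pid, p in enumerate(paths):
        for step, (frm, to, eid) in enumerate(p.steps()):
            e = edges[eid]
            rows.append(
                {
                    "path_id": pid,
                    "step": step,
                    "from_region": frm,
                    "to_region": to,
                    "edge_id": eid,
                    "direction": 1 if (frm, to) == (e.region_a, e.region_b) else -1,
                    "gain": e.gain,
                    "pseudo": p.pseudo,
                }
            )
    return pd.DataFrame(rows)
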
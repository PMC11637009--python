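"""Metric-free coordinates on cell networks.

The topological distance k between two cells is the number of cells on the
shortest path through the adjacency network; origin cells have k = 0.  In
each tissue region a dedicated origin anchors a radial coordinate:

* outDVB halves: the origin is the single cell adjacent to the boundary band
  that lies closest (metrically) to the mean position of the cells maximally
  distant from the tissue margin.
* boundary band (DVB): the origin is a line of cells transversing the band —
  at larval-type stages the cells within 1.2 * sqrt(A_cell / pi) of the
  straight segment joining the dorsal and ventral centre cells; at
  pupal-type stages the first cell row against the distal margin.

Ring counts ΔN(k), cumulative counts N(k) and the ring index k(N_ROI)
needed to enclose a tracked cell count provide the stage-to-stage tracking;
mean shortest-path lengths along cell centres, normalised by the outermost
ring, give the dimensionless coordinate r (or rho) in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cell_network import CellNetwork

__all__ = [
    "TopoChart",
    "topological_distance",
    "find_outDVB_origin",
    "find_DVB_origin",
    "ring_statistics",
    "roi_tracking",
    "normalized_path_coordinate",
    "build_chart",
]

DVB_LINE_RADIUS_FACTOR = 1.2


@dataclass
class TopoChart:
    """Topological coordinates of one region at one stage."""

    k: np.ndarray                 # (n_cells,) ring index; -1 for unreachable/excluded
    origin_cells: np.ndarray      # cell indices with k = 0
    cell_mask: np.ndarray         # cells belonging to the charted region
    path_length: np.ndarray = field(default=None)  # type: ignore[assignment]  # μm
    coord: np.ndarray = field(default=None)        # type: ignore[assignment]  # r or rho

    def rings(self) -> np.ndarray:
        ks = self.k[self.cell_mask & (self.k >= 0)]
        return np.arange(int(ks.max()) + 1) if len(ks) else np.empty(0, dtype=int)

    def to_frame(self, net: CellNetwork) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": net.cell_ids,
            "region": net.region,
            "k": self.k,
            "path_length_um": self.path_length,
            "r_or_rho": self.coord,
        })


def topological_distance(net: CellNetwork, origin_cells, graph=None,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Multi-source BFS ring index on the cell adjacency graph.

    ``mask`` restricts the walk to a cell subset (origins excepted).
    Unreachable cells get k = -1.
    """
    g = net.adjacency() if graph is None else graph
    if mask is not None:
        allowed = set(np.flatnonzero(mask)) | set(int(c) for c in origin_cells)
        g = g.subgraph(allowed)
    k = np.full(net.n_cells, -1, dtype=int)
    sources = [int(c) for c in origin_cells]
    if not sources:
        raise ValueError("no origin cells supplied")
    for node, d in _multi_source_bfs(g, sources).items():
        k[node] = d
    return k


def _multi_source_bfs(g, sources) -> dict:
    from collections import deque

    dist = {s: 0 for s in sources if s in g}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _margin_cells(net: CellNetwork, mask: np.ndarray) -> np.ndarray:
    """Outermost row of a region mask: cells with a bond on its boundary."""
    out = np.zeros(net.n_cells, dtype=bool)
    for cells in net.bonds().values():
        inside = [c for c in cells if mask[c]]
        if len(cells) == 1 and inside:
            out[inside[0]] = True
        elif inside and len(inside) < len(cells):
            for c in inside:
                out[c] = True
    return np.flatnonzero(out)


def find_outDVB_origin(net: CellNetwork, region_mask: np.ndarray,
                       dvb_mask: np.ndarray, graph=None) -> int:
    """Origin cell of one outDVB half.

    Cells maximally distant (topologically) from the tissue margin identify
    the region centre; the origin is the DVB-adjacent cell metrically closest
    to their mean position.  Ties resolve to the lowest cell index.
    """
    g = net.adjacency() if graph is None else graph
    region = np.flatnonzero(region_mask)
    if len(region) == 0:
        raise ValueError("empty region")
    if len(region) == 1:
        return int(region[0])
    margin = [c for c in _margin_cells(net, region_mask | dvb_mask) if region_mask[c]]
    if not margin:
        margin = list(_margin_cells(net, region_mask))
    sub = g.subgraph(region.tolist())
    dist = _multi_source_bfs(sub, [c for c in margin if c in sub])
    dmax = max(dist.get(int(c), -1) for c in region)
    far = np.array(sorted(c for c in region if dist.get(int(c), -1) == dmax))
    target = net.centroids()[far].mean(axis=0)
    dvb_adjacent = sorted(
        c for c in region
        if any(dvb_mask[nb] for nb in g.neighbors(int(c)))
    )
    if not dvb_adjacent:
        raise ValueError("region has no cells adjacent to the DVB")
    cen = net.centroids()
    d = np.linalg.norm(cen[dvb_adjacent] - target, axis=1)
    best = np.flatnonzero(np.isclose(d, d.min()))
    return int(np.array(dvb_adjacent)[best].min())


def find_DVB_origin(net: CellNetwork, dvb_mask: np.ndarray,
                    stage_kind: str = "larval",
                    center_D: int | None = None, center_V: int | None = None,
                    distal_margin: np.ndarray | None = None, graph=None) -> np.ndarray:
    """Origin cell line transversing the boundary band.

    Larval kind: band cells whose centroids lie within
    ``1.2 * sqrt(A_cell / pi)`` of the straight segment joining the dorsal
    and ventral centre cells.  Pupal kind: the first cell row adjacent to the
    distal margin (``distal_margin`` cell indices, or the band's own margin
    row when omitted).
    """
    dvb = np.flatnonzero(dvb_mask)
    if len(dvb) == 0:
        raise ValueError("empty DVB region")
    cen, area, _ = net.geometry()
    if stage_kind == "larval":
        if center_D is None or center_V is None:
            raise ValueError("larval DVB origin needs the dorsal and ventral centre cells")
        a, b = cen[center_D], cen[center_V]
        ab = b - a
        denom = float(ab @ ab)
        origin = []
        for c in dvb:
            t = np.clip((cen[c] - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
            d = np.linalg.norm(cen[c] - (a + t * ab))
            if d <= DVB_LINE_RADIUS_FACTOR * np.sqrt(area[c] / np.pi):
                origin.append(int(c))
        if not origin:
            raise ValueError("no DVB cells within the origin-line distance")
        return np.array(sorted(origin))
    if stage_kind == "pupal":
        g = net.adjacency() if graph is None else graph
        if distal_margin is None:
            distal_margin = _margin_cells(net, dvb_mask)
        margin_set = set(int(c) for c in distal_margin)
        row = sorted(c for c in dvb if int(c) in margin_set
                     or any(int(nb) in margin_set for nb in g.neighbors(int(c))))
        row = [c for c in row if int(c) in margin_set]
        if not row:
            raise ValueError("no DVB cells on the distal margin")
        return np.array(row)
    raise ValueError(f"unknown stage kind {stage_kind!r}")


def ring_statistics(chart: TopoChart) -> pd.DataFrame:
    """Per-ring counts ΔN(k) and cumulative counts N(k); empty rings kept."""
    ks = chart.k[chart.cell_mask & (chart.k >= 0)]
    if len(ks) == 0:
        raise ValueError("chart has no assigned cells")
    counts = np.bincount(ks)
    return pd.DataFrame({
        "k": np.arange(len(counts)),
        "delta_N": counts,
        "N": np.cumsum(counts),
    })


def roi_tracking(rings_t: pd.DataFrame, rings_later: pd.DataFrame, N_ROI: int
                 ) -> tuple[int, int]:
    """Smallest ring index enclosing ``N_ROI`` cells at each stage."""
    out = []
    for rings in (rings_t, rings_later):
        if N_ROI > int(rings["N"].iloc[-1]):
            raise ValueError("N_ROI exceeds the region's cell count")
        out.append(int(rings.loc[rings["N"] >= N_ROI, "k"].iloc[0]))
    return out[0], out[1]


def normalized_path_coordinate(net: CellNetwork, chart: TopoChart, graph=None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Metric coordinate r (or rho) from shortest paths along cell centres.

    Per-cell shortest weighted path length (edge weight = centroid distance)
    to the origin set, averaged per ring and normalised by the outermost
    ring's mean; returns (per-cell path length μm, per-cell coordinate).
    """
    g = net.adjacency() if graph is None else graph
    cen = net.centroids()
    w = {(a, b): float(np.linalg.norm(cen[a] - cen[b])) for a, b in g.edges()}
    nx.set_edge_attributes(g, {e: {"w": v} for e, v in w.items()})
    dist = nx.multi_source_dijkstra_path_length(
        g, [int(c) for c in chart.origin_cells], weight="w")
    plen = np.full(net.n_cells, np.nan)
    for node, d in dist.items():
        plen[node] = d
    coord = np.full(net.n_cells, np.nan)
    ks = chart.k
    valid = chart.cell_mask & (ks >= 0) & np.isfinite(plen)
    if not np.any(valid):
        raise ValueError("no valid cells for path coordinates")
    kmax = int(ks[valid].max())
    ring_mean = np.full(kmax + 1, np.nan)
    for k in range(kmax + 1):
        sel = valid & (ks == k)
        if np.any(sel):
            ring_mean[k] = plen[sel].mean()
    outer = ring_mean[np.isfinite(ring_mean)][-1]
    if outer <= 0:
        raise ValueError("outermost ring has zero mean path length")
    coord[valid] = ring_mean[ks[valid]] / outer
    return plen, coord


def build_chart(net: CellNetwork, origin_cells, region_mask: np.ndarray,
                graph=None) -> TopoChart:
    """Full chart: BFS rings, path lengths and normalised coordinate."""
    g = net.adjacency() if graph is None else graph
    k = topological_distance(net, origin_cells, graph=g, mask=region_mask)
    k[~region_mask] = -1
    for c in origin_cells:
        k[int(c)] = 0
    chart = TopoChart(k, np.asarray(origin_cells, dtype=int), region_mask)
    chart.path_length, chart.coord = normalized_path_coordinate(net, chart, graph=g)
    return chart
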
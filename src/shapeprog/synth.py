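"""Synthetic curved epithelia with known ground-truth cell dynamics.

Two generators cover the needs of the measurement stack:

* ``generate_ring_cap`` builds a radially organised tessellation of a
  spherical cap: ring 0 is a single apex cell, ring j >= 1 holds a
  programmable number of quadrilateral-ish cells between two polar circles.
  Because ring membership, per-ring cell counts, areas and aspect ratios are
  construction inputs, stage pairs produced by ``apply_stage_transition``
  carry exact ground-truth area strain, rearrangement strain and
  (analytically approximated) elongation strain per ring.

* ``generate_cap_tessellation`` builds an organic-looking Lloyd-relaxed
  spherical Voronoi tessellation (seeded, deterministic) for fixtures where
  polygonal disorder matters more than exact ground truth.

``fixture_suite`` bundles the small deterministic fixtures used across the
test suite: a hexagonal disc (ring law N(k) = 1 + 3k(k+1)), a rectangular
strip with a known transversal, small ring caps and analytic test curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_network import CellNetwork

__all__ = [
    "RingCapConfig",
    "generate_ring_cap",
    "apply_stage_transition",
    "generate_cap_tessellation",
    "hexagonal_disc",
    "strip_with_transversal",
    "fixture_suite",
    "ring_boundaries_for",
]


# ---------------------------------------------------------------------------
# Ring-structured cap tessellation (exact ground truth)
# ---------------------------------------------------------------------------

@dataclass
class RingCapConfig:
    """Layout of a ring-structured cap tessellation.

    ``ring_counts[0]`` must be 1 (the apex cell); ``boundaries`` holds the
    polar angles of the ring-separating circles (length ``len(ring_counts)``,
    the outer rim included, apex angle 0 implicit).
    """

    R: float
    ring_counts: np.ndarray
    boundaries: np.ndarray
    azimuth_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    # optional azimuthal subdivision of circle arcs (radians); 0 keeps cells
    # as true junction polygons, matching what segmentation pipelines emit
    max_arc: float = 0.0

    def __post_init__(self) -> None:
        self.ring_counts = np.asarray(self.ring_counts, dtype=int)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.ring_counts[0] != 1:
            raise ValueError("ring 0 must hold exactly the single apex cell")
        if len(self.boundaries) != len(self.ring_counts):
            raise ValueError("need one boundary circle per ring (rim included)")
        if np.any(np.diff(self.boundaries) <= 0) or self.boundaries[0] <= 0:
            raise ValueError("boundary angles must be positive and increasing")
        if self.azimuth_offsets is None:
            # generic irrational-ish offsets so cuts of adjacent rings never
            # coincide (guarantees shared arcs of >= 2 vertices)
            j = np.arange(len(self.ring_counts))
            self.azimuth_offsets = np.mod(0.173 + 0.3819660113 * j, 1.0)

    @property
    def n_rings(self) -> int:
        return len(self.ring_counts)

    @property
    def theta_M(self) -> float:
        return float(self.boundaries[-1])

    def cuts(self, j: int) -> np.ndarray:
        """Azimuthal cut angles of ring j (empty for the apex cell)."""
        m = int(self.ring_counts[j])
        if j == 0 or m < 2:
            return np.empty(0)
        return np.sort(np.mod(2.0 * np.pi * (np.arange(m) + self.azimuth_offsets[j]) / m,
                              2.0 * np.pi))

    def ring_areas(self) -> np.ndarray:
        """Total spherical area of each ring (μm²)."""
        cos = np.cos(np.concatenate([[0.0], self.boundaries]))
        return 2.0 * np.pi * self.R**2 * (-np.diff(cos))

    def cell_areas(self) -> np.ndarray:
        return self.ring_areas() / self.ring_counts

    def ring_aspect_scale(self) -> np.ndarray:
        """Analytic radial length scale L = sqrt(radial / azimuthal extent)
        per ring (= exp(Q_rr) of an equivalent rectangle)."""
        th = np.concatenate([[0.0], self.boundaries])
        a = self.R * np.diff(th)
        mid = 0.5 * (th[:-1] + th[1:])
        b = self.R * np.sin(mid) * 2.0 * np.pi / self.ring_counts
        # the apex cell is isotropic by construction
        L = np.sqrt(a / b)
        L[0] = 1.0
        return L

    def cumulative_counts(self) -> np.ndarray:
        return np.cumsum(self.ring_counts)


def ring_boundaries_for(R: float, theta_M: float, ring_counts,
                        rel_cell_area=None) -> np.ndarray:
    """Boundary circles giving each ring a cell area proportional to
    ``rel_cell_area`` (uniform by default): solid-angle slabs proportional to
    ring_count * relative area."""
    counts = np.asarray(ring_counts, dtype=float)
    w = np.ones_like(counts) if rel_cell_area is None else np.asarray(rel_cell_area, float)
    slab = counts * w
    cum = np.cumsum(slab) / slab.sum()
    cos = 1.0 - cum * (1.0 - np.cos(theta_M))
    return np.arccos(np.clip(cos, -1.0, 1.0))


def generate_ring_cap(config: RingCapConfig) -> CellNetwork:
    """Materialise a ring layout as a 3D cell network on the sphere."""
    cfg = config
    J = cfg.n_rings
    R = cfg.R
    th = np.concatenate([[0.0], cfg.boundaries])
    # circle c (1..J) at polar angle th[c] carries the cuts of rings c-1 and c
    circle_angles: list[np.ndarray] = [np.empty(0)]  # index 0 unused
    for c in range(1, J + 1):
        cuts = [cfg.cuts(c - 1)]
        if c <= J - 1:
            cuts.append(cfg.cuts(c))
        ang = np.unique(np.concatenate(cuts))
        if len(ang) == 0:
            raise ValueError(f"circle {c} has no division points; increase ring counts")
        # subdivide long arcs so polygonal cell areas track the spherical
        # patch areas (fill vertices are shared by the cells on both sides)
        if cfg.max_arc > 0:
            fill = []
            closed = np.concatenate([ang, [ang[0] + 2.0 * np.pi]])
            for lo, hi in zip(closed[:-1], closed[1:]):
                gap = hi - lo
                n_extra = int(np.floor(gap / cfg.max_arc))
                if n_extra:
                    fill.append(lo + gap * np.arange(1, n_extra + 1) / (n_extra + 1))
            if fill:
                ang = np.unique(np.concatenate([ang, np.mod(np.concatenate(fill),
                                                            2.0 * np.pi)]))
        circle_angles.append(ang)

    verts = []
    vid: dict[tuple[int, int], int] = {}
    for c in range(1, J + 1):
        for i, phi in enumerate(circle_angles[c]):
            vid[(c, i)] = len(verts)
            t = th[c]
            verts.append([R * np.sin(t) * np.cos(phi), R * np.sin(t) * np.sin(phi),
                          R * np.cos(t)])
    vertices = np.array(verts)

    def arc_indices(c: int, lo: float, hi: float) -> list[int]:
        """Vertex indices on circle c with azimuth in [lo, hi] (mod 2pi)."""
        ang = circle_angles[c]
        if hi > lo:
            sel = np.flatnonzero((ang >= lo - 1e-12) & (ang <= hi + 1e-12))
            return [vid[(c, int(i))] for i in sel]
        sel_hi = np.flatnonzero(ang >= lo - 1e-12)
        sel_lo = np.flatnonzero(ang <= hi + 1e-12)
        return [vid[(c, int(i))] for i in np.concatenate([sel_hi, sel_lo])]

    cells: list[np.ndarray] = []
    ring_of_cell: list[int] = []
    # apex cell: all of circle 1, ordered by azimuth
    cells.append(np.array([vid[(1, i)] for i in range(len(circle_angles[1]))],
                          dtype=np.intp))
    ring_of_cell.append(0)
    for j in range(1, J):
        cuts = cfg.cuts(j)
        m = len(cuts)
        for i in range(m):
            lo, hi = cuts[i], cuts[(i + 1) % m]
            inner = arc_indices(j, lo, hi)
            outer = arc_indices(j + 1, lo, hi)
            cells.append(np.array(inner + outer[::-1], dtype=np.intp))
            ring_of_cell.append(j)

    net = CellNetwork(vertices, cells)
    net.region = np.array([f"ring{r}" for r in ring_of_cell], dtype=object)
    net.reorient()
    return net


def apply_stage_transition(config: RingCapConfig,
                           area_factor=None,
                           new_counts=None,
                           ) -> tuple[RingCapConfig, pd.DataFrame]:
    """Later-stage layout realising prescribed per-ring cell behaviours.

    ``area_factor`` is the per-original-ring isotropic length strain
    (lambda_A*, so cell areas scale by its square); ``new_counts`` the
    later-stage ring occupancies (total conserved: division-free).  Returns
    the new layout and a ground-truth table per original ring with columns
    (k, N, lambda_A, lambda_Q, lambda_R) — lambda_Q is the analytic
    rectangle-equivalent value implied by the new layout.
    """
    K = config.n_rings
    lamA = np.ones(K) if area_factor is None else np.broadcast_to(
        np.asarray(area_factor, float), (K,)).copy()
    if np.any(lamA <= 0):
        raise ValueError("area factors must be positive")
    counts2 = config.ring_counts.copy() if new_counts is None else np.asarray(new_counts, int)
    if counts2[0] != 1:
        raise ValueError("the later stage must keep the single apex cell")
    if counts2.sum() != config.ring_counts.sum():
        raise ValueError("rearrangement schedule must conserve the cell count")

    N1 = config.cumulative_counts()
    A1 = config.ring_areas()
    # target cumulative area at the original cumulative counts, then spread
    # piecewise-linearly in N to place the new boundaries
    S_knots = np.concatenate([[0.0], np.cumsum(lamA**2 * A1)])
    N_knots = np.concatenate([[0.0], N1.astype(float)])
    N2 = np.cumsum(counts2).astype(float)
    S2 = np.interp(N2, N_knots, S_knots)
    cos2 = 1.0 - S2 / (2.0 * np.pi * config.R**2)
    boundaries2 = np.arccos(np.clip(cos2, -1.0, 1.0))
    cfg2 = RingCapConfig(config.R, counts2, boundaries2, max_arc=config.max_arc)

    # ground truth per original ring
    k_of_N2 = _k_of_N_interp(counts2)
    n_later = k_of_N2(N1.astype(float)) - k_of_N2(np.concatenate([[0.0], N1[:-1]]).astype(float))
    lamR = n_later / 1.0  # n(N, t) = 1 by construction
    # analytic elongation scale of the matched bin at the later stage:
    # count-weighted mean of the new rings' aspect scales over the bin's span
    L2_ring = cfg2.ring_aspect_scale()
    edges2 = np.concatenate([[0.0], np.cumsum(counts2).astype(float)])
    N_lo = np.concatenate([[0.0], N1[:-1].astype(float)])
    lamQ = np.empty(K)
    for k in range(K):
        lo = np.clip(edges2[:-1], N_lo[k], float(N1[k]))
        hi = np.clip(edges2[1:], N_lo[k], float(N1[k]))
        w = hi - lo
        lamQ[k] = float(np.sum(w * L2_ring) / np.sum(w)) / config.ring_aspect_scale()[k]
    truth = pd.DataFrame({
        "k": np.arange(K), "N": N1,
        "lambda_A": lamA, "lambda_Q": lamQ, "lambda_R": lamR,
    })
    return cfg2, truth


def radial_rearrangement_counts(ring_counts, stretch: float = 1.3,
                                start_ring: int = 6) -> np.ndarray:
    """Later-stage ring occupancies for a smooth radial lengthening.

    Rings up to ``start_ring`` are untouched; beyond it the continuous ring
    index stretches by ``stretch`` (> 1: radially oriented rearrangements,
    < 1: tangential).  The total cell count is conserved.
    """
    counts = np.asarray(ring_counts, dtype=float)
    K = len(counts)
    N1 = np.cumsum(counts)
    kk = np.arange(K, dtype=float)
    fk = np.where(kk <= start_ring, kk, start_ring + (kk - start_ring) * stretch)
    K2 = int(np.ceil(fk[-1]))
    old_k_at_edges = np.interp(np.arange(1.0, K2 + 1), fk, kk)
    N_edges = np.interp(old_k_at_edges, kk, N1)
    N_edges[-1] = N1[-1]
    c2 = np.round(np.diff(np.concatenate([[counts[0]], N_edges]))).astype(int)
    c2 = np.concatenate([[int(counts[0])], c2])
    c2[-1] += int(counts.sum()) - int(c2.sum())
    if np.any(c2 < 1):
        raise ValueError("stretch too aggressive: a ring would be emptied")
    return c2


def standard_stage_pair(kind: str, n_rings: int = 26, R: float = 77.66,
                        theta_M: float = 0.8):
    """Deterministic ~2000-cell stage pair with exact ground truth.

    ``kind`` is "area" (radial area-growth gradient, 25% length strain at
    the rim), "rearrangement" (radial lengthening by 1.3 outside ring 6) or
    "combined".  Returns (net_t, config_t, net_later, config_later, truth).
    """
    counts = np.array([1] + [6 * j for j in range(1, n_rings)])
    cfg1 = RingCapConfig(R, counts, ring_boundaries_for(R, theta_M, counts))
    grad = 1.0 + 0.25 * np.arange(n_rings) / n_rings
    if kind == "area":
        cfg2, truth = apply_stage_transition(cfg1, area_factor=grad)
    elif kind == "rearrangement":
        cfg2, truth = apply_stage_transition(
            cfg1, new_counts=radial_rearrangement_counts(counts))
    elif kind == "combined":
        cfg2, truth = apply_stage_transition(
            cfg1, area_factor=grad, new_counts=radial_rearrangement_counts(counts))
    else:
        raise ValueError(f"unknown stage-pair kind {kind!r}")
    return generate_ring_cap(cfg1), cfg1, generate_ring_cap(cfg2), cfg2, truth


def _k_of_N_interp(ring_counts: np.ndarray):
    """Continuous ring index as a function of cumulative cell count."""
    N = np.cumsum(ring_counts).astype(float)
    k = np.arange(len(ring_counts), dtype=float)
    # ring j covers cumulative counts (N(j-1), N(j)]; k(0) = -1 makes the
    # identity schedule give exactly one ring per bin
    xs = np.concatenate([[0.0], N])
    ys = np.concatenate([[-1.0], k])

    def f(n):
        return np.interp(n, xs, ys)

    return f


# ---------------------------------------------------------------------------
# Lloyd-relaxed spherical Voronoi tessellation (organic fixtures)
# ---------------------------------------------------------------------------

def generate_cap_tessellation(R: float, theta_M: float, n_cells: int, seed: int,
                              lloyd_iterations: int = 10,
                              density=None) -> CellNetwork:
    """Centroidal-Voronoi-like tessellation of a spherical cap.

    Generators are sampled uniformly on a padded cap (optionally re-weighted
    by ``density(r)`` with r = theta/theta_M), relaxed by Lloyd iterations of
    the spherical Voronoi diagram, and the cells whose generators lie inside
    the cap are kept.  Deterministic for a fixed seed.
    """
    from scipy.spatial import SphericalVoronoi

    if n_cells < 10:
        raise ValueError("need at least 10 cells for a sensible tessellation")
    rng = np.random.default_rng(seed)
    pad = min(theta_M * 0.35 + 0.1, np.pi - theta_M)
    theta_max = theta_M + pad
    n_total = max(int(n_cells * (1 - np.cos(theta_max)) / (1 - np.cos(theta_M))), n_cells + 8)
    z = 1.0 - rng.random(n_total) * (1.0 - np.cos(theta_max))
    if density is not None:
        # rejection step biasing generator density ~ 1/cell area
        theta = np.arccos(z)
        w = np.asarray([1.0 / max(density(min(t / theta_M, 1.0)), 1e-9) for t in theta])
        keepmask = rng.random(n_total) < w / w.max()
        z = z[keepmask]
    phi = rng.random(len(z)) * 2.0 * np.pi
    s = np.sqrt(1.0 - z**2)
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    for _ in range(lloyd_iterations):
        sv = SphericalVoronoi(pts, radius=1.0, threshold=1e-9)
        sv.sort_vertices_of_regions()
        new = np.array([sv.vertices[reg].mean(axis=0) for reg in sv.regions])
        new /= np.linalg.norm(new, axis=1, keepdims=True)
        if density is None:
            pts = new
        else:
            pts = pts + 0.3 * (new - pts)   # damped: keep the graded density
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    sv = SphericalVoronoi(pts, radius=1.0, threshold=1e-9)
    sv.sort_vertices_of_regions()
    keep = np.flatnonzero(np.arccos(np.clip(pts[:, 2], -1, 1)) <= theta_M)
    used = sorted({v for c in keep for v in sv.regions[c]})
    remap = {v: i for i, v in enumerate(used)}
    vertices = sv.vertices[used] * R
    cells = [np.array([remap[v] for v in sv.regions[c]], dtype=np.intp) for c in keep]
    net = CellNetwork(vertices, cells)
    net.reorient()
    return net


# ---------------------------------------------------------------------------
# Small deterministic fixtures
# ---------------------------------------------------------------------------

def hexagonal_disc(n_rings: int, side: float = 1.0) -> CellNetwork:
    """Flat disc of hexagonal cells: one centre cell plus 6k cells in ring k,
    so N(k) = 1 + 3k(k+1)."""
    a1 = np.array([np.sqrt(3.0), 0.0]) * side
    a2 = np.array([np.sqrt(3.0) / 2.0, 1.5]) * side
    centers = []
    for i in range(-n_rings, n_rings + 1):
        for j in range(-n_rings, n_rings + 1):
            if abs(i + j) <= n_rings:
                centers.append(i * a1 + j * a2)
    hexdirs = np.array([[np.cos(np.pi / 6 + m * np.pi / 3),
                         np.sin(np.pi / 6 + m * np.pi / 3)] for m in range(6)]) * side
    verts: list = []
    vid: dict = {}
    cells = []
    for c in centers:
        loop = []
        for d in hexdirs:
            p = c + d
            key = (round(p[0], 6), round(p[1], 6))
            if key not in vid:
                vid[key] = len(verts)
                verts.append([p[0], p[1], 0.0])
            loop.append(vid[key])
        cells.append(np.array(loop, dtype=np.intp))
    net = CellNetwork(np.array(verts), cells)
    net.reorient(outward=np.array([0.0, 0.0, 1.0]))
    return net


def strip_with_transversal(n_cols: int = 9, n_rows: int = 7, band_rows: int = 3,
                           cell: float = 1.0) -> tuple[CellNetwork, dict]:
    """Rectangular grid with a horizontal band (the boundary strip) and a
    known central transversal column.

    Returns the network plus a ``meta`` dict: band mask, the transversal
    column's cell indices, and the centre cells above/below the band.
    """
    if n_cols % 2 == 0 or band_rows >= n_rows:
        raise ValueError("need an odd column count and band_rows < n_rows")
    verts = np.array([[i * cell, j * cell, 0.0]
                      for j in range(n_rows + 1) for i in range(n_cols + 1)])

    def v(i, j):
        return j * (n_cols + 1) + i

    cells = []
    for j in range(n_rows):
        for i in range(n_cols):
            cells.append(np.array([v(i, j), v(i + 1, j), v(i + 1, j + 1), v(i, j + 1)],
                                  dtype=np.intp))
    net = CellNetwork(verts, cells)
    net.reorient(outward=np.array([0.0, 0.0, 1.0]))
    lo = (n_rows - band_rows) // 2
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = np.tile(np.arange(n_cols), n_rows)
    band = (rows >= lo) & (rows < lo + band_rows)
    mid = n_cols // 2
    transversal = np.flatnonzero(band & (cols == mid))
    center_D = int(np.flatnonzero((rows == n_rows - 1) & (cols == mid))[0])
    center_V = int(np.flatnonzero((rows == 0) & (cols == mid))[0])
    net.region = np.where(band, "DVB", np.where(rows >= lo + band_rows,
                                                "outDVB-D", "outDVB-V")).astype(object)
    meta = {"band": band, "transversal": transversal,
            "center_D": center_D, "center_V": center_V}
    return net, meta


def fixture_suite(seed: int = 0) -> dict:
    """Named small fixtures used across the test suite (all deterministic)."""
    counts = np.array([1, 6, 12, 18, 24, 30])
    cfg = RingCapConfig(R=20.0, ring_counts=counts,
                        boundaries=ring_boundaries_for(20.0, 0.8, counts))
    th = np.radians(np.linspace(-30, 30, 121))
    fixtures = {
        "hex_disc": hexagonal_disc(4),
        "strip": strip_with_transversal()[0],
        "ring_cap_small": generate_ring_cap(cfg),
        "voronoi_cap": generate_cap_tessellation(20.0, 0.8, 60, seed=seed),
        "circle_arc": 10.0 * np.column_stack([np.sin(th), np.cos(th)]),
        "line": np.column_stack([np.linspace(0, 10, 50), np.zeros(50)]),
        "parabola": np.column_stack([np.linspace(-0.2, 0.2, 201),
                                     np.linspace(-0.2, 0.2, 201) ** 2]),
    }
    return fixtures
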
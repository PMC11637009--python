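"""3D apical cell networks: geometry, triangle-method elongation tensors.

A cell is an ordered loop of 3D junction vertices.  Its centroid is the
vertex mean; its area is half the summed norms of the fan-triangle normals
n_i = (v_{i+1} - v_i) x (centroid - v_i); its unit normal is the normalised
sum of the n_i.  Subcellular triangles {v_i, v_{i+1}, centroid} carry the
elongation state: each triangle is the image of a reference equilateral
triangle (area 1) under a shape tensor, whose planar part decomposes into
area, elongation magnitude-and-axis, and in-plane rotation.  The elongation
magnitude is

    |Q| = arcsinh( |S_ts| / sqrt(|S_ta|^2 - |S_ts|^2) )

with S_ts / S_ta the traceless-symmetric and trace-plus-antisymmetric parts
of the planar shape tensor under the coefficient norm
|M| = sqrt(tr(M^T M) / 2) — the unique norm for which |Q| equals the SVD
log-aspect ratio (1/2) ln(sigma1/sigma2) exactly.  Cell elongation is the
area-weighted mean of triangle tensors; directional components contract the
tensor twice with the tangent-projected radial direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellNetwork",
    "cell_geometry",
    "subcellular_triangulation",
    "triangle_elongation",
    "cell_elongation",
    "directional_component",
    "network_elongation_tensors",
]

# reference equilateral triangle with area A0 = 1: side l = sqrt(4/sqrt(3))
_L = np.sqrt(4.0 / np.sqrt(3.0))
_CMAT = np.array([
    [_L, _L / 2.0, 0.0],
    [0.0, np.sqrt(3.0) / 2.0 * _L, 0.0],
    [0.0, 0.0, 1.0],
])
_CMAT_INV = np.linalg.inv(_CMAT)


@dataclass
class CellNetwork:
    """Cells as ordered loops of shared 3D junction vertices."""

    vertices: np.ndarray                  # (V, 3) μm
    cells: list                           # list of intp arrays (vertex loops)
    cell_ids: np.ndarray = field(default=None)   # type: ignore[assignment]
    region: np.ndarray = field(default=None)     # type: ignore[assignment]
    stage: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = [np.asarray(c, dtype=np.intp) for c in self.cells]
        if self.cell_ids is None:
            self.cell_ids = np.arange(len(self.cells))
        self.cell_ids = np.asarray(self.cell_ids)
        if self.region is None:
            self.region = np.array([""] * len(self.cells), dtype=object)
        self.region = np.asarray(self.region, dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        return np.array([self.vertices[c].mean(axis=0) for c in self.cells])

    def geometry(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(centroids, areas, unit normals) for all cells."""
        cen = np.empty((self.n_cells, 3))
        area = np.empty(self.n_cells)
        nrm = np.empty((self.n_cells, 3))
        for i, c in enumerate(self.cells):
            cen[i], area[i], nrm[i] = cell_geometry(self.vertices[c])
        return cen, area, nrm

    # -- topology -----------------------------------------------------------

    def bonds(self) -> dict:
        """Map from undirected junction-vertex pair to the cells sharing it."""
        out: dict[tuple[int, int], list[int]] = {}
        for ci, loop in enumerate(self.cells):
            for a, b in zip(loop, np.roll(loop, -1)):
                key = (int(min(a, b)), int(max(a, b)))
                out.setdefault(key, []).append(ci)
        return out

    def adjacency(self):
        """networkx Graph on cell indices; edges join cells sharing a bond."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        for cells in self.bonds().values():
            for i in range(len(cells)):
                for j in range(i + 1, len(cells)):
                    g.add_edge(cells[i], cells[j])
        return g

    def boundary_cells(self) -> np.ndarray:
        """Cells with at least one bond not shared with another cell."""
        mask = np.zeros(self.n_cells, dtype=bool)
        for cells in self.bonds().values():
            if len(cells) == 1:
                mask[cells[0]] = True
        return np.flatnonzero(mask)

    def reorient(self, outward: np.ndarray | None = None) -> None:
        """Flip loops so normals align with ``outward`` (default: radial)."""
        cen, _, nrm = self.geometry()
        if outward is None:
            ref = cen / np.maximum(np.linalg.norm(cen, axis=1, keepdims=True), 1e-12)
        else:
            ref = np.broadcast_to(np.asarray(outward, float), cen.shape)
        for i, c in enumerate(self.cells):
            if nrm[i] @ ref[i] < 0:
                self.cells[i] = c[::-1].copy()

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, vertices_path, cells_path) -> None:
        rows = []
        for ci, loop in enumerate(self.cells):
            for order, vi in enumerate(loop):
                x, y, z = self.vertices[vi]
                rows.append((self.cell_ids[ci], order, vi, x, y, z))
        pd.DataFrame(rows, columns=["cell_id", "vertex_order", "vertex_id", "x", "y", "z"]
                     ).to_csv(vertices_path, index=False)
        pd.DataFrame({"cell_id": self.cell_ids, "region": self.region,
                      "stage": self.stage}).to_csv(cells_path, index=False)

    @classmethod
    def from_csv(cls, vertices_path, cells_path) -> "CellNetwork":
        vdf = pd.read_csv(vertices_path)
        cdf = pd.read_csv(cells_path)
        vid = vdf["vertex_id"].to_numpy()
        n_v = int(vid.max()) + 1
        verts = np.zeros((n_v, 3))
        verts[vid] = vdf[["x", "y", "z"]].to_numpy()
        cells = []
        order = {cid: i for i, cid in enumerate(cdf["cell_id"])}
        loops: dict = {cid: [] for cid in cdf["cell_id"]}
        for cid, o, vi in zip(vdf["cell_id"], vdf["vertex_order"], vdf["vertex_id"]):
            loops[cid].append((o, vi))
        cells = [np.array([vi for _, vi in sorted(loops[cid])], dtype=np.intp)
                 for cid in cdf["cell_id"]]
        stage = str(cdf["stage"].iloc[0]) if "stage" in cdf and len(cdf) else ""
        return cls(verts, cells, cdf["cell_id"].to_numpy(),
                   cdf["region"].to_numpy(dtype=object), stage)


def cell_geometry(loop: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """(centroid, area, unit normal) of one vertex loop.

    Degenerate (collinear) loops return zero area and a zero normal.
    """
    loop = np.asarray(loop, dtype=float)
    if len(loop) < 3:
        raise ValueError("a cell needs at least three vertices")
    centroid = loop.mean(axis=0)
    n_i = np.cross(np.roll(loop, -1, axis=0) - loop, centroid - loop)
    norms = np.linalg.norm(n_i, axis=1)
    area = 0.5 * float(norms.sum())
    total = n_i.sum(axis=0)
    tnorm = np.linalg.norm(total)
    normal = total / tnorm if tnorm > 0 else np.zeros(3)
    return centroid, area, normal


def subcellular_triangulation(loop: np.ndarray) -> np.ndarray:
    """(N, 3, 3) triangles {v_i, v_{i+1}, centroid}; areas partition the cell."""
    loop = np.asarray(loop, dtype=float)
    centroid = loop.mean(axis=0)
    nxt = np.roll(loop, -1, axis=0)
    return np.stack([loop, nxt, np.broadcast_to(centroid, loop.shape)], axis=1)


def _rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _coeff_norm(M: np.ndarray) -> float:
    return float(np.sqrt(0.5 * np.sum(M * M)))


def triangle_elongation(tri: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Elongation magnitude |Q|, axis angle phi (in the triangle plane), and
    the lab-frame 3x3 elongation tensor of one triangle (rows: 3 vertices)."""
    P0, P1, P2 = np.asarray(tri, dtype=float)
    E1, E2 = P1 - P0, P2 - P0
    cr = np.cross(E1, E2)
    area2 = np.linalg.norm(cr)
    if area2 <= 0:
        raise ValueError("zero-area triangle")
    N = cr / area2
    theta_x = -np.arctan2(N[1], N[2])
    theta_y = np.arctan2(N[0], np.sqrt(max(1.0 - N[0] ** 2, 0.0)))
    U = _rot_x(theta_x) @ _rot_y(theta_y)          # maps z-hat onto N
    S3d = np.column_stack([E1, E2, N]) @ _CMAT_INV
    S_pl = U.T @ S3d
    M = S_pl[:2, :2]
    tr = M[0, 0] + M[1, 1]
    B = np.array([[0.5 * (M[0, 0] - M[1, 1]), 0.5 * (M[0, 1] + M[1, 0])],
                  [0.5 * (M[0, 1] + M[1, 0]), -0.5 * (M[0, 0] - M[1, 1])]])
    T = M - B                                      # trace + antisymmetric part
    nB, nT = _coeff_norm(B), _coeff_norm(T)
    under = nT * nT - nB * nB
    if under <= 0:
        raise ValueError("orientation-reversing or degenerate triangle map")
    q = float(np.arcsinh(nB / np.sqrt(under)))
    # the ts part of M carries angle 2*phi - theta_z; remove the in-plane
    # rotation (from the trace-antisymmetric part) so phi is the axis of the
    # left stretch, which is what transforms covariantly
    theta_z = np.arctan2(T[1, 0], T[0, 0])
    phi = 0.5 * (np.arctan2(B[0, 1], B[0, 0]) + theta_z)
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    Q_pl = q * np.array([[c2, s2, 0.0], [s2, -c2, 0.0], [0.0, 0.0, 0.0]])
    Q_lab = U @ Q_pl @ U.T
    return q, phi, Q_lab


def cell_elongation(loop: np.ndarray) -> np.ndarray:
    """Area-weighted mean of subcellular triangle elongation tensors."""
    tris = subcellular_triangulation(loop)
    areas = np.empty(len(tris))
    Q = np.zeros((len(tris), 3, 3))
    for i, t in enumerate(tris):
        E1, E2 = t[1] - t[0], t[2] - t[0]
        areas[i] = 0.5 * np.linalg.norm(np.cross(E1, E2))
        if areas[i] > 0:
            _, _, Q[i] = triangle_elongation(t)
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate cell (zero area)")
    return np.einsum("t,tij->ij", areas, Q) / total


def directional_component(Q: np.ndarray, centroid: np.ndarray, origin: np.ndarray,
                          normal: np.ndarray) -> float:
    """Radial elongation component Q_rr: the tensor contracted twice with the
    origin-to-centroid direction projected into the cell tangent plane."""
    r = np.asarray(centroid, float) - np.asarray(origin, float)
    r_t = r - (r @ normal) * np.asarray(normal, float)
    nrm = np.linalg.norm(r_t)
    if nrm < 1e-12:
        raise ValueError("cell sits at the origin; radial direction undefined")
    r_t = r_t / nrm
    return float(r_t @ Q @ r_t)


def network_elongation_tensors(net: CellNetwork) -> np.ndarray:
    """(n_cells, 3, 3) elongation tensors for every cell of a network."""
    return np.array([cell_elongation(net.vertices[c]) for c in net.cells])
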
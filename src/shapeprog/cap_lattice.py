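"""Double-layer spring lattices on spherical caps.

The mechanical model of the epithelium is a pair of concentric triangulated
surfaces (apical radius ``R``, basal radius ``R - h``) connected by
programmable springs.  The outer layer is an icosahedral-subdivision sphere
mesh cropped to a spherical cap of half-angle ``theta_M``; the inner layer is
a radially rescaled copy with identical in-layer topology.  Regular vertices
carry 13 springs (6 in-layer + 7 cross-layer: one vertical plus the diagonals
to the in-layer neighbours' copies); the 12 icosahedral point defects carry
11.  The lattice is born stress-free: every rest length equals the as-built
spring length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "CapLattice",
    "compute_cap_angle",
    "build_icosphere",
    "crop_to_cap",
    "make_double_layer",
    "build_from_surface",
    "build_cap_lattice",
]

# spring kind codes
KIND_TOP = 0
KIND_BOTTOM = 1
KIND_CROSS = 2

_KIND_NAMES = {KIND_TOP: "in-layer-top", KIND_BOTTOM: "in-layer-bottom", KIND_CROSS: "cross-layer"}


def compute_cap_angle(w_DV: float, w_ODV: float, R: float) -> float:
    """Half-angle (radians) of the spherical cap approximating a tissue disc.

    ``w_DV`` is the width of the central boundary band, ``w_ODV`` the mean
    in-surface extent of the regions flanking it, and ``R`` the apical radius
    of curvature, all in the same length unit.  The total in-surface diameter
    ``w_DV + 2 w_ODV`` subtends ``2 theta_M`` on a sphere of radius ``R``.
    """
    if R <= 0:
        raise ValueError(f"radius must be positive, got R={R}")
    if w_DV < 0 or w_ODV < 0:
        raise ValueError("widths must be non-negative")
    return 0.5 * (w_DV + 2.0 * w_ODV) / R


@dataclass
class TriMesh:
    """Triangulated surface: ``vertices`` (n, 3) float, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges (k, 2), each row sorted, lexicographic order."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices on edges used by exactly one face."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (outward for consistently wound meshes)."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for k in range(3):
            np.add.at(normals, f[:, k], fn)
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return normals / norms


# ---------------------------------------------------------------------------
# Icosahedral subdivision sphere
# ---------------------------------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.intp,
)


def build_icosphere(refine_factor: int, R: float) -> TriMesh:
    """Sphere mesh from icosahedron edge subdivision into ``refine_factor``
    segments per edge, with every point projected radially to radius ``R``.

    Vertex count is ``10 f^2 + 2`` and face count ``20 f^2``; at f=1 this is
    the bare icosahedron.  All faces are wound with outward normals.
    """
    f = int(refine_factor)
    if f < 1:
        raise ValueError(f"refine_factor must be >= 1, got {refine_factor}")
    if R <= 0:
        raise ValueError(f"radius must be positive, got R={R}")

    verts: list[np.ndarray] = [v for v in _ICO_VERTS]
    index: dict[tuple, int] = {("c", i): i for i in range(12)}

    def edge_key(a: int, b: int, step: int) -> tuple:
        # step counted from vertex a along edge a->b; canonicalise direction
        if a < b:
            return ("e", a, b, step)
        return ("e", b, a, f - step)

    def get_point(key: tuple, bary: np.ndarray, corners: np.ndarray) -> int:
        idx = index.get(key)
        if idx is None:
            idx = len(verts)
            verts.append(bary @ corners)
            index[key] = idx
        return idx

    faces: list[list[int]] = []
    for fi, (a, b, c) in enumerate(_ICO_FACES):
        corners = _ICO_VERTS[[a, b, c]]
        # grid index (i, j): weights (f-i-j, i, j) on corners (a, b, c)
        grid = np.full((f + 1, f + 1), -1, dtype=np.intp)
        for i in range(f + 1):
            for j in range(f + 1 - i):
                w0 = f - i - j
                if w0 == f:
                    key: tuple = ("c", int(a))
                elif i == f:
                    key = ("c", int(b))
                elif j == f:
                    key = ("c", int(c))
                elif j == 0:
                    key = edge_key(int(a), int(b), i)
                elif i == 0:
                    key = edge_key(int(a), int(c), j)
                elif w0 == 0:
                    key = edge_key(int(b), int(c), j)
                else:
                    key = ("f", fi, i, j)
                bary = np.array([w0, i, j], dtype=float) / f
                grid[i, j] = get_point(key, bary, corners)
        for i in range(f):
            for j in range(f - i):
                faces.append([grid[i, j], grid[i + 1, j], grid[i, j + 1]])
                if i + j < f - 1:
                    faces.append([grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]])

    vertices = np.array(verts)
    vertices *= R / np.linalg.norm(vertices, axis=1, keepdims=True)
    face_arr = np.array(faces, dtype=np.intp)

    # enforce outward winding (radial direction is the outward normal)
    v0, v1, v2 = (vertices[face_arr[:, k]] for k in range(3))
    outward = np.einsum("ij,ij->i", np.cross(v1 - v0, v2 - v0), (v0 + v1 + v2) / 3.0)
    flip = outward < 0
    face_arr[flip] = face_arr[flip][:, [0, 2, 1]]
    return TriMesh(vertices, face_arr)


def crop_to_cap(mesh: TriMesh, theta_M: float, axis: np.ndarray | None = None) -> TriMesh:
    """Spherical cap: keep vertices with polar angle <= ``theta_M`` from the
    cap axis (default +z) and faces whose three vertices all survive.
    """
    if not 0 < theta_M <= np.pi:
        raise ValueError(f"theta_M must be in (0, pi], got {theta_M}")
    v = mesh.vertices
    ax = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float) / np.linalg.norm(axis)
    costheta = (v @ ax) / np.linalg.norm(v, axis=1)
    keep = costheta >= np.cos(theta_M) - 1e-12
    if not np.any(keep):
        raise ValueError("cap crop produced an empty mesh")
    new_index = -np.ones(len(v), dtype=np.intp)
    new_index[keep] = np.arange(keep.sum())
    fkeep = np.all(keep[mesh.faces], axis=1)
    faces = new_index[mesh.faces[fkeep]]
    if len(faces) == 0:
        raise ValueError("cap crop produced a degenerate (face-free) mesh")
    # drop vertices not referenced by any surviving face
    used = np.unique(faces)
    if len(used) < keep.sum():
        remap = -np.ones(keep.sum(), dtype=np.intp)
        remap[used] = np.arange(len(used))
        faces = remap[faces]
        verts = v[keep][used]
    else:
        verts = v[keep]
    cap = TriMesh(verts, faces)
    _check_connected(cap)
    return cap


def _check_connected(mesh: TriMesh) -> None:
    n = mesh.n_vertices
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in mesh.edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    roots = {find(i) for i in range(n)}
    if len(roots) != 1:
        raise ValueError(f"cap crop produced {len(roots)} disconnected components")


# ---------------------------------------------------------------------------
# Double-layer lattice
# ---------------------------------------------------------------------------

@dataclass
class CapLattice:
    """Double-layer programmable spring lattice.

    ``vertices`` holds the current positions of both layers (top layer first),
    ``reference`` the as-built stress-free positions.  ``springs`` is (m, 2)
    vertex indices with per-spring ``rest_lengths`` and ``kinds``
    (in-layer-top / in-layer-bottom / cross-layer).  ``top_faces`` triangulate
    the top layer only (used for sectioning and export).
    """

    vertices: np.ndarray
    layer: np.ndarray            # (n,) 0 = top, 1 = bottom
    springs: np.ndarray          # (m, 2) intp
    rest_lengths: np.ndarray     # (m,)
    kinds: np.ndarray            # (m,)
    top_faces: np.ndarray        # (k, 3) indices into top-layer vertices
    R: float
    h: float
    theta_M: float
    reference: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.reference is None:
            self.reference = self.vertices.copy()

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_springs(self) -> int:
        return len(self.springs)

    @property
    def n_top(self) -> int:
        return int(np.sum(self.layer == 0))

    def spring_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        x = self.vertices if positions is None else positions
        return np.linalg.norm(x[self.springs[:, 0]] - x[self.springs[:, 1]], axis=1)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.intp)
        np.add.at(deg, self.springs[:, 0], 1)
        np.add.at(deg, self.springs[:, 1], 1)
        return deg

    def interior_mask(self) -> np.ndarray:
        """True for vertices away from the cap rim (both layers)."""
        top = TriMesh(self.vertices[self.layer == 0], self.top_faces)
        rim = np.zeros(self.n_vertices, dtype=bool)
        bnd = top.boundary_vertices()
        rim[bnd] = True
        rim[bnd + self.n_top] = True
        # cross-layer springs also touch the rim ring's neighbours; interior
        # here means "not on the boundary row", matching the regular 13-degree
        # bulk only one ring further in
        neighbour_of_rim = np.zeros(self.n_vertices, dtype=bool)
        s = self.springs
        touch = rim[s[:, 0]] | rim[s[:, 1]]
        neighbour_of_rim[s[touch, 0]] = True
        neighbour_of_rim[s[touch, 1]] = True
        return ~neighbour_of_rim

    def copy(self) -> "CapLattice":
        return CapLattice(
            self.vertices.copy(), self.layer.copy(), self.springs.copy(),
            self.rest_lengths.copy(), self.kinds.copy(), self.top_faces.copy(),
            self.R, self.h, self.theta_M, self.reference.copy(),
        )

    # -- summaries and export ------------------------------------------------

    def summary(self) -> dict:
        deg = self.degrees()
        lengths = self.spring_lengths()
        hist = {int(d): int(c) for d, c in zip(*np.unique(deg, return_counts=True))}
        return {
            "n_vertices": int(self.n_vertices),
            "n_springs": int(self.n_springs),
            "n_top": int(self.n_top),
            "R": self.R,
            "h": self.h,
            "theta_M_deg": float(np.degrees(self.theta_M)),
            "degree_histogram": hist,
            "modal_degree": int(max(hist, key=hist.get)),
            "edge_length_mean": float(lengths.mean()),
            "edge_length_std": float(lengths.std()),
        }

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def save_vtk(self, path) -> None:
        """Legacy-ASCII VTK polydata: vertices, springs as lines, layer tag
        as point data and spring kind as cell data."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nshapeprog lattice\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {self.n_vertices} double\n")
            for p in self.vertices:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write(f"LINES {self.n_springs} {3 * self.n_springs}\n")
            for i, j in self.springs:
                fh.write(f"2 {i} {j}\n")
            fh.write(f"POINT_DATA {self.n_vertices}\nSCALARS layer int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(l)) for l in self.layer) + "\n")
            fh.write(f"CELL_DATA {self.n_springs}\nSCALARS spring_kind int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(k)) for k in self.kinds) + "\n")

    def save_ply(self, path) -> None:
        """Top-layer surface as ASCII PLY (via trimesh)."""
        import trimesh

        mesh = trimesh.Trimesh(
            vertices=self.vertices[self.layer == 0], faces=self.top_faces, process=False
        )
        mesh.export(path, file_type="ply", encoding="ascii")


def make_double_layer(cap: TriMesh, h: float, R: float | None = None,
                      theta_M: float = np.nan) -> CapLattice:
    """Add a basal layer at radius ``R - h`` below a spherical-cap mesh.

    The bottom layer is the top layer radially rescaled (identical topology).
    Cross-layer springs join each top vertex to its own bottom copy and to the
    bottom copies of its in-layer neighbours (1 + 6 for regular vertices).
    Rest lengths equal as-built lengths, so the fresh lattice carries zero
    elastic energy.
    """
    radii = np.linalg.norm(cap.vertices, axis=1)
    if R is None:
        R = float(radii.mean())
    if not 0 < h < R:
        raise ValueError(f"need 0 < h < R, got h={h}, R={R}")
    n = cap.n_vertices
    bottom = cap.vertices * ((radii - h) / radii)[:, None]
    vertices = np.vstack([cap.vertices, bottom])
    layer = np.concatenate([np.zeros(n, dtype=np.intp), np.ones(n, dtype=np.intp)])
    return _assemble(vertices, layer, cap, n, R, h, theta_M)


def build_from_surface(surface: TriMesh, h: float, normals: np.ndarray | None = None) -> CapLattice:
    """Double-layer lattice from an arbitrary open surface mesh: the second
    layer is offset by ``h`` along the inward normal (-e_h); cross-layer
    topology as in :func:`make_double_layer`.  Warns (without failing) if the
    offset flips any face, i.e. the inner layer self-intersects.
    """
    if h <= 0:
        raise ValueError(f"offset thickness must be positive, got h={h}")
    nrm = surface.vertex_normals() if normals is None else np.asarray(normals, float)
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    n = surface.n_vertices
    bottom = surface.vertices - h * nrm
    # the offset self-intersects where it exceeds the local radius of
    # curvature; estimate curvature per edge as |dn| / |dv|
    e = surface.edges
    dv = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    dn = np.linalg.norm(nrm[e[:, 0]] - nrm[e[:, 1]], axis=1)
    if np.any(h * dn >= dv):
        warnings.warn("normal offset exceeds the local radius of curvature; "
                      "the inner layer self-intersects", RuntimeWarning, stacklevel=2)
    vertices = np.vstack([surface.vertices, bottom])
    layer = np.concatenate([np.zeros(n, dtype=np.intp), np.ones(n, dtype=np.intp)])
    R = float(np.linalg.norm(surface.vertices, axis=1).mean())
    return _assemble(vertices, layer, surface, n, R, h, np.nan)


def _assemble(vertices: np.ndarray, layer: np.ndarray, top: TriMesh, n: int,
              R: float, h: float, theta_M: float) -> CapLattice:
    e = top.edges
    springs = np.vstack([
        e,                                  # in-layer top
        e + n,                              # in-layer bottom
        np.column_stack([np.arange(n), np.arange(n) + n]),   # vertical
        np.column_stack([e[:, 0], e[:, 1] + n]),             # diagonals
        np.column_stack([e[:, 1], e[:, 0] + n]),
    ]).astype(np.intp)
    kinds = np.concatenate([
        np.full(len(e), KIND_TOP), np.full(len(e), KIND_BOTTOM),
        np.full(n + 2 * len(e), KIND_CROSS),
    ]).astype(np.intp)
    lat = CapLattice(vertices, layer, springs, np.empty(len(springs)), kinds,
                     top.faces.copy(), R, h, theta_M)
    lat.rest_lengths = lat.spring_lengths()
    return lat


def build_cap_lattice(refine_factor: int = 30, R: float = 77.66,
                      theta_M: float | None = None, h_over_R: float = 0.1,
                      axis: np.ndarray | None = None) -> CapLattice:
    """One-call construction of the standard cap lattice.

    Defaults reproduce the reference geometry: refine factor 30 at
    R = 77.66 μm (mean spring length ≈ 3.11 μm), cap half-angle 49.63° from
    the tissue dimensions, thickness h = 0.1 R.  ``axis`` selects which region
    of the sphere becomes the cap (used for replicate averaging).
    """
    if theta_M is None:
        theta_M = compute_cap_angle(15.0, 59.77, R)
    sphere = build_icosphere(refine_factor, R)
    if axis is not None:
        # rotate the requested axis onto +z so the crop logic stays identical
        sphere = TriMesh(sphere.vertices @ _rotation_to_z(axis).T, sphere.faces)
    cap = crop_to_cap(sphere, theta_M)
    lat = make_double_layer(cap, h_over_R * R, R=R, theta_M=theta_M)
    return lat


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s, c = np.linalg.norm(v), float(a @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
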
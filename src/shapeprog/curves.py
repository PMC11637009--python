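"""Cross-section curves: arc length, alignment, spline curvature, averaging.

Section curves come either from digitised tissue outlines (ordered x, y
points in μm) or from slicing the top lattice layer with a plane.  Curvature
is computed on a least-squares cubic spline parameterised by arc length with
five fixed interior knots (the curve midpoint and the points at one half and
three quarters of the half-length on either side):

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)

Aligned curves are averaged pointwise on a common arc-length grid with 5 μm
spacing; curvature-change profiles are compared on 40 positions of the
normalised [0, 1] coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .cap_lattice import CapLattice

__all__ = [
    "SectionCurve",
    "section_lattice",
    "arc_length",
    "align_curves",
    "curvature",
    "average_curves",
    "curvature_change",
    "read_curve_csv",
    "write_curve_csv",
]

N_CHANGE_POSITIONS = 40
AVERAGE_SPACING = 5.0  # μm


@dataclass
class SectionCurve:
    """Ordered planar curve with midpoint-centred arc length."""

    points: np.ndarray                 # (n, 2) μm
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) >= 2:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(seg == 0):
                self.points = self.points[np.concatenate([[True], seg > 0])]
                self.s = None
        if self.s is None:
            self.s = arc_length(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.s[-1] - self.s[0])


def arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative polyline arc length, offset so s = 0 at the curve centre
    (half the total length); negative on the left half."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points for an arc length")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        warnings.warn("duplicate consecutive points dropped", RuntimeWarning, stacklevel=2)
        keep = np.concatenate([[True], seg > 0])
        points = points[keep]
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s - s[-1] / 2.0


def section_lattice(lattice: CapLattice, plane: str | tuple = "xz") -> SectionCurve:
    """Intersect top-layer in-layer springs with a plane.

    ``plane`` is "xz" (normal +y), "yz" (normal +x) or a tuple
    ``(normal, offset)``.  Each spring crossing the plane contributes one
    interpolated point; points are ordered by their horizontal coordinate so
    the curve runs counterclockwise (left to right for a dome opening
    downward).
    """
    if plane == "xz":
        normal, offset, axes = np.array([0.0, 1.0, 0.0]), 0.0, (0, 2)
    elif plane == "yz":
        normal, offset, axes = np.array([1.0, 0.0, 0.0]), 0.0, (1, 2)
    else:
        normal, offset = plane
        normal = np.asarray(normal, float)
        normal = normal / np.linalg.norm(normal)
        # horizontal axis: projection of the most-aligned lab axis
        axes = None
    in_top = lattice.kinds == 0
    s = lattice.springs[in_top]
    p = lattice.vertices
    d = p @ normal - offset
    scale = max(float(np.abs(d).max()), 1.0)
    on_plane = np.abs(d) <= 1e-9 * scale
    da, db = d[s[:, 0]], d[s[:, 1]]
    crossing = (da * db) < 0
    t = da[crossing] / (da[crossing] - db[crossing])
    pts3 = p[s[crossing, 0]] + t[:, None] * (p[s[crossing, 1]] - p[s[crossing, 0]])
    # vertices sitting exactly on the plane (e.g. a mesh meridian) are
    # intersection points of all their springs; count each once
    touched = np.unique(s[(on_plane[s[:, 0]] | on_plane[s[:, 1]])].ravel())
    touched = touched[on_plane[touched]]
    if len(touched):
        pts3 = np.vstack([pts3, p[touched]])
    if len(pts3) == 0:
        raise ValueError("plane does not intersect the top layer")
    if axes is not None:
        pts = pts3[:, list(axes)]
    else:
        # build an orthonormal in-plane basis with the third lab axis as "up"
        up = np.array([0.0, 0.0, 1.0])
        u = np.cross(up, normal)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        pts = np.column_stack([pts3 @ u, pts3 @ v])
    order = np.argsort(pts[:, 0], kind="stable")
    return SectionCurve(pts[order])


def align_curves(curves: list[SectionCurve]) -> list[SectionCurve]:
    """Translate each curve's midpoint to the origin and rotate so the new
    y axis passes through the curve's centre of mass; mirror-inconsistent
    curves (signed area of the opposite sense) are flipped."""
    out = []
    for c in curves:
        pts = c.points
        if c.total_length <= 0:
            raise ValueError("degenerate zero-length curve")
        mid = _point_at(c, 0.0)
        pts = pts - mid
        com = pts.mean(axis=0)
        norm = np.linalg.norm(com)
        if norm > 1e-12:
            # rotate com direction onto -y or +y, whichever is nearer
            target = np.array([0.0, np.sign(com[1]) if com[1] != 0 else 1.0])
            u = com / norm
            cosang = u @ target
            sinang = u[0] * target[1] - u[1] * target[0]
            Rm = np.array([[cosang, -sinang], [sinang, cosang]])
            pts = pts @ Rm.T
        # counterclockwise convention: the polyline's net turning is positive
        # (a dome opening towards its centre of mass gets kappa = +1/R)
        seg = np.diff(pts, axis=0)
        turning = np.sum(seg[:-1, 0] * seg[1:, 1] - seg[:-1, 1] * seg[1:, 0])
        if turning < 0:
            pts = pts[::-1].copy()
        out.append(SectionCurve(pts))
    return out


def _point_at(curve: SectionCurve, s: float) -> np.ndarray:
    x = np.interp(s, curve.s, curve.points[:, 0])
    y = np.interp(s, curve.s, curve.points[:, 1])
    return np.array([x, y])


def _spline_pair(curve: SectionCurve):
    s = curve.s
    half = min(-s[0], s[-1])
    knots = np.array([-0.75, -0.5, 0.0, 0.5, 0.75]) * half
    # interior knots must lie strictly inside the data range
    knots = knots[(knots > s[0]) & (knots < s[-1])]
    sx = LSQUnivariateSpline(s, curve.points[:, 0], knots, k=3)
    sy = LSQUnivariateSpline(s, curve.points[:, 1], knots, k=3)
    return sx, sy


def curvature(curve: SectionCurve, s_eval: np.ndarray | None = None) -> np.ndarray:
    """Signed curvature kappa(s) on the five-knot least-squares cubic spline.

    Falls back to finite differences (with a warning) when the curve has too
    few points to support the spline.
    """
    s = curve.s if s_eval is None else np.asarray(s_eval, float)
    if curve.n >= 8:
        sx, sy = _spline_pair(curve)
        x1, y1 = sx(s, 1), sy(s, 1)
        x2, y2 = sx(s, 2), sy(s, 2)
    else:
        warnings.warn("too few points for the spline; finite-difference curvature",
                      RuntimeWarning, stacklevel=2)
        x1 = np.gradient(curve.points[:, 0], curve.s)
        y1 = np.gradient(curve.points[:, 1], curve.s)
        x2 = np.gradient(x1, curve.s)
        y2 = np.gradient(y1, curve.s)
        if s_eval is not None:
            x1, y1 = np.interp(s, curve.s, x1), np.interp(s, curve.s, y1)
            x2, y2 = np.interp(s, curve.s, x2), np.interp(s, curve.s, y2)
    return (x1 * y2 - y1 * x2) / (x1**2 + y1**2) ** 1.5


def average_curves(curves: list[SectionCurve],
                   spacing: float = AVERAGE_SPACING) -> tuple[SectionCurve, np.ndarray, np.ndarray]:
    """Pointwise mean curve and mean curvature profile over the common
    arc-length support, sampled every ``spacing`` μm.

    Returns (mean curve, sample arc lengths, mean curvature).
    """
    if not curves:
        raise ValueError("no curves to average")
    lo = max(c.s[0] for c in curves)
    hi = min(c.s[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves share no common arc-length support")
    grid = np.arange(0.0, min(-lo, hi) + 1e-9, spacing)
    grid = np.concatenate([-grid[:0:-1], grid])
    pts = np.mean([np.column_stack([np.interp(grid, c.s, c.points[:, 0]),
                                    np.interp(grid, c.s, c.points[:, 1])])
                   for c in curves], axis=0)
    kappa = np.mean([curvature(c, grid) for c in curves], axis=0)
    return SectionCurve(pts, grid.copy()), grid, kappa


def curvature_change(s_initial: np.ndarray, kappa_initial: np.ndarray,
                     s_later: np.ndarray, kappa_later: np.ndarray,
                     n_positions: int = N_CHANGE_POSITIONS) -> pd.DataFrame:
    """Curvature change on ``n_positions`` normalised positions.

    Each profile is normalised to [0, 1] along its own support, linearly
    interpolated onto the common positions, and subtracted; the mean of the
    two stages' arc lengths is re-attached per position.
    """
    pos = np.linspace(0.0, 1.0, n_positions)

    def _norm(s):
        return (s - s[0]) / (s[-1] - s[0])

    k0 = np.interp(pos, _norm(s_initial), kappa_initial)
    k1 = np.interp(pos, _norm(s_later), kappa_later)
    arc0 = np.interp(pos, _norm(s_initial), s_initial)
    arc1 = np.interp(pos, _norm(s_later), s_later)
    return pd.DataFrame({
        "position": pos,
        "arc_length_initial": arc0,
        "arc_length_later": arc1,
        "kappa_initial": k0,
        "kappa_later": k1,
        "delta_kappa": k1 - k0,
    })


def read_curve_csv(path) -> SectionCurve:
    df = pd.read_csv(path)
    return SectionCurve(df[["x", "y"]].to_numpy())


def write_curve_csv(curve: SectionCurve, path) -> None:
    pd.DataFrame({"x": curve.points[:, 0], "y": curve.points[:, 1]}).to_csv(path, index=False)
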
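"""Regional coordinate frames and spontaneous-strain programming.

A spontaneous strain is a change of local rest lengths: isotropic factor
``lam`` (area) and anisotropic factor ``lam_t`` (shape at fixed area),
assembled in the regional orthonormal frame (e1, e2, e3) as

    T = lam*lam_t (e1 x e1) + lam/lam_t (e2 x e2) + (e3 x e3)

with e1 the in-surface "radial" direction, e2 the in-surface perpendicular
and e3 the surface normal.  Per-spring tensors are endpoint averages (in lab
coordinates); programmed rest lengths are ``|T_a . dX_a|`` on the stress-free
reference spring vectors, ramped linearly over the quasi-static schedule.

Region layout on the cap (mirroring the tissue): two origin points O_D, O_V
at polar angle theta_DV/2 on either side of the apex; the boundary band (DVB)
is the strip of half-width w_DV/2 around the great circle separating them;
the remaining cap splits into the two flanking (outDVB) halves.  Scalar
coordinates r (outDVB, geodesic distance from the origin point) and rho (DVB,
in-surface distance from the transversal segment O_D-O_V) are normalised to
[0, 1] within each region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cap_lattice import CapLattice

__all__ = [
    "RegionalFrame",
    "SpontaneousStrainField",
    "assign_regions_and_frames",
    "assemble_strain_tensor",
    "spring_strain",
    "target_rest_lengths",
    "ramped_rest_length",
    "preset_patterns",
    "field_from_profile",
    "read_profile_csv",
    "PRESETS",
]

REGION_OUTDVB_D = 0
REGION_OUTDVB_V = 1
REGION_DVB = 2

REGION_NAMES = {REGION_OUTDVB_D: "outDVB-D", REGION_OUTDVB_V: "outDVB-V", REGION_DVB: "DVB"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


@dataclass
class RegionalFrame:
    """Per-vertex region labels, orthonormal bases and scalar coordinates."""

    region: np.ndarray            # (n,) int codes
    e1: np.ndarray                # (n, 3) in-surface radial direction
    e2: np.ndarray                # (n, 3) in-surface perpendicular
    e3: np.ndarray                # (n, 3) surface normal
    coord: np.ndarray             # (n,) r (outDVB) or rho (DVB) in [0, 1]
    origin_D: np.ndarray          # O_D (3,)
    origin_V: np.ndarray          # O_V (3,)
    singular: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.singular is None:
            self.singular = np.zeros(len(self.region), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.region)

    def basis(self) -> np.ndarray:
        """(n, 3, 3) with columns e1, e2, e3."""
        return np.stack([self.e1, self.e2, self.e3], axis=-1)


@dataclass
class SpontaneousStrainField:
    """Per-vertex isotropic/anisotropic factors and assembled 3x3 tensors."""

    lam: np.ndarray               # (n,) isotropic factor
    lam_t: np.ndarray             # (n,) anisotropic factor
    tensor: np.ndarray            # (n, 3, 3) lab-frame tensor
    frame: RegionalFrame

    @property
    def n(self) -> int:
        return len(self.lam)


def _project_tangent(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.einsum("ij,ij->i", v, normal)[:, None] * normal


def _segment_nearest(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest point on segment [a, b] for each row of p."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-30:
        return np.broadcast_to(a, p.shape).copy()
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return a + t[:, None] * ab


def assign_regions_and_frames(lattice: CapLattice, w_DV: float,
                              theta_DV: float | None = None) -> RegionalFrame:
    """Region labels, orthonormal frames and normalised coordinates on a cap.

    ``theta_DV`` defaults to ``w_DV / R`` so that the origins flank the
    boundary band.  With ``w_DV = 0`` (and hence ``theta_DV = 0``) the layout
    degenerates to a single radial coordinate system about the apex with
    r = theta / theta_M.
    """
    R = lattice.R
    if theta_DV is None:
        theta_DV = w_DV / R
    x = lattice.vertices
    radii = np.linalg.norm(x, axis=1)
    u = x / radii[:, None]                       # unit radial = surface normal e3
    half = theta_DV / 2.0
    O_D = R * np.array([np.sin(half), 0.0, np.cos(half)])
    O_V = R * np.array([-np.sin(half), 0.0, np.cos(half)])

    if np.isfinite(lattice.theta_M) and w_DV >= 2.0 * R * lattice.theta_M:
        raise ValueError("w_DV exceeds the cap diameter")

    # angular distance from the dividing great circle (plane x = 0)
    band_angle = np.arcsin(np.clip(u[:, 0], -1.0, 1.0))
    in_band = np.abs(band_angle) * R <= w_DV / 2.0 + 1e-12
    region = np.where(in_band, REGION_DVB,
                      np.where(u[:, 0] > 0, REGION_OUTDVB_D, REGION_OUTDVB_V))
    if w_DV <= 0:
        region = np.where(u[:, 0] >= 0, REGION_OUTDVB_D, REGION_OUTDVB_V)

    uD, uV = O_D / np.linalg.norm(O_D), O_V / np.linalg.norm(O_V)
    ang_D = np.arccos(np.clip(u @ uD, -1.0, 1.0))
    ang_V = np.arccos(np.clip(u @ uV, -1.0, 1.0))

    # in-surface distance to the transversal segment O_D-O_V (the rho origin)
    near = _segment_nearest(x, O_D, O_V)
    near_u = near / np.linalg.norm(near, axis=1)[:, None]
    ang_seg = np.arccos(np.clip(np.einsum("ij,ij->i", u, near_u), -1.0, 1.0))

    e3 = u
    ref = np.empty_like(x)
    is_D = region == REGION_OUTDVB_D
    is_V = region == REGION_OUTDVB_V
    is_B = region == REGION_DVB
    # vectors from the relevant origin, projected to the tangent plane
    vec = np.empty_like(x)
    vec[is_D] = x[is_D] - O_D * (radii[is_D, None] / R)
    vec[is_V] = x[is_V] - O_V * (radii[is_V, None] / R)
    vec[is_B] = x[is_B] - near[is_B] * (radii[is_B, None] / np.linalg.norm(near[is_B], axis=1)[:, None])
    t = _project_tangent(vec, e3)
    tnorm = np.linalg.norm(t, axis=1)
    singular = tnorm < 1e-9 * R
    safe = np.where(singular, 1.0, tnorm)
    e1 = t / safe[:, None]
    if np.any(singular) and np.any(~singular):
        # copy the frame of the nearest regular vertex (origin singularities)
        from scipy.spatial import cKDTree

        tree = cKDTree(x[~singular])
        _, idx = tree.query(x[singular])
        e1[singular] = e1[~singular][idx]
        e1[singular] = _project_tangent(e1[singular], e3[singular])
        e1[singular] /= np.linalg.norm(e1[singular], axis=1)[:, None]
    e2 = np.cross(e3, e1)

    coord = np.empty(len(x))
    geo_out = np.where(is_D, ang_D, ang_V) * R
    for mask, vals in ((is_D, geo_out), (is_V, geo_out), (is_B, ang_seg * R)):
        if np.any(mask):
            m = float(vals[mask].max())
            coord[mask] = vals[mask] / m if m > 0 else 0.0

    return RegionalFrame(region, e1, e2, e3, coord, O_D, O_V, singular)


def assemble_strain_tensor(lam: np.ndarray, lam_t: np.ndarray,
                           frame: RegionalFrame) -> SpontaneousStrainField:
    """Lab-frame tensors ``lam*lam_t e1e1 + lam/lam_t e2e2 + e3e3``."""
    lam = np.broadcast_to(np.asarray(lam, float), (frame.n,)).copy()
    lam_t = np.broadcast_to(np.asarray(lam_t, float), (frame.n,)).copy()
    if np.any(lam <= 0) or np.any(lam_t <= 0):
        raise ValueError("strain factors must be positive")
    # origin vertices have no defined radial axis; anisotropy is switched off
    lam_t[frame.singular] = 1.0
    # T = I + (l11 - 1) e1e1 + (l22 - 1) e2e2: identical to the spectral sum
    # l11 e1e1 + l22 e2e2 + e3e3 but exactly the identity when both factors
    # are 1 (so an identity program leaves rest lengths bitwise unchanged)
    t11 = (lam * lam_t - 1.0)[:, None, None]
    t22 = (lam / lam_t - 1.0)[:, None, None]
    T = (np.broadcast_to(np.eye(3), (frame.n, 3, 3)).copy()
         + t11 * np.einsum("ni,nj->nij", frame.e1, frame.e1)
         + t22 * np.einsum("ni,nj->nij", frame.e2, frame.e2))
    return SpontaneousStrainField(lam, lam_t, T, frame)


def spring_strain(field: SpontaneousStrainField, springs: np.ndarray) -> np.ndarray:
    """Per-spring tensor: lab-frame average of the two endpoint tensors."""
    return 0.5 * (field.tensor[springs[:, 0]] + field.tensor[springs[:, 1]])


def target_rest_lengths(lattice: CapLattice, field: SpontaneousStrainField) -> np.ndarray:
    """Programmed rest lengths ``|T_a . dX_a|`` on reference spring vectors."""
    s = lattice.springs
    dX = lattice.reference[s[:, 1]] - lattice.reference[s[:, 0]]
    if np.any(np.linalg.norm(dX, axis=1) == 0):
        raise ValueError("zero-length spring in reference configuration")
    Ta = spring_strain(field, s)
    return np.linalg.norm(np.einsum("aij,aj->ai", Ta, dX), axis=1)


def ramped_rest_length(delta_I: np.ndarray, delta_F: np.ndarray,
                       T: int, T_F: int) -> np.ndarray:
    """Linear ramp from initial to final rest length over T_F quasi-static steps."""
    if T_F < 1:
        raise ValueError(f"T_F must be >= 1, got {T_F}")
    if not 0 <= T <= T_F:
        raise ValueError(f"step index T={T} outside [0, {T_F}]")
    return delta_I + (np.asarray(delta_F) - delta_I) * (T / T_F)


# ---------------------------------------------------------------------------
# Preset analytic patterns and tabulated profiles
# ---------------------------------------------------------------------------

def _uniform(frame, lam=1.0, lam_t=1.0):
    return np.full(frame.n, lam), np.full(frame.n, lam_t)


def _iso_gradient(frame, a=0.1):
    return 1.0 + a * frame.coord, np.ones(frame.n)


def _aniso_radial(frame, a=0.1):
    return np.ones(frame.n), 1.0 + a * frame.coord


def _aniso_tangential(frame, a=0.1, peak="center"):
    """Tangential extension (contraction along the radial e1).

    ``peak="center"`` concentrates the tangential excess at the origin,
    which flattens the cap centre; ``peak="rim"`` concentrates it at the
    periphery, which sharpens the centre into a trumpet shape.
    """
    w = (1.0 - frame.coord) if peak == "center" else frame.coord
    return np.ones(frame.n), 1.0 / (1.0 + a * w)


PRESETS = {
    "uniform": _uniform,
    "iso_gradient": _iso_gradient,
    "aniso_radial": _aniso_radial,
    "aniso_tangential": _aniso_tangential,
}


def preset_patterns(name: str, frame: RegionalFrame, **params) -> SpontaneousStrainField:
    """Analytic strain patterns evaluated on the lattice vertices."""
    try:
        fn = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    lam, lam_t = fn(frame, **params)
    return assemble_strain_tensor(lam, lam_t, frame)


def read_profile_csv(path) -> pd.DataFrame:
    """Tabulated strain profile with columns (region, coordinate, lambda_iso,
    lambda_aniso); coordinates are r (outDVB) or rho (DVB)."""
    df = pd.read_csv(path)
    required = {"region", "coordinate", "lambda_iso", "lambda_aniso"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    return df


def field_from_profile(profile: pd.DataFrame, frame: RegionalFrame) -> SpontaneousStrainField:
    """Interpolate a tabulated (region, coordinate) profile onto vertices.

    Linear in the region's coordinate with end values clamped.  Region names
    in the table may be 'outDVB' (applied to both halves), 'outDVB-D',
    'outDVB-V' or 'DVB'.
    """
    lam = np.ones(frame.n)
    lam_t = np.ones(frame.n)
    groups = {name: g.sort_values("coordinate") for name, g in profile.groupby("region")}
    for code, mask in ((REGION_OUTDVB_D, frame.region == REGION_OUTDVB_D),
                       (REGION_OUTDVB_V, frame.region == REGION_OUTDVB_V),
                       (REGION_DVB, frame.region == REGION_DVB)):
        if not np.any(mask):
            continue
        name = REGION_NAMES[code]
        g = groups.get(name)
        if g is None and code in (REGION_OUTDVB_D, REGION_OUTDVB_V):
            g = groups.get("outDVB")
        if g is None:
            raise ValueError(f"profile has no rows for region {name!r}")
        xs = g["coordinate"].to_numpy()
        lam[mask] = np.interp(frame.coord[mask], xs, g["lambda_iso"].to_numpy())
        lam_t[mask] = np.interp(frame.coord[mask], xs, g["lambda_aniso"].to_numpy())
    return assemble_strain_tensor(lam, lam_t, frame)
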
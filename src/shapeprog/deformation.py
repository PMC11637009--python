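"""Per-vertex deformation gradients, in-plane decomposition, residual strain.

For each vertex the deformation gradient ``F`` is the 3x3 tensor best
mapping the stress-free reference spring vectors onto the current ones in
the least-squares sense (ordinary least squares, solved per spatial
component).  In the local regional frame its in-plane diagonal entries give
the isotropic and anisotropic components; by default these are the
square-root forms

    F_iso = sqrt(F_rr * F_pp),   F_aniso = sqrt(F_rr / F_pp)

which compose multiplicatively with the (lam, lam_t) convention of the
spontaneous strain (the product convention without the square root is
available via ``convention="printed"``).  The residual strain is
``F . inv(T)`` against the programmed tensor ``T``: identity when the
programmed strain is realised exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cap_lattice import CapLattice
from .strain_frames import RegionalFrame, SpontaneousStrainField

__all__ = [
    "DeformationField",
    "fit_deformation_gradient",
    "deformation_field",
    "decompose_inplane",
    "residual_strain",
]

OFFDIAG_WARN = 0.05


@dataclass
class DeformationField:
    F: np.ndarray             # (n, 3, 3) deformation gradients
    residual: np.ndarray      # (n,) least-squares residual S per vertex
    rank_deficient: np.ndarray  # (n,) bool flags


def _neighbor_lists(lattice: CapLattice) -> list[np.ndarray]:
    n = lattice.n_vertices
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for a, b in lattice.springs:
        nbrs[a].append(b)
        nbrs[b].append(a)
    return [np.array(v, dtype=np.intp) for v in nbrs]


def fit_deformation_gradient(reference: np.ndarray, current: np.ndarray,
                             vertex: int, neighbors: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """OLS fit of F minimising sum_a |F X_a - x_a|^2 over springs at a vertex.

    ``X_a`` are reference spring vectors, ``x_a`` current ones.  Returns the
    tensor, the residual sum of squares, and a rank-deficiency flag (the
    pseudo-inverse solution is still returned when flagged).
    """
    X = reference[neighbors] - reference[vertex]
    x = current[neighbors] - current[vertex]
    F_t, res, rank, _ = np.linalg.lstsq(X, x, rcond=None)
    deficient = rank < 3
    S = float(np.sum((X @ F_t - x) ** 2))
    return F_t.T, S, deficient


def deformation_field(lattice: CapLattice, positions: np.ndarray | None = None) -> DeformationField:
    """Deformation gradients at every vertex of the lattice.

    Reference spring vectors come from the stress-free reference positions,
    current ones from ``positions`` (default: the lattice's present state).
    """
    cur = lattice.vertices if positions is None else np.asarray(positions, float)
    ref = lattice.reference
    nbrs = _neighbor_lists(lattice)
    n = lattice.n_vertices
    F = np.empty((n, 3, 3))
    S = np.empty(n)
    bad = np.zeros(n, dtype=bool)
    for v in range(n):
        F[v], S[v], bad[v] = fit_deformation_gradient(ref, cur, v, nbrs[v])
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} vertices have rank-deficient spring "
                      "neighborhoods; pseudo-inverse solutions returned",
                      RuntimeWarning, stacklevel=2)
    return DeformationField(F, S, bad)


def decompose_inplane(F: np.ndarray, frame: RegionalFrame,
                      convention: str = "sqrt", warn_offdiag: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic and anisotropic in-plane components of per-vertex tensors.

    Rotates each tensor into the local frame, polar-decomposes the in-plane
    2x2 block (discarding the rotation factor, so rigid in-plane rotations
    decompose to 1), reads the stretch diagonal F_rr, F_pp and combines them
    per the chosen convention ("sqrt" default, "printed" for the plain
    products).  Warns if in-plane off-diagonal (shear) components exceed
    |0.05| anywhere.
    """
    F = np.asarray(F)
    single = F.ndim == 2
    if single:
        F = F[None]
    e1, e2 = frame.e1, frame.e2
    if single and e1.ndim == 2 and len(e1) != 1:
        raise ValueError("frame and tensor counts disagree")
    # in-plane 2x2 block in the local frame, with the in-plane rotation
    # factored out (right polar stretch), so rigid rotations read as identity
    M = np.empty((len(F), 2, 2))
    M[:, 0, 0] = np.einsum("ni,nij,nj->n", e1, F, e1)
    M[:, 0, 1] = np.einsum("ni,nij,nj->n", e1, F, e2)
    M[:, 1, 0] = np.einsum("ni,nij,nj->n", e2, F, e1)
    M[:, 1, 1] = np.einsum("ni,nij,nj->n", e2, F, e2)
    W, sig, Vt = np.linalg.svd(M)
    # right stretch U = V diag(sig) V^T (flip a singular direction if the
    # block is orientation-reversing so U stays the symmetric factor of M)
    det = np.linalg.det(M)
    sig = sig.copy()
    sig[:, 1] = np.where(det < 0, -sig[:, 1], sig[:, 1])
    V = Vt.transpose(0, 2, 1)
    U = np.einsum("nij,nj,nkj->nik", V, sig, V)
    Frr, Fpp = U[:, 0, 0], U[:, 1, 1]
    if np.any(Frr <= 0) or np.any(Fpp <= 0):
        raise ValueError("non-positive in-plane diagonal entries")
    Frp = U[:, 0, 1]
    Fpr = U[:, 1, 0]
    if warn_offdiag and max(np.abs(Frp).max(initial=0), np.abs(Fpr).max(initial=0)) > OFFDIAG_WARN:
        warnings.warn("in-plane off-diagonal components exceed 0.05; the "
                      "diagonal decomposition may be unreliable",
                      RuntimeWarning, stacklevel=2)
    if convention == "sqrt":
        iso, aniso = np.sqrt(Frr * Fpp), np.sqrt(Frr / Fpp)
    elif convention == "printed":
        iso, aniso = Frr * Fpp, Frr / Fpp
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if single:
        return iso[0], aniso[0]
    return iso, aniso


def residual_strain(F: np.ndarray, programmed: SpontaneousStrainField,
                    convention: str = "sqrt") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual strain ``F . inv(T)`` and its (iso, aniso) components.

    Identity wherever the relaxed deformation realises the programmed strain
    exactly; the anisotropic component proxies for leftover deviatoric
    stress.
    """
    T = programmed.tensor
    if np.any(np.abs(np.linalg.det(T)) < 1e-30):
        raise np.linalg.LinAlgError("programmed strain tensor is singular")
    res = np.einsum("nij,njk->nik", F, np.linalg.inv(T))
    iso, aniso = decompose_inplane(res, programmed.frame, convention=convention,
                                   warn_offdiag=False)
    return res, iso, aniso
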
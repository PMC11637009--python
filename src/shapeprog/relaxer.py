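"""Quasi-static overdamped relaxation of the programmed spring lattice.

Elastic energy  W = 1/2 sum_a k (delta_a - deltaT_a)^2  over all springs;
vertices follow overdamped gradient descent

    x_alpha <- x_alpha - dtau (k/gamma) sum_a (delta_a - deltaT_a) u_a

with u_a the unit vector along spring a pointing away from the partner
vertex.  The inner loop runs until the mean per-step displacement relative to
the cap radius drops below the tolerance; rest lengths are ramped linearly
from their initial to their programmed values over ``T_F`` quasi-static
steps, with a full force balance reached inside each step.  Updates are
synchronous and the iteration is free of randomness, so identical inputs
give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cap_lattice import CapLattice
from .strain_frames import SpontaneousStrainField, ramped_rest_length, target_rest_lengths

__all__ = ["RelaxConfig", "RelaxReport", "energy", "relax_to_force_balance", "run_program"]


@dataclass
class RelaxConfig:
    k: float = 1.0                    # spring constant (only step_factor matters)
    gamma: float = 1.0                # friction coefficient
    step_factor: float = 0.01         # dtau * k / gamma
    tolerance: float = 1e-9           # on <|dx|> / R per update step
    T_F: int = 5                      # quasi-static steps for the rest-length ramp
    max_iterations: int = 5_000_000   # inner-loop guard
    record_every: int = 10_000        # energy-trace sampling stride

    def __post_init__(self) -> None:
        if self.step_factor <= 0:
            raise ValueError("step_factor must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RelaxReport:
    iterations: int
    converged: bool
    final_energy: float
    final_mean_step: float            # <|dx|>/R at the last iteration
    energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def energy(lattice: CapLattice, positions: np.ndarray | None = None, k: float = 1.0,
           rest_lengths: np.ndarray | None = None) -> float:
    """Total elastic energy  1/2 sum_a k (delta_a - deltaT_a)^2."""
    rest = lattice.rest_lengths if rest_lengths is None else rest_lengths
    d = lattice.spring_lengths(positions)
    return 0.5 * k * float(np.sum((d - rest) ** 2))


def _incidence(lattice: CapLattice) -> sp.csr_matrix:
    """Signed incidence matrix (n_vertices x n_springs): +1 at the first
    endpoint, -1 at the second, so that grad = M @ (force-per-spring)."""
    m = lattice.n_springs
    s = lattice.springs
    rows = np.concatenate([s[:, 0], s[:, 1]])
    cols = np.tile(np.arange(m), 2)
    data = np.concatenate([np.ones(m), -np.ones(m)])
    return sp.csr_matrix((data, (rows, cols)), shape=(lattice.n_vertices, m))


def relax_to_force_balance(lattice: CapLattice, config: RelaxConfig | None = None,
                           incidence: sp.csr_matrix | None = None) -> RelaxReport:
    """Gradient-descent relaxation to force balance (modifies positions in place).

    Returns an iteration report with a sampled energy trace.  Non-convergence
    within ``max_iterations`` is reported (``converged=False``) and the
    partial state is kept.
    """
    cfg = config or RelaxConfig()
    M = _incidence(lattice) if incidence is None else incidence
    x = lattice.vertices
    s = lattice.springs
    rest = lattice.rest_lengths
    step = cfg.step_factor
    tol = cfg.tolerance
    R = lattice.R
    n = lattice.n_vertices

    energies = [energy(lattice, k=cfg.k)]
    mean_step = np.inf
    it = 0
    while it < cfg.max_iterations:
        d = x[s[:, 0]] - x[s[:, 1]]
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        f = (dist - rest) / dist
        grad = M @ (f[:, None] * d)            # (n, 3)
        dx = step * grad
        x -= dx
        it += 1
        mean_step = float(np.mean(np.sqrt(np.einsum("ij,ij->i", dx, dx)))) / R
        if it % cfg.record_every == 0:
            energies.append(energy(lattice, k=cfg.k))
        if mean_step <= tol:
            break
    energies.append(energy(lattice, k=cfg.k))
    return RelaxReport(it, mean_step <= tol, energies[-1], mean_step, np.array(energies))


def run_program(lattice: CapLattice, strain: SpontaneousStrainField,
                config: RelaxConfig | None = None) -> tuple[list[CapLattice], list[RelaxReport]]:
    """Program rest lengths from a spontaneous-strain field and relax.

    The programmed rest lengths ``deltaF`` are reached through ``T_F``
    quasi-static steps of the linear ramp, each relaxed to force balance.
    Returns the trajectory of balanced lattices (T = 0 .. T_F, index 0 being
    the input state) and the per-step relaxation reports.
    """
    cfg = config or RelaxConfig()
    delta_I = lattice.rest_lengths.copy()
    delta_F = target_rest_lengths(lattice, strain)
    M = _incidence(lattice)
    trajectory = [lattice.copy()]
    reports: list[RelaxReport] = []
    for T in range(1, cfg.T_F + 1):
        lattice.rest_lengths = ramped_rest_length(delta_I, delta_F, T, cfg.T_F)
        reports.append(relax_to_force_balance(lattice, cfg, incidence=M))
        trajectory.append(lattice.copy())
    return trajectory, reports
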
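"""Shared fixtures: small lattices and cell networks, all deterministic."""

import numpy as np
import pytest

from shapeprog.cap_lattice import build_cap_lattice
from shapeprog.synth import (RingCapConfig, generate_ring_cap, hexagonal_disc,
                             ring_boundaries_for, strip_with_transversal)


@pytest.fixture(scope="session")
def cap_f5():
    """Small double-layer cap (refine factor 5, tissue geometry)."""
    return build_cap_lattice(refine_factor=5)


@pytest.fixture(scope="session")
def cap_f10():
    """Reduced production cap (refine factor 10)."""
    return build_cap_lattice(refine_factor=10)


@pytest.fixture(scope="session")
def hex_disc():
    """Flat hexagonal disc with 4 rings (61 cells)."""
    return hexagonal_disc(4)


@pytest.fixture(scope="session")
def strip():
    """Rectangular grid with a central band and known transversal."""
    return strip_with_transversal()


@pytest.fixture(scope="session")
def ring_cap_small():
    """Ring-structured cap tessellation with 91 cells."""
    counts = np.array([1, 6, 12, 18, 24, 30])
    cfg = RingCapConfig(20.0, counts, ring_boundaries_for(20.0, 0.8, counts))
    return generate_ring_cap(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
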
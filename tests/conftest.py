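"""Shared fixtures: small text systems and synthetic ground-truth runs."""

from __future__ import annotations

import numpy as np
import pytest

from poredyn import (
    AtomGroup,
    PoreSystemSpec,
    ScpnSpec,
    Topology,
    Trajectory,
    build_scpn_topology,
    simulate_pore_system,
)

THREE_WATERS_GRO = """three waters
9
    1SOL     OW    1   1.000   1.000   1.000
    1SOL    HW1    2   1.080   1.000   1.000
    1SOL    HW2    3   1.000   1.080   1.000
    2SOL     OW    4   2.000   2.000   2.000
    2SOL    HW1    5   2.080   2.000   2.000
    2SOL    HW2    6   2.000   2.080   2.000
    3SOL     OW    7   0.500   0.500   0.500
    3SOL    HW1    8   0.580   0.500   0.500
    3SOL    HW2    9   0.500   0.580   0.500
   3.00000   3.00000   3.00000
"""


@pytest.fixture
def three_waters_gro(tmp_path):
    p = tmp_path / "waters.gro"
    p.write_text(THREE_WATERS_GRO)
    return p


@pytest.fixture(scope="session")
def scpn_8x8():
    """Idealized 8-ring, 8-amide stack: topology, coords, box."""
    return build_scpn_topology(ScpnSpec(n_rings=8, amides_per_ring=8))


@pytest.fixture(scope="session")
def pore_system():
    """Small membrane-pore run with ground truth (shared, read-only)."""
    spec = PoreSystemSpec(n_waters=400, n_cations=12, n_anions=12, n_steps=150, seed=42)
    return simulate_pore_system(spec)


@pytest.fixture(scope="session")
def free_walkers():
    """Free Brownian walkers (no membrane) for diffusion/RDF checks."""
    spec = PoreSystemSpec(
        D_water=2.3e-9, box=(8.0, 8.0, 8.0), membrane_slab=None, pore_radius=0.0,
        n_waters=600, n_cations=40, n_anions=0, dt=5.0, n_steps=300, seed=9,
    )
    return simulate_pore_system(spec)


def random_water_topology(n_waters: int, rng: np.random.Generator, box: float = 3.0):
    """Random 3-site waters (O + 2 H at 0.1 nm) for brute-force oracles."""
    names, resnames, resids, elements, roles = [], [], [], [], []
    coords = []
    for i in range(n_waters):
        o = rng.uniform(0, box, size=3)
        for name, elem, role, pos in (
            ("OW", "O", "water_oxygen", o),
            ("HW1", "H", "water_hydrogen", o + 0.1 * _unit(rng)),
            ("HW2", "H", "water_hydrogen", o + 0.1 * _unit(rng)),
        ):
            names.append(name)
            resnames.append("SOL")
            resids.append(i + 1)
            elements.append(elem)
            roles.append(role)
            coords.append(pos)
    top = Topology(
        atom_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        ring_index=np.full(len(names), -1),
    )
    return top, np.asarray(coords), np.full(3, box)


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
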
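"""Shared fixtures: small synthetic structures and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from trajnet.pipeline import default_planted_bonds
from trajnet.structio import Atom, Structure, Topology, Trajectory, mass_of
from trajnet.synthetic_data import ComplexSpec, make_toy_complex


def make_atoms(spec: list[tuple[str, str, str, int, str]]) -> Topology:
    """Build a topology from (name, element, resname, resid, chain) tuples."""
    atoms = [
        Atom(i + 1, name, elem, resname, resid, chain, mass_of(elem))
        for i, (name, elem, resname, resid, chain) in enumerate(spec)
    ]
    return Topology(atoms)


@pytest.fixture
def dipeptide_topology() -> Topology:
    """Two-residue protein chain A with backbone + one hydrogen each."""
    spec = []
    for resid in (1, 2):
        spec += [
            ("N", "N", "ALA", resid, "A"),
            ("H", "H", "ALA", resid, "A"),
            ("CA", "C", "ALA", resid, "A"),
            ("C", "C", "ALA", resid, "A"),
            ("O", "O", "ALA", resid, "A"),
        ]
    return make_atoms(spec)


@pytest.fixture
def toy_complex():
    """Standard planted toy complex: 5+5 ligand bonds and 1 dimer bond."""
    spec = ComplexSpec(planted_hbonds=default_planted_bonds(), seed=0)
    return make_toy_complex(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def constant_trajectory(topology: Topology, coords: np.ndarray, n_frames: int = 5):
    return Trajectory(topology, np.repeat(coords[None], n_frames, axis=0))
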
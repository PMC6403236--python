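"""Synthetic structures, trajectories and fixtures with planted ground truth.

This module generates every input the analysis pipeline needs, with the
statistical structure the analyses assume, so that each stage can be tested
against a known truth without any external data:

* toy two-chain "horseshoe" complexes with an optional two-strand duplex
  ligand and hydrogen bonds planted at defined interaction sites
  (N-terminal, C-terminal, dimer interface) that satisfy the 0.35 nm / 30°
  criteria by construction;
* Gaussian trajectories with planted low-rank fluctuation modes (the
  oracle for covariance/PCA recovery);
* graph fixtures with analytically known betweenness centrality;
* nonbonded parameter fixtures (null, unit-charge and bounded-random
  schemes).

Every generator is deterministic given its spec and seed.  Toy residues are
idealised (4–6 atoms) rather than full amino acids: sufficient to exercise
every geometric, energetic and network operator while keeping fixtures
readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .network import ResidueGraph
from .structio import (
    Atom,
    NonbondedParams,
    Structure,
    Topology,
    Trajectory,
    TrajnetError,
    mass_of,
)


class SyntheticDataError(TrajnetError):
    pass


# --------------------------------------------------------------------------- #
# Toy complex with planted hydrogen bonds
# --------------------------------------------------------------------------- #

SITES = ("N-terminal", "C-terminal", "dimer")


@dataclass(frozen=True)
class PlantedHBond:
    """One planted donor→acceptor hydrogen bond at a named interaction site."""

    donor: tuple[str, int]  # (chain, resid) — must be a protein residue
    acceptor: tuple[str, int]
    site: str = "N-terminal"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise SyntheticDataError(f"unknown site {self.site!r}; use one of {SITES}")


@dataclass
class ComplexSpec:
    """Blueprint for a toy receptor–ligand complex.

    Two arc-shaped protein chains mimic the horseshoe fold of a leucine-rich
    repeat ectodomain dimer; the optional ladder ligand mimics a duplex
    nucleic acid bound between them.  ``planted_hbonds`` place ideal-geometry
    hydrogen bonds at the three interaction sites; all other cross-group
    donor–acceptor distances stay above 0.4 nm.
    """

    n_residues_per_chain: int = 24
    protein_chains: tuple[str, str] = ("A", "B")
    include_ligand: bool = True
    n_ligand_bp: int = 12
    ligand_chains: tuple[str, str] = ("R", "S")
    planted_hbonds: list[PlantedHBond] = field(default_factory=list)
    seed: int = 0
    jitter_nm: float = 0.015


_PROTEIN_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([-0.06, -0.08, 0.0]),
    "CA": np.array([0.15, 0.0, 0.0]),
    "C": np.array([0.25, 0.10, 0.0]),
    "O": np.array([0.25, 0.25, 0.0]),
}

_NUCLEIC_OFFSETS = {
    "P": np.array([0.0, 0.0, 0.0]),
    "O5'": np.array([0.15, 0.0, 0.0]),
    "C5'": np.array([0.28, 0.08, 0.0]),
    "C4'": np.array([0.40, 0.16, 0.0]),
    "C3'": np.array([0.50, 0.28, 0.0]),
    "O3'": np.array([0.58, 0.40, 0.0]),
}


def _protein_arc_positions(n: int, z: float, rng: np.random.Generator, jitter: float):
    # Horseshoe arc: 240° sweep, radius chosen to keep base spacing >= 0.6 nm.
    sweep = np.deg2rad(240.0)
    radius = max(3.0, 0.62 * n / sweep)
    angles = np.linspace(0.0, sweep, n)
    pts = np.column_stack(
        (radius * np.cos(angles), radius * np.sin(angles), np.full(n, z))
    )
    return pts + rng.uniform(-jitter, jitter, size=pts.shape)


def make_toy_complex(spec: ComplexSpec) -> tuple[Trajectory, dict]:
    """Build a single-frame toy complex with planted hydrogen bonds.

    Returns the one-frame trajectory and a JSON-able "truth" dict recording
    the planted bonds and per-group-pair counts, for consumption by tests
    and the pipeline.  Raises on infeasible plantings (reused donors or
    acceptor atoms, unknown residues, accidental extra contacts).
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    atom_lookup: dict[tuple[str, int, str], int] = {}
    serial = 1

    def add_residue(chain: str, resid: int, resname: str, base: np.ndarray, offsets):
        nonlocal serial
        for name, off in offsets.items():
            element = "H" if name == "H" else name[0]
            atoms.append(
                Atom(serial, name, element, resname, resid, chain, mass_of(element))
            )
            atom_lookup[(chain, resid, name)] = len(coords)
            coords.append(base + off)
            serial += 1

    n = spec.n_residues_per_chain
    if n < 4:
        raise SyntheticDataError("need at least 4 residues per chain")
    for chain, z in zip(spec.protein_chains, (0.0, 2.0)):
        pts = _protein_arc_positions(n, z, rng, spec.jitter_nm)
        for i in range(n):
            add_residue(chain, i + 1, "ALA", pts[i], _PROTEIN_OFFSETS)
    if spec.include_ligand:
        for chain, x in zip(spec.ligand_chains, (-0.5, 0.5)):
            for i in range(spec.n_ligand_bp):
                base = np.array([x, 0.0, 0.1 + 0.55 * i])
                base = base + rng.uniform(-spec.jitter_nm, spec.jitter_nm, 3)
                resname = "A" if (i % 2 == 0) else "U"
                add_residue(chain, i + 1, resname, base, _NUCLEIC_OFFSETS)

    xyz = np.array(coords)

    # Plant the requested hydrogen bonds: reposition the acceptor atom on the
    # donor N → acceptor-base line at 0.30 nm and align the donor hydrogen
    # with it (H–D–A angle 0°, d(D,A) = 0.30 nm ≤ 0.35 nm).
    used_donors: set[tuple[str, int]] = set()
    used_acceptors: set[tuple[str, int]] = set()
    protein_set = set(spec.protein_chains)
    planted_records = []
    for hb in spec.planted_hbonds:
        dchain, dresid = hb.donor
        achain, aresid = hb.acceptor
        if dchain not in protein_set:
            raise SyntheticDataError(
                f"donor {hb.donor} must be a protein residue (ligand has no H)"
            )
        if hb.donor in used_donors:
            raise SyntheticDataError(f"donor residue {hb.donor} planted twice")
        if hb.acceptor in used_acceptors:
            raise SyntheticDataError(f"acceptor residue {hb.acceptor} planted twice")
        used_donors.add(hb.donor)
        used_acceptors.add(hb.acceptor)
        try:
            d_idx = atom_lookup[(dchain, dresid, "N")]
            h_idx = atom_lookup[(dchain, dresid, "H")]
        except KeyError:
            raise SyntheticDataError(f"no donor residue {hb.donor}") from None
        acc_name = "O" if achain in protein_set else "O5'"
        try:
            a_idx = atom_lookup[(achain, aresid, acc_name)]
        except KeyError:
            raise SyntheticDataError(f"no acceptor residue {hb.acceptor}") from None
        u = xyz[a_idx] - xyz[d_idx]
        norm = np.linalg.norm(u)
        if norm == 0:
            raise SyntheticDataError("coincident donor and acceptor bases")
        u /= norm
        xyz[a_idx] = xyz[d_idx] + 0.30 * u
        xyz[h_idx] = xyz[d_idx] + 0.10 * u
        planted_records.append(
            {
                "donor": f"{dchain}:{dresid}",
                "acceptor": f"{achain}:{aresid}",
                "site": hb.site,
                "donor_atom": int(d_idx),
                "hydrogen_atom": int(h_idx),
                "acceptor_atom": int(a_idx),
            }
        )

    topology = Topology(atoms)
    traj = Trajectory(topology, xyz[None, :, :], timestep_ps=10.0)
    _validate_planting(traj, planted_records, spec)

    counts: dict[str, int] = {}
    for rec in planted_records:
        ca = rec["donor"].split(":")[0]
        cb = rec["acceptor"].split(":")[0]
        key = "-".join(sorted((ca, cb)))
        counts[key] = counts.get(key, 0) + 1
    truth = {
        "planted_hbonds": planted_records,
        "pair_counts": counts,
        "protein_chains": list(spec.protein_chains),
        "ligand_chains": list(spec.ligand_chains) if spec.include_ligand else [],
        "seed": spec.seed,
    }
    return traj, truth


def _validate_planting(traj: Trajectory, records: list[dict], spec: ComplexSpec) -> None:
    """Reject overcrowded specs: besides planted pairs, every cross-group
    donor–acceptor distance must exceed 0.4 nm."""
    from .hbond import detect_hbonds, infer_donors_acceptors

    das = infer_donors_acceptors(traj)
    planted = {(r["donor_atom"], r["acceptor_atom"]) for r in records}
    chains = traj.topology.chains
    coords = traj.coords[0]
    for d, _h in das.donor_pairs:
        for a in das.acceptors:
            if chains[d] == chains[a]:
                continue
            if (int(d), int(a)) in planted:
                continue
            if np.linalg.norm(coords[d] - coords[a]) <= 0.4:
                raise SyntheticDataError(
                    "infeasible planting: unplanted cross-group donor–acceptor "
                    f"pair ({int(d)}, {int(a)}) within 0.4 nm"
                )
    bonds = detect_hbonds(coords, das)
    cross = {
        (b.donor, b.acceptor) for b in bonds if chains[b.donor] != chains[b.acceptor]
    }
    if cross != planted:
        raise SyntheticDataError(
            f"planting failed: detected cross-group bonds {cross} != planted {planted}"
        )


def write_truth(truth: dict, path: str | Path) -> None:
    """Write the planted-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------- #
# Planted-mode Gaussian trajectories
# --------------------------------------------------------------------------- #


@dataclass
class FluctuationSpec:
    """Low-rank Gaussian fluctuation model for a reference structure.

    ``modes`` is a (k, 3N) row-orthonormal array of displacement directions
    with per-mode variances (nm²); ``noise_sigma`` is the std (nm) of the
    isotropic background added to every coordinate.  Frame spacing defaults
    to 10 ps, the usual sampling interval for essential-dynamics analysis.
    """

    n_frames: int
    modes: np.ndarray
    variances: np.ndarray
    noise_sigma: float = 0.0
    timestep_ps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if self.modes.shape[0] != self.variances.size:
            raise SyntheticDataError("one variance per mode required")
        if np.any(self.variances < 0):
            raise SyntheticDataError("variances must be non-negative")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.modes.shape[0]), atol=1e-8):
            raise SyntheticDataError("mode directions must be orthonormal")


def make_gaussian_trajectory(
    reference: Structure, spec: FluctuationSpec
) -> Trajectory:
    """Sample frames x_t = ref + Σ_m a_{t,m}·v_m + ε_t with a ~ N(0, var_m)
    and isotropic Gaussian noise ε; bit-reproducible for a fixed seed."""
    n_dof = reference.coords.size
    if spec.modes.shape[1] != n_dof:
        raise SyntheticDataError(
            f"modes have {spec.modes.shape[1]} dof, structure has {n_dof}"
        )
    rng = np.random.default_rng(spec.seed)
    amps = rng.normal(
        0.0, np.sqrt(spec.variances), size=(spec.n_frames, spec.variances.size)
    )
    disp = amps @ spec.modes
    if spec.noise_sigma > 0:
        disp = disp + rng.normal(0.0, spec.noise_sigma, size=disp.shape)
    frames = reference.coords.reshape(1, -1) + disp
    coords = frames.reshape(spec.n_frames, -1, 3)
    return Trajectory(
        reference.topology, coords, timestep_ps=spec.timestep_ps
    )


def rigid_body_subspace(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of rigid translations and rotations about
    the geometric centre of ``coords`` (N, 3)."""
    n = coords.shape[0]
    com = coords.mean(axis=0)
    rel = coords - com
    basis = []
    for ax in np.eye(3):
        t = np.tile(ax, n)
        basis.append(t)
    for ax in np.eye(3):
        r = np.cross(np.broadcast_to(ax, rel.shape), rel).reshape(-1)
        basis.append(r)
    B = np.array(basis)
    Q, R = np.linalg.qr(B.T)
    keep = np.abs(np.diag(R)) > 1e-10
    return Q[:, keep].T


def random_fluctuation_spec(
    reference: Structure,
    variances=(0.9, 0.3, 0.1),
    n_frames: int = 5000,
    noise_sigma: float = 0.005,
    seed: int = 0,
    remove_rigid: bool = True,
) -> FluctuationSpec:
    """Draw random orthonormal planted modes (orthogonal to the rigid-body
    subspace by default, so superposition fitting cannot absorb them)."""
    n_dof = reference.coords.size
    k = len(variances)
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_dof, k))
    if remove_rigid:
        R = rigid_body_subspace(reference.coords)
        raw = raw - R.T @ (R @ raw)
    Q, _ = np.linalg.qr(raw)
    return FluctuationSpec(
        n_frames=n_frames,
        modes=Q.T[:k],
        variances=np.asarray(variances, dtype=float),
        noise_sigma=noise_sigma,
        seed=seed + 1,
    )


# --------------------------------------------------------------------------- #
# Graph fixtures
# --------------------------------------------------------------------------- #

GRAPH_KINDS = (
    "path",
    "star",
    "cycle",
    "complete",
    "two_cluster_bridge",
    "random_connected",
)


def make_graph_fixture(kind: str, n: int, seed: int = 0) -> ResidueGraph:
    """Known-topology residue graphs for centrality oracles.

    Nodes are pseudo-residues ("A", 1..n).  ``random_connected`` builds a
    random spanning tree plus extra random edges (connectivity guaranteed)
    and assigns random hydrogen-bond weights in 0..3; the deterministic
    kinds carry weight 0.
    """
    if n < 3:
        raise SyntheticDataError("graph fixtures need n >= 3")
    if kind not in GRAPH_KINDS:
        raise SyntheticDataError(f"unknown kind {kind!r}; use one of {GRAPH_KINDS}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = [("A", i + 1) for i in range(n)]
    for v in nodes:
        g.add_node(v, resname="GLY")

    def add(u, v, w=0):
        g.add_edge(nodes[u], nodes[v], distance_nm=0.5, hbond_weight=int(w))

    if kind == "path":
        for i in range(n - 1):
            add(i, i + 1)
    elif kind == "star":
        for i in range(1, n):
            add(0, i)
    elif kind == "cycle":
        for i in range(n):
            add(i, (i + 1) % n)
    elif kind == "complete":
        for i in range(n):
            for j in range(i + 1, n):
                add(i, j)
    elif kind == "two_cluster_bridge":
        half = n // 2
        for i in range(half):
            for j in range(i + 1, half):
                add(i, j)
        for i in range(half, n):
            for j in range(i + 1, n):
                add(i, j)
        add(0, half)  # the bridge
    else:  # random_connected
        for i in range(1, n):
            j = int(rng.integers(0, i))
            add(i, j, rng.integers(0, 4))
        n_extra = int(rng.integers(0, n))
        for _ in range(n_extra):
            i, j = rng.integers(0, n, size=2)
            if i != j and not g.has_edge(nodes[i], nodes[j]):
                add(int(i), int(j), rng.integers(0, 4))
    return ResidueGraph(g, contact_cutoff=0.7)


# --------------------------------------------------------------------------- #
# Parameter fixtures
# --------------------------------------------------------------------------- #

PARAM_SCHEMES = ("zeros", "unit_charges", "random")


def make_params_fixture(
    structure: Structure,
    scheme: str = "zeros",
    seed: int = 0,
    charged_pairs: list[tuple[int, int]] | None = None,
) -> NonbondedParams:
    """Nonbonded parameter fixtures.

    ``zeros``: all charges and epsilons zero (null-energy fixture);
    ``unit_charges``: +1e / −1e on each (i, j) pair in ``charged_pairs``
    (default: first and last atom), zero epsilon; ``random``: bounded
    uniform draws q ∈ [−1, 1] e, σ ∈ [0.25, 0.4] nm, ε ∈ [0.1, 1] kJ/mol.
    """
    n = len(structure.topology)
    if scheme not in PARAM_SCHEMES:
        raise SyntheticDataError(f"unknown scheme {scheme!r}; use one of {PARAM_SCHEMES}")
    if scheme == "zeros":
        return NonbondedParams(np.zeros(n), np.full(n, 0.3), np.zeros(n))
    if scheme == "unit_charges":
        q = np.zeros(n)
        pairs = charged_pairs if charged_pairs is not None else [(0, n - 1)]
        for i, j in pairs:
            q[i] += 1.0
            q[j] -= 1.0
        return NonbondedParams(q, np.full(n, 0.3), np.zeros(n))
    rng = np.random.default_rng(seed)
    return NonbondedParams(
        rng.uniform(-1.0, 1.0, n),
        rng.uniform(0.25, 0.4, n),
        rng.uniform(0.1, 1.0, n),
    )
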
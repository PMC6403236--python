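"""Pairwise nonbonded interaction-energy decomposition between atom groups.

The interaction energy between two groups is the sum over cross pairs of a
truncated Coulomb term f·q_i·q_j/r_ij (f = 138.935458 kJ·mol⁻¹·nm·e⁻²) and
a Lennard-Jones term 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with σ/ε combined by the
Lorentz–Berthelot or geometric rule.  No long-range (mesh Ewald / reaction
field) correction is applied: per-group decompositions of lattice-summed
electrostatics are not well defined, so absolute magnitudes will differ
from simulations run with such treatments.  Window statistics use
block-averaged errors (5 equal blocks; error = sd of block means / √5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT
from .structio import NonbondedParams, Selection, Trajectory, TrajnetError


class EnergyError(TrajnetError):
    pass


@dataclass(frozen=True)
class EnergyBreakdown:
    """Coulomb + Lennard-Jones decomposition (kJ/mol); total is their sum."""

    coulomb: float
    lennard_jones: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lennard_jones


@dataclass
class EnergySeries:
    """Per-frame interaction-energy decomposition over a window."""

    times_ps: np.ndarray
    coulomb: np.ndarray
    lennard_jones: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.lennard_jones


@dataclass(frozen=True)
class EnergyTableRow:
    """One row of an interaction-energy table: labels, mean and error."""

    group_a: str
    group_b: str
    run: str
    mean_coulomb: float
    mean_lennard_jones: float
    mean_total: float
    error: float

    def __post_init__(self) -> None:
        if self.error < 0:
            raise EnergyError("error estimate must be non-negative")


def _cross_pairs(ia: np.ndarray, ib: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pi, pj = np.meshgrid(ia, ib, indexing="ij")
    return pi.ravel(), pj.ravel()


def _pair_distances(frame: np.ndarray, pi: np.ndarray, pj: np.ndarray) -> np.ndarray:
    diff = frame[pi] - frame[pj]
    r = np.sqrt((diff ** 2).sum(axis=1))
    if np.any(r == 0):
        k = int(np.nonzero(r == 0)[0][0])
        raise EnergyError(
            f"zero distance between atoms {int(pi[k])} and {int(pj[k])}"
        )
    return r


def coulomb_energy(
    frame: np.ndarray,
    charges: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
    cutoff: float | None = None,
) -> float:
    """Truncated Coulomb energy (kJ/mol) over the given atom pairs."""
    pi, pj = np.asarray(pairs[0]), np.asarray(pairs[1])
    r = _pair_distances(np.asarray(frame, dtype=float), pi, pj)
    mask = np.ones_like(r, dtype=bool) if cutoff is None else r <= cutoff
    q = np.asarray(charges, dtype=float)
    return float(COULOMB_CONSTANT * (q[pi[mask]] * q[pj[mask]] / r[mask]).sum())


def _combined_lj(
    params: NonbondedParams, pi: np.ndarray, pj: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    si, sj = params.sigma[pi], params.sigma[pj]
    ei, ej = params.epsilon[pi], params.epsilon[pj]
    if params.combination_rule == "lorentz_berthelot":
        sij = 0.5 * (si + sj)
    else:
        sij = np.sqrt(si * sj)
    return sij, np.sqrt(ei * ej)


def lj_energy(
    frame: np.ndarray,
    params: NonbondedParams,
    pairs: tuple[np.ndarray, np.ndarray],
    cutoff: float | None = None,
) -> float:
    """Truncated Lennard-Jones energy (kJ/mol) over the given atom pairs."""
    pi, pj = np.asarray(pairs[0]), np.asarray(pairs[1])
    r = _pair_distances(np.asarray(frame, dtype=float), pi, pj)
    mask = np.ones_like(r, dtype=bool) if cutoff is None else r <= cutoff
    sij, eij = _combined_lj(params, pi[mask], pj[mask])
    sr6 = (sij / r[mask]) ** 6
    return float((4.0 * eij * (sr6 ** 2 - sr6)).sum())


def _window_stats(total: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged error of a window series."""
    mean = float(total.mean())
    if total.size < n_blocks:
        n_blocks = max(1, total.size)
    blocks = np.array_split(total, n_blocks)
    bmeans = np.array([b.mean() for b in blocks])
    if n_blocks < 2:
        return mean, 0.0
    err = float(bmeans.std(ddof=1) / np.sqrt(n_blocks))
    return mean, err


def interaction_energy_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
    cutoff: float | None = None,
    window: np.ndarray | None = None,
    labels: tuple[str, str] = ("A", "B"),
    run: str = "run1",
) -> tuple[EnergySeries, EnergyTableRow]:
    """Per-frame cross-group interaction energy plus window statistics.

    Only cross pairs contribute (intra-group interactions are excluded).
    The table row reports the window mean of the total and its 5-block
    averaged error.
    """
    ia, ib = group_a.indices, group_b.indices
    if ia.size == 0 or ib.size == 0:
        raise EnergyError("empty group")
    if np.intersect1d(ia, ib).size:
        raise EnergyError("groups overlap; cross-group energy undefined")
    if params.n_atoms != traj.n_atoms:
        raise EnergyError("parameter table does not cover the topology")
    pi, pj = _cross_pairs(ia, ib)
    coul = np.empty(traj.n_frames)
    lj = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        coul[f] = coulomb_energy(frame, params.charge, (pi, pj), cutoff)
        lj[f] = lj_energy(frame, params, (pi, pj), cutoff)
    series = EnergySeries(traj.times_ps, coul, lj)
    w = slice(None) if window is None else window
    total_w = series.total[w]
    if np.size(total_w) == 0:
        raise EnergyError("empty averaging window")
    mean, err = _window_stats(np.asarray(total_w))
    row = EnergyTableRow(
        labels[0],
        labels[1],
        run,
        float(np.mean(coul[w])),
        float(np.mean(lj[w])),
        mean,
        err,
    )
    return series, row


def residue_pair_energy(
    traj: Trajectory,
    residue_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
    cutoff: float | None = None,
    window: np.ndarray | None = None,
    labels: tuple[str, str] = ("residue", "B"),
    run: str = "run1",
) -> EnergyTableRow:
    """Interaction energy of a single residue with a group (one table row)."""
    if len(residue_a) == 0:
        raise EnergyError("residue selection resolves to no atoms")
    _, row = interaction_energy_series(
        traj, residue_a, group_b, params, cutoff, window, labels, run
    )
    return row
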
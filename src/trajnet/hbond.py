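"""Geometric hydrogen-bond detection and per-frame counting between groups.

A hydrogen bond is declared when the donor–acceptor distance is at most
0.35 nm and the hydrogen–donor–acceptor angle is at most 30° (the Gromacs
``gmx hbond`` convention: distance between heavy atoms, angle at the
donor).  Donors are N/O atoms covalently bonded to a hydrogen (bond
inferred from a 0.12 nm distance cutoff in the first frame); acceptors are
all N and O atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import SeriesResult
from .structio import Selection, Trajectory, TrajnetError


class HBondError(TrajnetError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: donor–acceptor cutoff (nm) and H–D–A angle (deg)."""

    da_cutoff: float = 0.35
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise HBondError("hydrogen-bond cutoffs must be positive")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (atom indices into the topology)."""

    donor: int
    hydrogen: int
    acceptor: int
    da_distance: float
    hda_angle: float


@dataclass
class DonorAcceptorSet:
    """Resolved donors (D–H index pairs) and acceptor atom indices."""

    donor_pairs: np.ndarray  # (n_donors, 2): donor heavy atom, hydrogen
    acceptors: np.ndarray  # (n_acceptors,)


COVALENT_DH_CUTOFF_NM = 0.12


def infer_donors_acceptors(
    traj: Trajectory, frame: int = 0
) -> DonorAcceptorSet:
    """Infer donor D–H pairs and acceptor atoms from topology + geometry.

    Donors: N or O atoms with a hydrogen within 0.12 nm in the given frame
    (covalent bond heuristic).  Hydrogens bonded to carbon are never
    donors.  Acceptors: every N and O atom.  A topology without hydrogens
    yields an empty donor set with a warning.
    """
    top = traj.topology
    coords = traj.coords[frame]
    is_no = (top.elements == "N") | (top.elements == "O")
    acceptors = np.nonzero(is_no)[0]
    h_idx = np.nonzero(top.elements == "H")[0]
    if h_idx.size == 0:
        warnings.warn(
            "topology contains no hydrogens; donor set is empty",
            stacklevel=2,
        )
        return DonorAcceptorSet(np.empty((0, 2), dtype=int), acceptors)
    pairs = []
    heavy = np.nonzero(is_no)[0]
    for h in h_idx:
        d2 = ((coords[heavy] - coords[h]) ** 2).sum(axis=1)
        close = heavy[d2 <= COVALENT_DH_CUTOFF_NM ** 2]
        for d in close:
            pairs.append((int(d), int(h)))
    return DonorAcceptorSet(
        np.array(pairs, dtype=int).reshape(-1, 2), acceptors
    )


def detect_hbonds(
    coords: np.ndarray,
    donors: DonorAcceptorSet,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Detect all hydrogen bonds in one coordinate frame.

    A bond requires d(D,A) ≤ da_cutoff and the H–D–A angle ≤ angle_cutoff;
    the donor atom itself (and its hydrogen) are excluded as acceptors for
    that bond.
    """
    out: list[HBond] = []
    acc = donors.acceptors
    if acc.size == 0 or donors.donor_pairs.size == 0:
        return out
    acc_xyz = coords[acc]
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    for d, h in donors.donor_pairs:
        da = acc_xyz - coords[d]
        dist = np.linalg.norm(da, axis=1)
        mask = (dist <= criteria.da_cutoff) & (acc != d) & (acc != h)
        if not mask.any():
            continue
        dh = coords[h] - coords[d]
        dh_norm = np.linalg.norm(dh)
        if dh_norm == 0:
            continue
        cand = np.nonzero(mask)[0]
        cosang = (da[cand] @ dh) / (dist[cand] * dh_norm)
        cosang = np.clip(cosang, -1.0, 1.0)
        ok = cosang >= cos_cut
        for j, c in zip(cand[ok], cosang[ok]):
            out.append(
                HBond(
                    int(d),
                    int(h),
                    int(acc[j]),
                    float(dist[j]),
                    float(np.rad2deg(np.arccos(c))),
                )
            )
    return out


def _inter_group_count(
    bonds: list[HBond], set_a: frozenset[int], set_b: frozenset[int]
) -> int:
    n = 0
    for b in bonds:
        if (b.donor in set_a and b.acceptor in set_b) or (
            b.donor in set_b and b.acceptor in set_a
        ):
            n += 1
    return n


def hbond_count_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    window: np.ndarray | None = None,
    donors: DonorAcceptorSet | None = None,
) -> tuple[SeriesResult, float, float]:
    """Per-frame count of hydrogen bonds between two disjoint groups.

    Counts bonds with donor in A and acceptor in B plus donor in B and
    acceptor in A.  Returns the series together with the mean and
    (population) standard deviation over ``window`` (default: all frames).
    """
    ia, ib = group_a.indices, group_b.indices
    if np.intersect1d(ia, ib).size:
        raise HBondError("groups overlap; inter-group hydrogen bonds undefined")
    if donors is None:
        donors = infer_donors_acceptors(traj)
    set_a, set_b = frozenset(int(i) for i in ia), frozenset(int(i) for i in ib)
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.coords[f], donors, criteria)
        counts[f] = _inter_group_count(bonds, set_a, set_b)
    series = SeriesResult(traj.times_ps, counts, "hbond_count", "count")
    sel = counts if window is None else counts[window]
    if sel.size == 0:
        raise HBondError("empty averaging window")
    return series, float(sel.mean()), float(sel.std())
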
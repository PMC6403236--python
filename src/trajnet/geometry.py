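"""Superposition-based deviation and fluctuation metrics, compactness,
exposure and inter-group distance series.

Covers RMSD/RMSF (Kabsch least-squares superposition), radius of gyration,
centre-of-mass and minimum inter-group distances, and Shrake–Rupley
solvent-accessible surface area.  All lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import VDW_RADII_NM
from .structio import Selection, Structure, Trajectory, TrajnetError


class GeometryError(TrajnetError):
    pass


@dataclass
class SeriesResult:
    """A per-frame scalar time series (e.g. RMSD(t), Rg(t), distance(t))."""

    times_ps: np.ndarray
    values: np.ndarray
    label: str
    units: str

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ps.shape != self.values.shape:
            raise GeometryError("times and values must have equal lengths")
        if self.times_ps.size > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise GeometryError("times must be strictly increasing")

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ProfileResult:
    """A per-atom or per-residue scalar profile (e.g. the RMSF profile)."""

    keys: list
    values: np.ndarray
    label: str
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != self.values.size:
            raise GeometryError("keys and values must have equal lengths")


# --------------------------------------------------------------------------- #
# Superposition
# --------------------------------------------------------------------------- #


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation + translation`` minimises the (weighted) RMSD to
    ``reference``.  The rotation is proper (det = +1; the reflection branch
    of the SVD is corrected).  Requires at least 3 non-collinear atoms.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("mobile and reference must be matching (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cx = (w[:, None] * X).sum(axis=0) / wsum
    cy = (w[:, None] * Y).sum(axis=0) / wsum
    X0 = X - cx
    Y0 = Y - cy
    if np.linalg.matrix_rank(Y0, tol=1e-10) < 2 or np.linalg.matrix_rank(X0, tol=1e-10) < 2:
        raise GeometryError("degenerate (collinear or coincident) configuration")
    H = X0.T @ (w[:, None] * Y0)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = cy - cx @ R
    diff = X @ R + t - Y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return R, t, rmsd


def _fit_frames(
    coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Fit every frame to ``reference`` by LS superposition on ``fit_idx``."""
    out = np.empty_like(coords)
    ref = reference[fit_idx]
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f, fit_idx], ref)
        out[f] = coords[f] @ R + t
    return out


def fit_to_mean(
    coords: np.ndarray,
    fit_idx: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively fit frames to their mean until the mean is a fixed point.

    Starts from the first frame as reference, then alternates (fit all
    frames → recompute mean) until the mean moves by less than ``tol`` (nm,
    max-norm).  At convergence each frame is least-squares fitted to the
    returned mean, which removes rigid-body motion without leaking it into
    the fluctuation statistics.  Returns ``(fitted_coords, mean_coords)``.
    """
    fitted = _fit_frames(coords, coords[0], fit_idx)
    mean = fitted.mean(axis=0)
    for _ in range(max_iter):
        fitted = _fit_frames(coords, mean, fit_idx)
        new_mean = fitted.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return fitted, mean


# --------------------------------------------------------------------------- #
# Deviation / fluctuation series
# --------------------------------------------------------------------------- #


def _require_nonempty(sel: Selection, what: str = "selection") -> np.ndarray:
    if len(sel) == 0:
        raise GeometryError(f"empty {what}")
    return sel.indices


def rmsd_series(
    traj: Trajectory, selection: Selection, reference_frame: int = 0
) -> SeriesResult:
    """Backbone-style RMSD(t): each frame is fitted to the reference frame on
    the selection and the post-fit RMSD over the selection is recorded."""
    idx = _require_nonempty(selection)
    ref = traj.coords[reference_frame, idx]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, values[f] = kabsch_superpose(traj.coords[f, idx], ref)
    return SeriesResult(traj.times_ps, values, f"rmsd[{selection.expression}]", "nm")


def rmsf(
    traj: Trajectory,
    selection: Selection,
    fit_selection: Selection | None = None,
    frame_window: np.ndarray | slice | None = None,
    by_residue: bool = True,
) -> ProfileResult:
    """Root-mean-square fluctuation about the window-mean structure.

    Frames in the window are fitted to their mean on ``fit_selection``
    (default: the analysis selection itself); RMSF_i = sqrt(<|x_i − <x_i>|²>).
    With ``by_residue`` (default) atoms are aggregated per residue by the
    root-mean-square of their squared fluctuations, matching the usual
    per-residue fluctuation profile.
    """
    idx = _require_nonempty(selection)
    fit_idx = _require_nonempty(fit_selection) if fit_selection is not None else idx
    if frame_window is None:
        window_coords = traj.coords
    else:
        window_coords = traj.coords[frame_window]
    if window_coords.shape[0] < 2:
        raise GeometryError("RMSF window must contain at least 2 frames")
    fitted, mean = fit_to_mean(window_coords, fit_idx)
    dev = fitted[:, idx] - mean[idx]
    msf = (dev ** 2).sum(axis=2).mean(axis=0)
    if not by_residue:
        top = traj.topology
        keys = [f"{top.chains[i]}:{top.resids[i]}:{top.names[i]}" for i in idx]
        return ProfileResult(keys, np.sqrt(msf), "rmsf", "nm")
    top = traj.topology
    res_of = top.residue_index()[idx]
    keys: list = []
    vals: list[float] = []
    rkeys = top.residue_keys()
    for r in np.unique(res_of):
        chain, resid, resname = rkeys[r]
        keys.append((chain, resid, resname))
        vals.append(float(np.sqrt(msf[res_of == r].mean())))
    return ProfileResult(keys, np.array(vals), "rmsf", "nm")


def rmsf_chain_correlation(
    profile_a: ProfileResult, profile_b: ProfileResult
) -> float:
    """Pearson correlation between the fluctuation profiles of two chains
    (position-matched residues)."""
    a = profile_a.values
    b = profile_b.values
    if a.size != b.size:
        raise GeometryError("profiles must have equal lengths")
    if a.size < 2:
        raise GeometryError("need at least 2 values for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise GeometryError("zero variance in a profile: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def radius_of_gyration(
    traj: Trajectory, selection: Selection, mass_weighted: bool = True
) -> SeriesResult:
    """Mass-weighted radius of gyration per frame:
    Rg = sqrt(Σ m_i |x_i − x_com|² / Σ m_i)."""
    idx = _require_nonempty(selection)
    m = traj.topology.masses[idx] if mass_weighted else np.ones(idx.size)
    msum = m.sum()
    if msum <= 0:
        raise GeometryError("total mass is zero")
    xyz = traj.coords[:, idx]
    com = (m[None, :, None] * xyz).sum(axis=1) / msum
    dev = xyz - com[:, None, :]
    rg = np.sqrt((m[None, :] * (dev ** 2).sum(axis=2)).sum(axis=1) / msum)
    return SeriesResult(traj.times_ps, rg, f"rg[{selection.expression}]", "nm")


def com_distance(
    traj: Trajectory,
    selection_a: Selection,
    selection_b: Selection,
    mass_weighted: bool = True,
) -> SeriesResult:
    """Per-frame distance between the (mass-weighted) centres of mass of two
    atom groups."""
    ia = _require_nonempty(selection_a, "selection A")
    ib = _require_nonempty(selection_b, "selection B")
    masses = traj.topology.masses
    ma = masses[ia] if mass_weighted else np.ones(ia.size)
    mb = masses[ib] if mass_weighted else np.ones(ib.size)
    if ma.sum() <= 0 or mb.sum() <= 0:
        raise GeometryError("total mass is zero")
    com_a = (ma[None, :, None] * traj.coords[:, ia]).sum(axis=1) / ma.sum()
    com_b = (mb[None, :, None] * traj.coords[:, ib]).sum(axis=1) / mb.sum()
    d = np.linalg.norm(com_a - com_b, axis=1)
    return SeriesResult(traj.times_ps, d, "com_distance", "nm")


def min_distance(
    traj: Trajectory, selection_a: Selection, selection_b: Selection
) -> SeriesResult:
    """Per-frame minimum distance over all cross pairs of two disjoint
    atom groups."""
    ia = _require_nonempty(selection_a, "selection A")
    ib = _require_nonempty(selection_b, "selection B")
    if np.intersect1d(ia, ib).size:
        raise GeometryError("selections overlap; minimum distance undefined")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = cdist(traj.coords[f, ia], traj.coords[f, ib]).min()
    return SeriesResult(traj.times_ps, values, "min_distance", "nm")


# --------------------------------------------------------------------------- #
# Solvent-accessible surface area (Shrake–Rupley)
# --------------------------------------------------------------------------- #


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere via the golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    structure: Structure,
    selection: Selection,
    probe_radius: float = 0.14,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area (nm²).

    For each selected atom, ``n_points`` quasi-uniform sphere points are
    placed at radius (r_vdw + probe); a point is exposed iff it lies outside
    every *other* selected atom's expanded sphere.  Returns per-atom areas
    (in selection order) and their total.
    """
    idx = _require_nonempty(selection)
    table = radii if radii is not None else VDW_RADII_NM
    elements = structure.topology.elements[idx]
    try:
        r = np.array([table[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise GeometryError(f"no van der Waals radius for element {exc}") from None
    xyz = structure.coords[idx]
    expanded = r + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = expanded.max()
    areas = np.empty(idx.size)
    for i in range(idx.size):
        pts = xyz[i] + expanded[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(xyz[i], expanded[i] + rmax) if j != i
        ]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        frac = exposed.sum() / n_points
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas, float(areas.sum())


def sasa_series(
    traj: Trajectory,
    selection: Selection,
    probe_radius: float = 0.14,
    n_points: int = 960,
    stride: int = 1,
) -> SeriesResult:
    """Total SASA per frame (optionally strided for long trajectories)."""
    frames = range(0, traj.n_frames, stride)
    values = []
    times = []
    for f in frames:
        _, total = sasa(traj.frame(f), selection, probe_radius, n_points)
        values.append(total)
        times.append(traj.times_ps[f])
    return SeriesResult(np.array(times), np.array(values), "sasa", "nm^2")
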
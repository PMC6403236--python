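"""Essential dynamics: coordinate covariance analysis of an MD ensemble.

The positional covariance matrix C = <(x−<x>)(x−<x>)ᵀ> is accumulated over
least-squares-fitted frames and diagonalised; the leading eigenvectors are
the dominant collective motions.  On top of the eigensystem this module
provides PC projections, free-energy landscapes over PC pairs
(ΔG = −k_B·T·ln P/P_max), representative-frame extraction, the Hess
normalized covariance overlap, the root-mean-square inner product (RMSIP)
between eigenvector sets, and porcupine displacement vectors.

Covariance is unweighted (no mass weighting) by default; frames are fitted
to the ensemble mean, iterated to a fixed point so that rigid-body motion
cannot leak into the leading modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import BOLTZMANN_KJ_MOL_K
from .geometry import fit_to_mean
from .structio import Selection, Trajectory, TrajnetError


class EssentialDynamicsError(TrajnetError):
    pass


@dataclass
class CovarianceModel:
    """Mean structure, 3N×3N covariance (nm²) and its eigensystem."""

    selection: Selection
    mean: np.ndarray  # (3N,)
    covariance: np.ndarray  # (3N, 3N)
    eigenvalues: np.ndarray  # descending, (3N,)
    eigenvectors: np.ndarray  # orthonormal columns, (3N, 3N)
    n_frames: int

    @property
    def trace(self) -> float:
        return float(np.trace(self.covariance))

    @property
    def n_dof(self) -> int:
        return int(self.mean.size)


@dataclass
class ProjectionSet:
    """Per-frame scores on the first k principal components (nm)."""

    times_ps: np.ndarray
    scores: np.ndarray  # (n_frames, k)
    k: int


@dataclass
class FELGrid:
    """Free-energy landscape over a 2D principal-component histogram."""

    xedges: np.ndarray
    yedges: np.ndarray
    counts: np.ndarray  # (n_bins, n_bins)
    free_energy: np.ndarray  # kJ/mol; +inf on unoccupied bins
    temperature_K: float
    components: tuple[int, int]


@dataclass
class OverlapResult:
    """Subspace similarity of two covariance models."""

    normalized_overlap: float
    rmsip: float
    inner_products: np.ndarray  # (k, k)


@dataclass
class PorcupineResult:
    """Per-atom displacement vectors along one mode plus extreme structures."""

    vectors: np.ndarray  # (N, 3), scale·sqrt(λ)·eigenvector
    plus: np.ndarray  # (N, 3) mean + vectors
    minus: np.ndarray  # (N, 3) mean − vectors
    mode_index: int


# --------------------------------------------------------------------------- #
# Covariance construction and projections
# --------------------------------------------------------------------------- #


def build_covariance(
    traj: Trajectory | list[Trajectory],
    selection: Selection,
    window: np.ndarray | None = None,
) -> CovarianceModel:
    """Build the fitted coordinate covariance model over a frame window.

    Accepts one trajectory or several runs to pool (frames are concatenated
    after a common fit, mirroring the usual concatenated-runs protocol).
    Each frame is least-squares fitted to the ensemble mean on the
    selection; C = <(x−<x>)(x−<x>)ᵀ> with the plain 1/F normalisation.
    """
    trajs = traj if isinstance(traj, list) else [traj]
    idx = selection.indices
    if idx.size == 0:
        raise EssentialDynamicsError("empty selection")
    parts = []
    times = []
    for t in trajs:
        c = t.coords if window is None else t.coords[window]
        parts.append(c[:, idx])
        times.append(t.times_ps if window is None else t.times_ps[window])
    coords = np.concatenate(parts, axis=0)
    if coords.shape[0] < 2:
        raise EssentialDynamicsError("need at least 2 frames for a covariance")
    all_idx = np.arange(idx.size)
    fitted, mean = fit_to_mean(coords, all_idx)
    X = fitted.reshape(fitted.shape[0], -1)
    mu = mean.reshape(-1)
    D = X - mu
    C = D.T @ D / D.shape[0]
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return CovarianceModel(
        selection=selection,
        mean=mu,
        covariance=C,
        eigenvalues=evals[order],
        eigenvectors=evecs[:, order],
        n_frames=X.shape[0],
    )


def cumulative_variance(model: CovarianceModel, k: int) -> float:
    """Fraction of total positional variance carried by the first k modes."""
    if k < 0 or k > model.n_dof:
        raise EssentialDynamicsError(f"k={k} outside [0, {model.n_dof}]")
    tr = model.trace
    # Traces below 1e-18 nm² are pure round-off (a constant ensemble).
    if tr <= 1e-18:
        raise EssentialDynamicsError("zero-trace covariance: fraction undefined")
    return float(model.eigenvalues[:k].sum() / tr)


def project(
    traj: Trajectory | list[Trajectory],
    model: CovarianceModel,
    k: int,
    window: np.ndarray | None = None,
) -> ProjectionSet:
    """Project frames onto the first k eigenvectors: score_t = Vₖᵀ(x_t − mean).

    Frames are fitted to the model mean on the model's selection before
    projection, matching the covariance construction.
    """
    trajs = traj if isinstance(traj, list) else [traj]
    idx = model.selection.indices
    parts = []
    times = []
    for t in trajs:
        c = t.coords if window is None else t.coords[window]
        parts.append(c[:, idx])
        times.append(t.times_ps if window is None else t.times_ps[window])
    coords = np.concatenate(parts, axis=0)
    if coords.shape[1] * 3 != model.n_dof:
        raise EssentialDynamicsError("selection does not match the model")
    if k < 1 or k > model.n_dof:
        raise EssentialDynamicsError(f"k={k} outside [1, {model.n_dof}]")
    mean_xyz = model.mean.reshape(-1, 3)
    from .geometry import kabsch_superpose

    scores = np.empty((coords.shape[0], k))
    Vk = model.eigenvectors[:, :k]
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f], mean_xyz)
        fitted = coords[f] @ R + t
        scores[f] = (fitted.reshape(-1) - model.mean) @ Vk
    t_axis = np.concatenate(times)
    if np.unique(t_axis).size != t_axis.size:
        t_axis = np.arange(t_axis.size, dtype=float)
    return ProjectionSet(t_axis, scores, k)


# --------------------------------------------------------------------------- #
# Free-energy landscape
# --------------------------------------------------------------------------- #


def fel(
    projections: ProjectionSet,
    i: int = 0,
    j: int = 1,
    n_bins: int = 32,
    temperature_K: float = 300.0,
    pad_fraction: float = 0.05,
) -> FELGrid:
    """Free-energy landscape over two principal components.

    ΔG_bin = −k_B·T·ln(P_bin / P_max) from the normalized 2D histogram of
    the (PC_i, PC_j) scores; the most populated bin sits at ΔG = 0 and
    unoccupied bins are +∞.  Bin edges span the data range padded by
    ``pad_fraction`` on each side.
    """
    if n_bins < 2:
        raise EssentialDynamicsError("need at least 2 bins per axis")
    s = projections.scores
    if s.shape[0] < 1:
        raise EssentialDynamicsError("no frames to histogram")
    if max(i, j) >= projections.k:
        raise EssentialDynamicsError("component index beyond stored scores")
    x, y = s[:, i], s[:, j]

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        if span == 0:
            span = max(abs(hi), 1.0)
            lo, hi = lo - 0.5 * span, hi + 0.5 * span
        pad = pad_fraction * span
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    xe, ye = _edges(x), _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    pmax = counts.max()
    with np.errstate(divide="ignore"):
        dg = np.where(
            counts > 0,
            -BOLTZMANN_KJ_MOL_K * temperature_K * np.log(counts / pmax),
            np.inf,
        )
    return FELGrid(xe, ye, counts, dg, temperature_K, (i, j))


def representative_frame(grid: FELGrid, projections: ProjectionSet) -> int:
    """Frame whose PC scores fall nearest the centre of the global-minimum
    free-energy bin (ties broken toward the lowest frame index)."""
    if not np.any(grid.counts > 0):
        raise EssentialDynamicsError("no occupied bins")
    flat = np.argmax(grid.counts)  # ΔG = 0 bin; first in row-major order on ties
    bi, bj = np.unravel_index(flat, grid.counts.shape)
    cx = 0.5 * (grid.xedges[bi] + grid.xedges[bi + 1])
    cy = 0.5 * (grid.yedges[bj] + grid.yedges[bj + 1])
    i, j = grid.components
    d2 = (projections.scores[:, i] - cx) ** 2 + (projections.scores[:, j] - cy) ** 2
    return int(np.argmin(d2))


# --------------------------------------------------------------------------- #
# Subspace comparison
# --------------------------------------------------------------------------- #


def covariance_overlap(
    model_a: CovarianceModel, model_b: CovarianceModel, k: int = 10
) -> float:
    """Hess normalized covariance overlap of rank-k reconstructions.

    overlap = 1 − sqrt( tr(Ã + B̃ − 2(Ã^{1/2} B̃ Ã^{1/2})^{1/2})
                        / (tr Ã + tr B̃) ),
    where Ã, B̃ keep the first k eigenpairs.  1 for identical fluctuation
    spaces, 0 for disjoint ones; round-off is clipped into [0, 1].
    """
    if model_a.n_dof != model_b.n_dof:
        raise EssentialDynamicsError("models have different dimensions")
    k = min(k, model_a.n_dof)
    la = np.clip(model_a.eigenvalues[:k], 0.0, None)
    lb = np.clip(model_b.eigenvalues[:k], 0.0, None)
    tra, trb = la.sum(), lb.sum()
    if tra + trb <= 0:
        raise EssentialDynamicsError("both models have zero trace")
    Va = model_a.eigenvectors[:, :k]
    Vb = model_b.eigenvectors[:, :k]
    # tr (A^{1/2} B A^{1/2})^{1/2} = sum of singular values of
    # La^{1/2} Va^T Vb Lb^{1/2}  (k×k), since the nonzero eigenvalues of
    # A^{1/2} B A^{1/2} are the squared singular values of B^{1/2} A^{1/2}.
    M = (np.sqrt(la)[:, None] * (Va.T @ Vb)) * np.sqrt(lb)[None, :]
    cross = np.linalg.svd(M, compute_uv=False).sum()
    inner = (tra + trb - 2.0 * cross) / (tra + trb)
    # The normalized difference is a catastrophic cancellation for nearly
    # identical models; below 1e-12 it is round-off, not signal, and the
    # square root would inflate it to ~1e-6.  Floor it to zero there.
    if inner < 1e-12:
        inner = 0.0
    return float(np.clip(1.0 - np.sqrt(inner), 0.0, 1.0))


def rmsip(
    model_a: CovarianceModel, model_b: CovarianceModel, k: int = 10
) -> tuple[float, np.ndarray]:
    """Root-mean-square inner product of the first k eigenvectors:
    sqrt((1/k) Σ_ij (v_i·w_j)²), with the k×k inner-product matrix."""
    if k < 1:
        raise EssentialDynamicsError("k must be at least 1")
    if model_a.n_dof != model_b.n_dof:
        raise EssentialDynamicsError("models have different dimensions")
    Va = model_a.eigenvectors[:, :k]
    Vb = model_b.eigenvectors[:, :k]
    P = Va.T @ Vb
    return float(np.sqrt((P ** 2).sum() / k)), P


def porcupine(
    model: CovarianceModel, mode_index: int = 0, scale: float = 1.0
) -> PorcupineResult:
    """Displacement vectors scale·sqrt(λ)·v along one mode and the two
    extreme structures mean ± displacement."""
    if mode_index < 0 or mode_index >= model.n_dof:
        raise EssentialDynamicsError(f"mode {mode_index} does not exist")
    lam = model.eigenvalues[mode_index]
    if lam <= 1e-14:
        if scale != 0.0:
            warnings.warn(
                f"mode {mode_index} has (near-)zero eigenvalue; vectors are zero",
                stacklevel=2,
            )
        disp = np.zeros(model.n_dof)
    else:
        disp = scale * np.sqrt(lam) * model.eigenvectors[:, mode_index]
    mean = model.mean.reshape(-1, 3)
    v = disp.reshape(-1, 3)
    return PorcupineResult(v, mean + v, mean - v, mode_index)
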
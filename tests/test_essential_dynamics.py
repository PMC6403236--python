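"""Covariance analysis, projections, FEL, overlap/RMSIP and porcupine."""

import numpy as np
import pytest
import scipy.linalg

from trajnet.essential_dynamics import (
    CovarianceModel,
    EssentialDynamicsError,
    build_covariance,
    covariance_overlap,
    cumulative_variance,
    fel,
    porcupine,
    project,
    representative_frame,
    rmsip,
)
from trajnet.structio import Selection, Trajectory
from trajnet.synthetic_data import (
    make_gaussian_trajectory,
    random_fluctuation_spec,
    rigid_body_subspace,
    FluctuationSpec,
)

from conftest import make_atoms


def _chain(n):
    top = make_atoms([("CA", "C", "ALA", i + 1, "A") for i in range(n)])
    rng = np.random.default_rng(7)
    base = rng.uniform(0, 4, size=(n, 3))
    return top, base


def _sel(n):
    return Selection("all", np.arange(n))


def _nonrigid_unit_vector(base, seed=0):
    """A unit 3N-vector orthogonal to the rigid-body subspace of ``base``."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=base.size)
    R = rigid_body_subspace(base)
    v -= R.T @ (R @ v)
    return v / np.linalg.norm(v)


def _model_from_eig(evals, evecs, selection=None):
    evals = np.asarray(evals, dtype=float)
    C = evecs @ np.diag(evals) @ evecs.T
    sel = selection or Selection("all", np.arange(evecs.shape[0] // 3))
    return CovarianceModel(sel, np.zeros(evecs.shape[0]), C, evals, evecs, 0)


class TestBuildCovariance:
    def test_constant_trajectory_zero_matrix(self):
        top, base = _chain(5)
        traj = Trajectory(top, np.repeat(base[None], 4, axis=0))
        model = build_covariance(traj, _sel(5))
        np.testing.assert_allclose(model.covariance, 0.0, atol=1e-24)
        assert model.trace == pytest.approx(0.0, abs=1e-20)

    def test_rank_one_alternation_recovered(self):
        """Frames mean ± a·v give a single nonzero eigenvalue a² with
        eigenvector ±v."""
        top, base = _chain(6)
        v = _nonrigid_unit_vector(base, seed=1)
        a = 0.12
        plus = (base.reshape(-1) + a * v).reshape(-1, 3)
        minus = (base.reshape(-1) - a * v).reshape(-1, 3)
        traj = Trajectory(top, np.stack([plus, minus] * 3))
        model = build_covariance(traj, _sel(6))
        assert model.eigenvalues[0] == pytest.approx(a ** 2, rel=1e-8)
        assert abs(model.eigenvalues[1]) < 1e-12
        assert abs(np.dot(model.eigenvectors[:, 0], v)) == pytest.approx(1.0, abs=1e-6)

    def test_planted_spectrum_recovered(self):
        """Three orthogonal planted modes (0.9, 0.3, 0.1 nm²) at 5000 frames:
        eigenvalues within 5%, residual spectrum mass below 2% of trace."""
        top, base = _chain(40)
        from trajnet.structio import Structure

        ref = Structure(top, base)
        spec = random_fluctuation_spec(
            ref, variances=(0.9, 0.3, 0.1), n_frames=5000, noise_sigma=0.005, seed=3
        )
        traj = make_gaussian_trajectory(ref, spec)
        model = build_covariance(traj, _sel(40))
        np.testing.assert_allclose(
            model.eigenvalues[:3], [0.9, 0.3, 0.1], rtol=0.05
        )
        assert model.eigenvalues[3:].sum() < 0.02 * model.trace

    def test_eigen_reconstruction(self):
        top, base = _chain(10)
        rng = np.random.default_rng(5)
        traj = Trajectory(top, base[None] + rng.normal(0, 0.05, size=(50, 10, 3)))
        model = build_covariance(traj, _sel(10))
        recon = model.eigenvectors @ np.diag(model.eigenvalues) @ model.eigenvectors.T
        assert np.abs(model.covariance - recon).max() <= 1e-8 * model.trace

    def test_too_few_frames(self):
        top, base = _chain(5)
        with pytest.raises(EssentialDynamicsError):
            build_covariance(Trajectory(top, base[None]), _sel(5))


class TestCumulativeVariance:
    def test_full_rank_is_one(self):
        top, base = _chain(5)
        rng = np.random.default_rng(2)
        traj = Trajectory(top, base[None] + rng.normal(0, 0.02, size=(40, 5, 3)))
        model = build_covariance(traj, _sel(5))
        assert cumulative_variance(model, model.n_dof) == pytest.approx(1.0)

    def test_rank_one_first_component_is_one(self):
        top, base = _chain(6)
        v = _nonrigid_unit_vector(base)
        plus = (base.reshape(-1) + 0.1 * v).reshape(-1, 3)
        minus = (base.reshape(-1) - 0.1 * v).reshape(-1, 3)
        traj = Trajectory(top, np.stack([plus, minus]))
        model = build_covariance(traj, _sel(6))
        assert cumulative_variance(model, 1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_trace_undefined(self):
        top, base = _chain(5)
        traj = Trajectory(top, np.repeat(base[None], 3, axis=0))
        model = build_covariance(traj, _sel(5))
        with pytest.raises(EssentialDynamicsError):
            cumulative_variance(model, 1)


class TestProject:
    def test_mean_projects_to_zero(self):
        top, base = _chain(8)
        rng = np.random.default_rng(4)
        traj = Trajectory(top, base[None] + rng.normal(0, 0.03, size=(60, 8, 3)))
        model = build_covariance(traj, _sel(8))
        mean_traj = Trajectory(top, model.mean.reshape(1, -1, 3))
        scores = project(mean_traj, model, 3).scores
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_rank_one_scores(self):
        top, base = _chain(6)
        v = _nonrigid_unit_vector(base, seed=9)
        a = 0.2
        plus = (base.reshape(-1) + a * v).reshape(-1, 3)
        minus = (base.reshape(-1) - a * v).reshape(-1, 3)
        traj = Trajectory(top, np.stack([plus, minus] * 2))
        model = build_covariance(traj, _sel(6))
        scores = project(traj, model, 2).scores
        np.testing.assert_allclose(np.abs(scores[:, 0]), a, atol=1e-8)
        np.testing.assert_allclose(scores[:, 1], 0.0, atol=1e-8)

    def test_training_score_variance_equals_eigenvalue(self):
        top, base = _chain(10)
        rng = np.random.default_rng(11)
        traj = Trajectory(top, base[None] + rng.normal(0, 0.05, size=(80, 10, 3)))
        model = build_covariance(traj, _sel(10))
        scores = project(traj, model, 5).scores
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=0), model.eigenvalues[:5], atol=1e-8
        )
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)


def _projection_set(scores):
    from trajnet.essential_dynamics import ProjectionSet

    scores = np.asarray(scores, dtype=float)
    return ProjectionSet(np.arange(len(scores), dtype=float), scores, scores.shape[1])


class TestFEL:
    def test_single_occupied_bin(self):
        proj = _projection_set(np.tile([[0.3, -0.1]], (20, 1)))
        grid = fel(proj, n_bins=8)
        assert (grid.counts > 0).sum() == 1
        assert grid.free_energy[grid.counts > 0][0] == 0.0
        assert np.all(np.isinf(grid.free_energy[grid.counts == 0]))

    def test_uniform_occupancy_flat_zero(self):
        n_bins = 4
        centers = (np.arange(n_bins) + 0.5) / n_bins
        xx, yy = np.meshgrid(centers, centers)
        proj = _projection_set(np.column_stack([xx.ravel(), yy.ravel()]))
        grid = fel(proj, n_bins=n_bins, pad_fraction=0.0)
        np.testing.assert_array_equal(grid.counts, 1)
        np.testing.assert_allclose(grid.free_energy, 0.0, atol=1e-12)

    def test_occupancy_ratio_e_gives_kbt_gap(self):
        """Two bins whose counts are in ratio e differ by k_B·T =
        2.494 kJ/mol at 300 K (to the precision an integer-count ratio can
        represent e, well inside 1e-6)."""
        m = 1_000_000
        c1 = 2_718_282  # round(e * m): ratio e to 7 significant digits
        pts = np.concatenate(
            [np.tile([[0.25, 0.5]], (c1, 1)), np.tile([[0.75, 0.5]], (m, 1))]
        )
        proj = _projection_set(pts)
        grid = fel(proj, n_bins=2, temperature_K=300.0, pad_fraction=0.0)
        occupied = grid.free_energy[grid.counts > 0]
        gap = occupied.max() - occupied.min()
        kbt = 0.0083144621 * 300.0
        assert gap == pytest.approx(kbt, abs=1e-6)
        assert kbt == pytest.approx(2.494, abs=5e-4)

    def test_too_few_bins(self):
        with pytest.raises(EssentialDynamicsError):
            fel(_projection_set([[0.0, 0.0]]), n_bins=1)


class TestRepresentativeFrame:
    def test_single_frame(self):
        proj = _projection_set([[0.1, 0.2]])
        grid = fel(proj, n_bins=4)
        assert representative_frame(grid, proj) == 0

    def test_denser_cluster_wins(self, rng):
        a = rng.normal(0, 0.02, size=(100, 2)) + [1.0, 1.0]
        b = rng.normal(0, 0.02, size=(10, 2)) - [1.0, 1.0]
        proj = _projection_set(np.vstack([a, b]))
        idx = representative_frame(fel(proj, n_bins=8), proj)
        assert idx < 100  # lies in the dense cluster

    def test_constructed_grid_exact_index(self):
        # Three frames in one bin, one elsewhere; nearest-to-centre decides.
        pts = np.array([[0.1, 0.1], [0.12, 0.12], [0.14, 0.1], [0.9, 0.9]])
        proj = _projection_set(pts)
        grid = fel(proj, n_bins=2, pad_fraction=0.0)
        bi, bj = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
        cx = 0.5 * (grid.xedges[bi] + grid.xedges[bi + 1])
        cy = 0.5 * (grid.yedges[bj] + grid.yedges[bj + 1])
        d2 = ((pts[:3] - [cx, cy]) ** 2).sum(axis=1)
        assert representative_frame(grid, proj) == int(np.argmin(d2))


class TestOverlap:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))
        evals, evecs = np.linalg.eigh(A @ A.T)
        model = _model_from_eig(evals[::-1], evecs[:, ::-1])
        assert covariance_overlap(model, model, 6) == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_rank_one_models(self):
        evecs = np.eye(6)
        a = _model_from_eig([1.0, 0, 0, 0, 0, 0], evecs)
        b = _model_from_eig(
            [1.0, 0, 0, 0, 0, 0], np.roll(evecs, 1, axis=1)
        )
        assert covariance_overlap(a, b, 1) == pytest.approx(0.0, abs=1e-8)

    def test_matches_dense_matrix_function_evaluation(self):
        """Independent oracle: the same Hess formula evaluated with dense
        scipy.linalg.sqrtm matrix square roots."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 6))
        Y = rng.normal(size=(6, 6))
        A = X @ X.T
        B = Y @ Y.T
        ea, va = np.linalg.eigh(A)
        eb, vb = np.linalg.eigh(B)
        ma = _model_from_eig(ea[::-1], va[:, ::-1])
        mb = _model_from_eig(eb[::-1], vb[:, ::-1])
        Ah = scipy.linalg.sqrtm(A)
        inner = np.trace(A) + np.trace(B) - 2 * np.trace(
            scipy.linalg.sqrtm(Ah @ B @ Ah)
        )
        expected = 1.0 - np.sqrt(inner.real / (np.trace(A) + np.trace(B)))
        assert covariance_overlap(ma, mb, 6) == pytest.approx(expected, abs=1e-8)

    def test_symmetry_and_sign_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 6))
        Y = rng.normal(size=(6, 6))
        ea, va = np.linalg.eigh(X @ X.T)
        eb, vb = np.linalg.eigh(Y @ Y.T)
        ma = _model_from_eig(ea[::-1], va[:, ::-1])
        mb = _model_from_eig(eb[::-1], vb[:, ::-1])
        assert covariance_overlap(ma, mb, 4) == pytest.approx(
            covariance_overlap(mb, ma, 4), abs=1e-12
        )
        mb_flip = _model_from_eig(eb[::-1], -vb[:, ::-1])
        assert covariance_overlap(ma, mb_flip, 4) == pytest.approx(
            covariance_overlap(ma, mb, 4), abs=1e-12
        )

    def test_zero_trace_rejected(self):
        z = _model_from_eig(np.zeros(6), np.eye(6))
        with pytest.raises(EssentialDynamicsError):
            covariance_overlap(z, z, 3)


class TestRmsip:
    def test_identical_bases(self):
        evecs = np.linalg.qr(np.random.default_rng(1).normal(size=(9, 9)))[0]
        m = _model_from_eig(np.arange(9, 0, -1, dtype=float), evecs)
        value, P = rmsip(m, m, 3)
        assert value == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-10)

    def test_orthogonal_sets_zero(self):
        evecs = np.eye(6)
        a = _model_from_eig([3.0, 2, 1, 0, 0, 0], evecs)
        b = _model_from_eig([3.0, 2, 1, 0, 0, 0], np.roll(evecs, 3, axis=1))
        value, _ = rmsip(a, b, 3)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_complete_bases_give_one(self):
        """Completeness identity: two full orthonormal bases of the same
        space have RMSIP 1 for k = 3N."""
        rng = np.random.default_rng(3)
        qa = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        qb = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        a = _model_from_eig(np.arange(6, 0, -1, dtype=float), qa)
        b = _model_from_eig(np.arange(6, 0, -1, dtype=float), qb)
        value, _ = rmsip(a, b, 6)
        assert value == pytest.approx(1.0, abs=1e-10)

    def test_k_zero_rejected(self):
        m = _model_from_eig(np.ones(6), np.eye(6))
        with pytest.raises(EssentialDynamicsError):
            rmsip(m, m, 0)


class TestPorcupine:
    def test_rank_one_closure(self):
        """scale 1 on a rank-1 ±a alternation reproduces the two training
        conformations."""
        top, base = _chain(6)
        v = _nonrigid_unit_vector(base, seed=13)
        a = 0.15
        plus = (base.reshape(-1) + a * v).reshape(-1, 3)
        minus = (base.reshape(-1) - a * v).reshape(-1, 3)
        traj = Trajectory(top, np.stack([plus, minus] * 2))
        model = build_covariance(traj, _sel(6))
        res = porcupine(model, 0, scale=1.0)
        got = {tuple(np.round(res.plus.reshape(-1), 8)),
               tuple(np.round(res.minus.reshape(-1), 8))}
        mean = model.mean
        want = {
            tuple(np.round(mean + a * model.eigenvectors[:, 0], 8)),
            tuple(np.round(mean - a * model.eigenvectors[:, 0], 8)),
        }
        assert got == want
        # extremes coincide with the training conformations (fitted frames)
        np.testing.assert_allclose(
            sorted(np.abs(res.vectors.reshape(-1))),
            sorted(np.abs(a * v)),
            atol=1e-6,
        )

    def test_scale_zero_returns_mean(self):
        m = _model_from_eig([1.0, 0.5] + [0.0] * 4, np.eye(6))
        res = porcupine(m, 0, scale=0.0)
        np.testing.assert_array_equal(res.plus, res.minus)

    def test_zero_mode_warns_and_zeros(self):
        m = _model_from_eig([1.0] + [0.0] * 5, np.eye(6))
        with pytest.warns(UserWarning, match="zero eigenvalue"):
            res = porcupine(m, 3, scale=1.0)
        np.testing.assert_array_equal(res.vectors, 0.0)

    def test_max_norm_atom_is_planted_max_amplitude_atom(self):
        """Vector norms are proportional to per-atom mode amplitude."""
        n_dof = 12
        v = np.zeros(n_dof)
        v[6] = 0.8  # atom 2 x-component dominates
        v[1] = 0.6
        evecs = np.zeros((n_dof, n_dof))
        evecs[:, 0] = v
        rest = scipy.linalg.null_space(v[None, :])
        evecs[:, 1:] = rest
        m = _model_from_eig([0.5] + [0.0] * (n_dof - 1), evecs)
        res = porcupine(m, 0, scale=2.0)
        norms = np.linalg.norm(res.vectors, axis=1)
        assert int(np.argmax(norms)) == 2
        np.testing.assert_allclose(
            norms[2] / norms[0], 0.8 / 0.6, rtol=1e-10
        )


def test_planted_pipeline_rmsip_parameter_recovery():
    """Simulate → covariance → eigendecompose recovers the planted subspace:
    RMSIP(planted, recovered, k=3) ≥ 0.99 at 5000 frames."""
    top, base = _chain(40)
    from trajnet.structio import Structure

    ref = Structure(top, base)
    spec = random_fluctuation_spec(
        ref, variances=(0.9, 0.3, 0.1), n_frames=5000, noise_sigma=0.005, seed=21
    )
    traj = make_gaussian_trajectory(ref, spec)
    model = build_covariance(traj, _sel(40))
    planted = CovarianceModel(
        _sel(40),
        model.mean,
        np.zeros((120, 120)),
        np.array([0.9, 0.3, 0.1]),
        spec.modes.T,
        0,
    )
    value, _ = rmsip(planted, model, 3)
    assert value >= 0.99
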
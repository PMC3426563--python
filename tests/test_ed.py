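import numpy as np
import pytest

from foldens.ed import (EssentialSpace, TransitionVector, covariance_matrix,
                        essential_space, hess_similarity, overlap,
                        random_subspace_gamma, relative_similarity,
                        transition_vector)
from foldens.structures import Ensemble, b_factors
from foldens.synthetic import sample_gaussian_ensemble


def _orthonormal(dim, k, seed):
    q, _ = np.linalg.qr(np.random.default_rng(seed).standard_normal((dim, k)))
    return q


class TestCovariance:
    def test_identical_frames_zero(self, small_helix):
        ens = sample_gaussian_ensemble(small_helix, [], 0.0, 10, seed=0)
        cov = covariance_matrix(ens)
        np.testing.assert_allclose(cov, 0.0, atol=1e-20)

    def test_diagonal_gaussian_variances(self, toy_native):
        sigma = 0.5
        ens = sample_gaussian_ensemble(toy_native, [], sigma, 5000, seed=3)
        cov = covariance_matrix(ens)
        # rigid-body removal leaves a small uniform deficit, well within 10%
        assert np.mean(np.diag(cov)) == pytest.approx(sigma**2, rel=0.10)
        # symmetric PSD
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_trace_matches_b_factors(self, toy_native):
        ens = sample_gaussian_ensemble(toy_native, [], 0.4, 200, seed=4)
        cov = covariance_matrix(ens)
        prof = b_factors(ens, per="atom")
        assert cov.trace() == pytest.approx(
            float(np.sum(prof.per_residue_b * 3 / (8 * np.pi**2))), rel=1e-9)

    def test_single_frame_raises(self, small_helix):
        ens = sample_gaussian_ensemble(small_helix, [], 0.1, 2, seed=0).subset([0])
        with pytest.raises(ValueError):
            covariance_matrix(ens)


class TestEssentialSpace:
    def test_rank_one(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        space = essential_space(np.outer(v, v), n_modes=1)
        assert space.eigenvalues[0] == pytest.approx(v @ v)
        assert abs(space.eigenvectors[:, 0] @ (v / np.linalg.norm(v))) == pytest.approx(1.0)

    def test_identity_covariance(self):
        space = essential_space(np.eye(30), n_modes=5)
        np.testing.assert_allclose(space.eigenvalues, 1.0)
        gram = space.eigenvectors.T @ space.eigenvectors
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_planted_low_rank_plus_noise(self):
        dim = 90
        q = _orthonormal(dim, 3, seed=5)
        lams = np.array([50.0, 30.0, 20.0])
        cov = (q * lams) @ q.T + 0.01 * np.eye(dim)
        space = essential_space(cov, n_modes=3)
        for k in range(3):
            assert abs(space.eigenvectors[:, k] @ q[:, k]) > 0.99

    def test_variance_target_selection(self):
        cov = np.diag([8.0, 1.0, 0.5, 0.5] + [0.0] * 26)
        space = essential_space(cov, variance_target=0.8)
        assert space.n_modes == 1
        space = essential_space(cov, variance_target=0.95)
        assert space.n_modes == 3

    def test_too_many_modes_raises(self):
        with pytest.raises(ValueError):
            essential_space(np.eye(30), n_modes=31)

    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError, match="orthonormal"):
            EssentialSpace(np.ones((30, 2)), np.array([1.0, 0.5]), 10)


class TestHessSimilarity:
    def test_identical_subspaces(self):
        q = _orthonormal(60, 10, seed=1)
        a = EssentialSpace(q, np.arange(10, 0, -1, dtype=float), 20)
        assert hess_similarity(a, a, 10) == pytest.approx(1.0)

    def test_orthogonal_complements(self):
        q = _orthonormal(60, 20, seed=2)
        a = EssentialSpace(q[:, :10], np.arange(10, 0, -1, dtype=float), 20)
        b = EssentialSpace(q[:, 10:], np.arange(10, 0, -1, dtype=float), 20)
        assert hess_similarity(a, b, 10) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        qa = _orthonormal(60, 8, seed=3)
        qb = _orthonormal(60, 8, seed=4)
        ev = np.arange(8, 0, -1, dtype=float)
        a, b = EssentialSpace(qa, ev, 20), EssentialSpace(qb, ev, 20)
        assert hess_similarity(a, b, 8) == pytest.approx(hess_similarity(b, a, 8))

    def test_random_subspace_expectation(self):
        gammas = random_subspace_gamma(300, 10, n_draws=200, seed=6)
        assert gammas.mean() == pytest.approx(10 / 300, rel=0.20)
        assert np.all((gammas >= 0) & (gammas <= 1))

    def test_dimension_mismatch_raises(self):
        a = EssentialSpace(_orthonormal(30, 2, 0), np.array([2.0, 1.0]), 10)
        b = EssentialSpace(_orthonormal(60, 2, 0), np.array([2.0, 1.0]), 20)
        with pytest.raises(ValueError):
            hess_similarity(a, b, 2)


@pytest.fixture(scope="module")
def planted_pair(small_helix):
    rng = np.random.default_rng(8)
    q, _ = np.linalg.qr(rng.standard_normal((60, 2)))
    spec = [(q[:, 0], 100.0), (q[:, 1], 50.0)]
    e1 = sample_gaussian_ensemble(small_helix, spec, 0.1, 2000, seed=10)
    e2 = sample_gaussian_ensemble(small_helix, spec, 0.1, 2000, seed=11)
    return e1, e2


class TestRelativeSimilarity:

    def test_same_frames_kappa_one(self, planted_pair):
        e1, _ = planted_pair
        sim = relative_similarity(e1, e1, n=2)
        assert sim.kappa == pytest.approx(1.0, abs=0.05)
        assert sim.gamma >= min(sim.gamma_self_a, sim.gamma_self_b) - 0.05

    def test_independent_samples_kappa_near_one(self, planted_pair):
        e1, e2 = planted_pair
        sim = relative_similarity(e1, e2, n=2)
        assert 0.9 <= sim.kappa <= 1.1

    def test_orthogonal_modes_kappa_small(self, small_helix):
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.standard_normal((60, 4)))
        e1 = sample_gaussian_ensemble(small_helix, [(q[:, 0], 100.0), (q[:, 1], 50.0)],
                                      0.01, 1000, seed=12)
        e2 = sample_gaussian_ensemble(small_helix, [(q[:, 2], 100.0), (q[:, 3], 50.0)],
                                      0.01, 1000, seed=13)
        sim = relative_similarity(e1, e2, n=2)
        assert sim.kappa < 0.1

    def test_too_few_frames_raises(self, small_helix):
        tiny = sample_gaussian_ensemble(small_helix, [], 0.1, 3, seed=0)
        with pytest.raises(ValueError, match="4 frames"):
            relative_similarity(tiny, tiny, n=2)


class TestTransitionVector:
    def test_displaced_ensembles_give_displacement_direction(self, small_helix):
        from foldens.synthetic import _rigid_subspace
        rng = np.random.default_rng(14)
        d = rng.standard_normal(60)
        rigid = _rigid_subspace(small_helix.coords)
        d -= rigid @ (rigid.T @ d)
        d /= np.linalg.norm(d)
        shifted = small_helix.with_coords((small_helix.coords.ravel() + 20.0 * d).reshape(-1, 3))
        e1 = sample_gaussian_ensemble(small_helix, [], 0.05, 200, seed=15)
        e2 = sample_gaussian_ensemble(shifted, [], 0.05, 200, seed=16)
        tv = transition_vector(e1, e2, seed=0)
        assert abs(tv.r @ d) > 0.99

    def test_self_gives_first_mode(self, small_helix):
        rng = np.random.default_rng(17)
        q, _ = np.linalg.qr(rng.standard_normal((60, 1)))
        ens = sample_gaussian_ensemble(small_helix, [(q[:, 0], 100.0)], 0.05, 500, seed=18)
        tv = transition_vector(ens, ens, seed=0)
        space = essential_space(covariance_matrix(ens), n_modes=1)
        assert abs(tv.r @ space.eigenvectors[:, 0]) > 0.999

    def test_sign_invariance_of_overlap(self, small_helix):
        rng = np.random.default_rng(19)
        ens = sample_gaussian_ensemble(small_helix, [], 0.3, 100, seed=20)
        space = essential_space(covariance_matrix(ens), n_modes=5)
        r = _orthonormal(60, 1, seed=21)[:, 0]
        ov1 = overlap(space, TransitionVector(r), 5)
        ov2 = overlap(space, TransitionVector(-r), 5)
        assert ov1 == pytest.approx(ov2)

    def test_incompatible_topologies_raise(self, small_helix, toy_native):
        e1 = sample_gaussian_ensemble(small_helix, [], 0.1, 10, seed=0)
        e2 = sample_gaussian_ensemble(toy_native, [], 0.1, 10, seed=0)
        with pytest.raises(ValueError):
            transition_vector(e1, e2)


class TestOverlap:
    @pytest.fixture()
    def space(self):
        q = _orthonormal(60, 10, seed=22)
        return EssentialSpace(q, np.arange(10, 0, -1, dtype=float), 20)

    def test_first_mode_full_overlap(self, space):
        r = TransitionVector(space.eigenvectors[:, 0])
        assert overlap(space, r, 5) == pytest.approx(1.0)

    def test_orthogonal_zero(self, space):
        # build a vector orthogonal to all 10 modes
        rng = np.random.default_rng(23)
        v = rng.standard_normal(60)
        v -= space.eigenvectors @ (space.eigenvectors.T @ v)
        v /= np.linalg.norm(v)
        assert overlap(space, TransitionVector(v), 10) == pytest.approx(0.0, abs=1e-10)

    def test_45_degrees(self, space):
        rng = np.random.default_rng(24)
        v = rng.standard_normal(60)
        v -= space.eigenvectors @ (space.eigenvectors.T @ v)
        v /= np.linalg.norm(v)
        r = (space.eigenvectors[:, 0] + v) / np.sqrt(2.0)
        assert overlap(space, TransitionVector(r), 10) == pytest.approx(np.sqrt(0.5))

    def test_monotone_in_n(self, space):
        rng = np.random.default_rng(25)
        r = rng.standard_normal(60)
        r /= np.linalg.norm(r)
        vals = [overlap(space, TransitionVector(r), n) for n in range(1, 11)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="norm"):
            TransitionVector(np.ones(60))

    def test_too_many_modes_requested(self, space):
        r = TransitionVector(space.eigenvectors[:, 0])
        with pytest.raises(ValueError):
            overlap(space, r, 11)


class TestParameterRecovery:
    @pytest.mark.parametrize("n_frames", [100, 1000, 5000])
    def test_gamma_grows_with_sampling(self, small_helix, n_frames):
        rng = np.random.default_rng(26)
        q, _ = np.linalg.qr(rng.standard_normal((60, 3)))
        spec = [(q[:, 0], 100.0), (q[:, 1], 60.0), (q[:, 2], 30.0)]
        e1 = sample_gaussian_ensemble(small_helix, spec, 0.05, n_frames, seed=27)
        e2 = sample_gaussian_ensemble(small_helix, spec, 0.05, n_frames, seed=28)
        s1 = essential_space(covariance_matrix(e1), n_modes=3)
        s2 = essential_space(covariance_matrix(e2), n_modes=3)
        gamma = hess_similarity(s1, s2, 3)
        if not hasattr(self.__class__, "_gammas"):
            self.__class__._gammas = {}
        self.__class__._gammas[n_frames] = gamma
        assert gamma > 0.9
        if len(self.__class__._gammas) == 3:
            gs = self.__class__._gammas
            assert gs[5000] >= gs[100] - 0.02
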
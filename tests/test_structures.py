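import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from foldens.structures import (Structure, b_factors, contact_map,
                                kabsch_superpose, radius_of_gyration, rmsd,
                                sasa, tm_score)
from foldens.synthetic import sample_gaussian_ensemble

from conftest import bead_structure


# ---------------------------------------------------------------------------
# superposition

class TestKabsch:
    def test_identical_coords_zero_rmsd(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 3))
        moved, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(moved, x, atol=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 3)) * 4
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([1.0, 2.0, 3.0])
        _, r = kabsch_superpose(y, x)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self):
        # independent oracle: exhaustive Euler-angle grid + simplex refinement
        rng = np.random.default_rng(11)
        a = rng.standard_normal((4, 3)) * 3
        b = rng.standard_normal((4, 3)) * 3
        _, r_kabsch = kabsch_superpose(a, b)

        am, bm = a - a.mean(0), b - b.mean(0)

        def obj(angles):
            rot = Rotation.from_euler("zyx", angles).as_matrix()
            return rmsd(am @ rot.T, bm)

        grid = np.linspace(0, 2 * np.pi, 25, endpoint=False)
        best, best_ang = np.inf, None
        for x in grid:
            for y in np.linspace(-np.pi / 2, np.pi / 2, 13):
                for z in grid:
                    v = obj([x, y, z])
                    if v < best:
                        best, best_ang = v, [x, y, z]
        res = minimize(obj, best_ang, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert r_kabsch == pytest.approx(res.fun, abs=1e-8)

    def test_rotation_is_proper(self):
        # a mirrored target must not be matched by an improper rotation
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 3))
        y = x.copy()
        y[:, 0] = -y[:, 0]
        _, r = kabsch_superpose(y, x)
        assert r > 0.1

    def test_degenerate_mask_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_small_mask_raises(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(x, x)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rmsd_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((12, 3)) * 5
        b = rng.standard_normal((12, 3)) * 5
        _, r0 = kabsch_superpose(a, b)
        rot = Rotation.random(random_state=seed).as_matrix()
        _, r1 = kabsch_superpose(a @ rot.T + 7.0, b)
        _, r2 = kabsch_superpose(a, b @ rot.T - 3.0)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(r0, abs=1e-9)


# ---------------------------------------------------------------------------
# TM-score

def _tm_oracle(model, ref):
    """Exhaustive superposition oracle: every contiguous seed fragment of
    every length >= 4, each refined by distance-cutoff iteration."""
    n = len(model)
    d0 = 1.24 * (n - 15) ** (1 / 3) - 1.8
    best = 0.0
    for length in range(4, n + 1):
        for start in range(0, n - length + 1):
            cur = np.arange(start, start + length)
            for _ in range(40):
                moved, _ = kabsch_superpose(model, ref, cur)
                d = np.linalg.norm(moved - ref, axis=1)
                best = max(best, float(np.mean(1 / (1 + (d / d0) ** 2))))
                new = np.nonzero(d < d0)[0]
                if len(new) < 4:
                    new = np.argsort(d)[:4]
                new = np.sort(new)
                if np.array_equal(new, cur):
                    break
                cur = new
    return best


class TestTMScore:
    def test_self_is_one(self, small_helix):
        assert tm_score(small_helix.coords, small_helix.coords) == pytest.approx(1.0)

    def test_large_displacement_goes_to_zero(self, small_helix):
        far = small_helix.coords + np.array([500.0, 0.0, 0.0]) * np.arange(20)[:, None]
        score = tm_score(far, small_helix.coords)
        assert 0 < score < 0.25

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        ref = np.cumsum(rng.standard_normal((20, 3)) * 2, axis=0)
        model = ref.copy()
        model[15:] += rng.standard_normal((5, 3)) * 8
        rot = Rotation.random(random_state=5).as_matrix()
        model = model @ rot.T + np.array([3.0, -2.0, 7.0])
        assert tm_score(model, ref) == pytest.approx(_tm_oracle(model, ref), abs=1e-3)

    def test_short_chain_raises(self):
        x = np.random.default_rng(0).standard_normal((15, 3))
        with pytest.raises(ValueError, match="length"):
            tm_score(x, x)

    def test_mismatched_lengths_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            tm_score(rng.standard_normal((20, 3)), rng.standard_normal((21, 3)))

    def test_bounded(self, small_helix):
        rng = np.random.default_rng(9)
        noisy = small_helix.coords + rng.standard_normal((20, 3)) * 2
        score = tm_score(noisy, small_helix.coords)
        assert 0 < score <= 1


# ---------------------------------------------------------------------------
# radius of gyration

class TestRg:
    def test_single_atom(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)])
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(3.0))

    def test_zero_masses_raise(self):
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(np.zeros((3, 3)), np.zeros(3))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((15, 3)) * 6
        rot = Rotation.random(random_state=4).as_matrix()
        assert radius_of_gyration(x @ rot.T + 11.0) == pytest.approx(
            radius_of_gyration(x), abs=1e-10)


# ---------------------------------------------------------------------------
# B-factors

class TestBFactors:
    def test_identical_frames_zero(self, toy_native):
        ens = sample_gaussian_ensemble(toy_native, [], 0.0, 5, seed=0)
        prof = b_factors(ens)
        np.testing.assert_allclose(prof.per_residue_b, 0.0, atol=1e-18)

    def test_isotropic_jitter_expectation(self, toy_native):
        # B = 8 pi^2 sigma^2, up to the (3N-6)/3N rigid-body deficit
        sigma = 0.3
        ens = sample_gaussian_ensemble(toy_native, [], sigma, 10_000, seed=7)
        prof = b_factors(ens, per="atom")
        expected = 8 * np.pi**2 * sigma**2
        assert prof.per_residue_b.mean() == pytest.approx(expected, rel=0.05)

    def test_locality_of_mobile_residue(self, toy_native):
        from foldens.structures import Ensemble
        rng = np.random.default_rng(0)
        frames = np.repeat(toy_native.coords[None], 50, axis=0)
        frames[:, 30, :] += rng.standard_normal((50, 3)) * 2.0
        mask = np.ones(60, dtype=bool)
        mask[30] = False  # align on the frozen part
        ens = Ensemble(toy_native, frames, align_mask=mask)
        prof = b_factors(ens)
        assert np.argmax(prof.per_residue_b) == 30
        others = np.delete(prof.per_residue_b, 30)
        assert prof.per_residue_b[30] > 100 * others.max()

    def test_single_frame_raises(self, toy_native):
        ens = sample_gaussian_ensemble(toy_native, [], 0.1, 2, seed=0).subset([0])
        with pytest.raises(ValueError, match="2 frames"):
            b_factors(ens)


# ---------------------------------------------------------------------------
# contacts

class TestContactMap:
    def test_distant_residues_no_contact(self):
        s = bead_structure([[0, 0, 0], [20.0, 0, 0]])
        cm = contact_map(s, cutoff=5.5, min_seq_sep=1)
        assert cm.pairs == set()

    def test_collinear_triplet(self):
        s = bead_structure([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        cm = contact_map(s, cutoff=5.5, min_seq_sep=1)
        assert cm.pairs == {(1, 2), (2, 3)}
        assert [cm.per_residue_counts[r] for r in (1, 2, 3)] == [1, 2, 1]

    def test_seq_separation_filter(self):
        s = bead_structure([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        cm = contact_map(s, cutoff=5.5, min_seq_sep=3)
        assert cm.pairs == set()

    def test_invalid_params(self, small_helix):
        with pytest.raises(ValueError):
            contact_map(small_helix, cutoff=-1.0)
        with pytest.raises(ValueError):
            contact_map(small_helix, min_seq_sep=0)

    def test_cbeta_mode_runs_on_bead_model(self, small_helix):
        cm = contact_map(small_helix, mode="cbeta")
        assert cm.n_contacts > 0


# ---------------------------------------------------------------------------
# SASA

class TestSASA:
    def test_isolated_atom_analytic_sphere(self):
        s = bead_structure([[0.0, 0, 0]])
        res = sasa(s, probe_radius=1.4, n_points=960)
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert res.per_atom_area[0] == pytest.approx(analytic, rel=0.02)

    def test_enclosed_atom_zero(self):
        s = Structure(["CA", "S"], [1, 2], ["ALA", "ALA"],
                      [[0, 0, 0], [0, 0, 0.05]], ["C", "S"],
                      np.array([0.4, 1.8]))
        res = sasa(s, n_points=240)
        assert res.per_atom_area[0] == 0.0

    def test_separated_atoms_full_area(self):
        s = bead_structure([[0, 0, 0], [0, 0, 50.0]])
        res = sasa(s, n_points=240)
        full = 4 * np.pi * 3.1**2
        np.testing.assert_allclose(res.per_atom_area, full, rtol=1e-9)

    def test_burial_monotonic_with_overlap(self):
        prev = np.inf
        for d in (7.0, 5.0, 3.0, 1.5):
            s = bead_structure([[0, 0, 0], [0, 0, d]])
            total = sasa(s, n_points=480).total_area
            assert total <= prev + 1e-6
            prev = total

    def test_coincident_atoms_deterministic(self):
        s = bead_structure([[0, 0, 0], [0, 0, 0]])
        r1 = sasa(s, n_points=240)
        r2 = sasa(s, n_points=240)
        np.testing.assert_array_equal(r1.per_atom_area, r2.per_atom_area)

    def test_too_few_points_raises(self, small_helix):
        with pytest.raises(ValueError, match="n_points"):
            sasa(small_helix, n_points=10)

    def test_trp_area_sums_trp_residues(self, toy_native):
        res = sasa(toy_native, n_points=240)
        manual = sum(res.per_residue_area[r] for r in (8, 15, 47, 54))
        assert res.trp_area == pytest.approx(manual)  # bead fallback = whole residue
        assert res.trp_area <= res.total_area
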
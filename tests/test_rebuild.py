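"""Backbone reconstruction: geometry extraction, constraints, placement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from adafa.rebuild import (
    CaTrace,
    InternalGeometry,
    add_constraint_noise,
    add_distance_noise,
    build_from_geometry,
    extract_geometry,
    geometry_to_distances,
    place_next_ca,
    placement_energy,
    read_ca_trace,
    rebuild_chain,
    seed_first_four,
    synthetic_helix,
    write_ca_trace,
)
from adafa.metrics import superpose_rmsd


def random_chain(rng, n=8, step=3.8):
    # non-degenerate walk with realistic consecutive spacing
    dirs = rng.normal(size=(n - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(step * dirs, axis=0)])


class TestSyntheticHelix:
    def test_consecutive_distances_constant_and_canonical(self):
        h = synthetic_helix(30)
        d = np.linalg.norm(np.diff(h.coords, axis=0), axis=1)
        assert np.allclose(d, d[0])
        assert 3.7 <= d[0] <= 3.9

    def test_uniform_internal_coordinates(self):
        g = extract_geometry(synthetic_helix(25))
        assert np.allclose(g.bond_angles, g.bond_angles[0])
        assert np.allclose(g.dihedrals, g.dihedrals[0])

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            synthetic_helix(4)


class TestExtractGeometry:
    def test_rigid_invariance(self, rng):
        X = random_chain(rng)
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        Y = X @ R.T + np.array([10.0, -3.0, 7.0])
        g1, g2 = extract_geometry(X), extract_geometry(Y)
        assert np.allclose(g1.bond_lengths, g2.bond_lengths)
        assert np.allclose(g1.bond_angles, g2.bond_angles)
        assert np.allclose(g1.dihedrals, g2.dihedrals)

    def test_mirror_negates_dihedrals_only(self, rng):
        X = random_chain(rng)
        Y = X * np.array([1.0, 1.0, -1.0])
        g1, g2 = extract_geometry(X), extract_geometry(Y)
        assert np.allclose(g1.bond_lengths, g2.bond_lengths)
        assert np.allclose(g1.bond_angles, g2.bond_angles)
        assert np.allclose(g1.dihedrals, -g2.dihedrals)

    def test_round_trip_with_exact_placer(self, rng):
        """Extract -> exact internal-to-Cartesian rebuild -> RMSD ~ 0."""
        for _ in range(5):
            X = random_chain(rng, n=10)
            Y = build_from_geometry(extract_geometry(X))
            assert superpose_rmsd(X, Y) < 1e-9

    def test_collinear_triple_raises_with_index(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0], [4, 1, 1]], dtype=float)
        with pytest.raises(ValueError, match="residue"):
            extract_geometry(X)

    def test_too_short(self):
        with pytest.raises(ValueError):
            extract_geometry(np.zeros((3, 3)))


class TestGeometryToDistances:
    def test_adjacent_target_is_bond_length(self, rng):
        g = extract_geometry(random_chain(rng, n=9))
        c = geometry_to_distances(g)
        assert np.allclose(c.targets[:, 0], g.bond_lengths[3:])

    def test_straight_chain_collinear_limit(self):
        # theta = 180 degrees everywhere: d(i, i-2) = b_i + b_{i-1}
        n = 6
        g = InternalGeometry(
            bond_lengths=np.full(n - 1, 3.8),
            bond_angles=np.full(n - 2, 180.0),
            dihedrals=np.zeros(n - 3),
        )
        c = geometry_to_distances(g)
        assert np.allclose(c.targets[:, 1], 7.6)
        assert np.allclose(c.targets[:, 3], 4 * 3.8)

    def test_generic_matches_exact_conversion(self, rng):
        X = random_chain(rng, n=9)
        g = extract_geometry(X)
        c = geometry_to_distances(g)
        Y = build_from_geometry(g)
        for i in range(4, 9):
            measured = [np.linalg.norm(Y[i] - Y[i - 1 - j]) for j in range(4)]
            assert np.allclose(c.targets[i - 4], measured)


class TestPlacementEnergy:
    def test_native_position_zero(self, rng):
        X = random_chain(rng, n=6)
        targets = [np.linalg.norm(X[5] - X[4 - j]) for j in range(4)]
        assert placement_energy(X[5], X[4::-1][:4], targets) == pytest.approx(0.0)

    def test_single_violation_squares(self):
        prev = np.array([[0, 0, 0], [0, 0, 2], [0, 2, 0], [2, 0, 0]], dtype=float)
        cand = np.array([1.0, 0.0, 0.0])
        d = np.linalg.norm(prev - cand, axis=1)
        targets = d.copy()
        targets[0] += 0.3
        assert placement_energy(cand, prev, targets) == pytest.approx(0.09)

    def test_matches_term_by_term_sum(self, rng):
        prev = rng.normal(size=(4, 3))
        cand = rng.normal(size=3)
        targets = rng.uniform(1, 5, size=4)
        brute = sum((np.linalg.norm(cand - prev[j]) - targets[j]) ** 2 for j in range(4))
        assert placement_energy(cand, prev, targets) == pytest.approx(brute)
        brute_abs = sum(abs(np.linalg.norm(cand - prev[j]) - targets[j]) for j in range(4))
        assert placement_energy(cand, prev, targets, form="abs") == pytest.approx(brute_abs)


class TestSeedFirstFour:
    def test_prefix_geometry_round_trip(self, rng):
        g = extract_geometry(random_chain(rng, n=8))
        four = seed_first_four(g, rng)
        gp = extract_geometry(four)
        assert np.allclose(gp.bond_lengths, g.bond_lengths[:3])
        assert np.allclose(gp.bond_angles, g.bond_angles[:2])
        assert np.allclose(gp.dihedrals, g.dihedrals[:1])

    def test_two_seeds_rigid_related(self, rng):
        g = extract_geometry(random_chain(rng, n=8))
        a = seed_first_four(g, np.random.default_rng(1))
        b = seed_first_four(g, np.random.default_rng(2))
        assert superpose_rmsd(a, b) < 1e-9


class TestPlaceNextCa:
    def test_noise_free_reaches_tolerance(self, rng):
        X = random_chain(rng, n=6)
        prev4 = X[4::-1][:4]
        targets = np.array([np.linalg.norm(X[5] - X[4 - j]) for j in range(4)])
        pos, e = place_next_ca(prev4, targets, seed=3)
        assert e < 1e-6
        assert np.linalg.norm(pos - X[5]) < 1e-3

    def test_seed_determinism(self, rng):
        X = random_chain(rng, n=6)
        prev4 = X[4::-1][:4]
        targets = np.array([np.linalg.norm(X[5] - X[4 - j]) for j in range(4)])
        p1, e1 = place_next_ca(prev4, targets, seed=11)
        p2, e2 = place_next_ca(prev4, targets, seed=11)
        assert np.array_equal(p1, p2) and e1 == e2

    def test_search_box_contains_native_atom(self, rng):
        from adafa.rebuild import _PlacementProblem
        X = random_chain(rng, n=6)
        prev4 = X[4::-1][:4]
        targets = np.array([np.linalg.norm(X[5] - X[4 - j]) for j in range(4)])
        prob = _PlacementProblem(prev4, targets, "squared")
        assert np.all(X[5] >= prob.space.lower) and np.all(X[5] <= prob.space.upper)


class TestRebuildChain:
    def test_short_helix_high_accuracy(self):
        h = synthetic_helix(10)
        g = extract_geometry(h)
        tr, en = rebuild_chain(g, seed=0)
        assert len(tr) == 10
        assert superpose_rmsd(tr, h) < 0.5
        assert en.max() < 1e-6

    def test_rebuilt_geometry_matches_input(self):
        h = synthetic_helix(9)
        g = extract_geometry(h)
        tr, en = rebuild_chain(g, seed=1)
        g2 = extract_geometry(tr)
        assert np.allclose(g.bond_lengths, g2.bond_lengths, atol=1e-3)
        assert np.allclose(g.bond_angles, g2.bond_angles, atol=0.1)

    def test_too_short_raises(self):
        g = extract_geometry(synthetic_helix(5).coords[:4])
        with pytest.raises(ValueError):
            rebuild_chain(g)


class TestConstraintNoise:
    def test_zero_fraction_is_identity(self, rng):
        g = extract_geometry(synthetic_helix(12))
        g2 = add_constraint_noise(g, 0.0, rng)
        assert np.array_equal(g.bond_lengths, g2.bond_lengths)
        assert np.array_equal(g.dihedrals, g2.dihedrals)

    def test_perturbation_mean_zero_monte_carlo(self):
        rng = np.random.default_rng(7)
        g = extract_geometry(synthetic_helix(6))
        b0 = g.bond_lengths[0]
        draws = np.array([add_constraint_noise(g, 0.1, rng).bond_lengths[0]
                          for _ in range(10_000)])
        se = 0.1 * b0 / np.sqrt(draws.size)
        assert abs(draws.mean() - b0) < 3 * se

    def test_angle_ranges_preserved(self):
        rng = np.random.default_rng(3)
        g = extract_geometry(synthetic_helix(20))
        for _ in range(50):
            gn = add_constraint_noise(g, 0.3, rng)
            assert np.all(gn.bond_angles > 0) and np.all(gn.bond_angles < 180)
            assert np.all(gn.dihedrals > -180) and np.all(gn.dihedrals <= 180)

    def test_distance_noise_alternative(self, rng):
        g = extract_geometry(synthetic_helix(10))
        c = geometry_to_distances(g)
        cn = add_distance_noise(c, 0.1, rng)
        assert cn.targets.shape == c.targets.shape
        assert np.all(cn.targets > 0)
        assert not np.allclose(cn.targets, c.targets)


class TestPdbIo:
    def test_write_read_round_trip(self, tmp_path):
        h = synthetic_helix(15)
        path = tmp_path / "helix.pdb"
        write_ca_trace(h, path)
        back = read_ca_trace(path)
        assert len(back) == 15
        assert np.allclose(back.coords, np.round(h.coords, 3), atol=5e-4)
        assert back.residue_ids == h.residue_ids

    def test_missing_chain_raises(self, tmp_path):
        h = synthetic_helix(6)
        path = tmp_path / "helix.pdb"
        write_ca_trace(h, path)
        with pytest.raises(ValueError, match="chain"):
            read_ca_trace(path, chain="Z")
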
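import numpy as np
import pytest

from distmap.io_structures import CaTrace, SecondaryStructure
from distmap.maps import BinaryMap, binarize, distance_map, quantize_4class
from distmap.metrics import kabsch
from distmap.reconstruct import (AnnealingConfig, PseudoEnergyParams, anneal,
                                 build_constraints, init_conformation, mirror,
                                 pseudo_energy, reconstruct, strand_interval)

PARAMS = PseudoEnergyParams()


class TestStrandInterval:
    def test_two_residue_hand_values(self):
        d_min, d_max = strand_interval(2)
        assert d_min == pytest.approx(2 * 3.436 - 2 * 0.05107 - 0.04 * 4)
        assert d_min == pytest.approx(6.60986)
        assert d_max == pytest.approx(6.92986)

    def test_width_is_twice_the_quadratic_term(self):
        d_min, d_max = strand_interval(5)
        assert d_max - d_min == pytest.approx(2 * 0.04 * 25)

    def test_upper_bound_monotone_up_to_40(self):
        uppers = [strand_interval(l)[1] for l in range(2, 41)]
        assert all(b > a for a, b in zip(uppers, uppers[1:]))

    def test_too_short_strand_is_an_error(self):
        with pytest.raises(ValueError):
            strand_interval(1)


class TestBuildConstraints:
    def test_all_coil_has_no_strand_constraints(self):
        ss = SecondaryStructure("C" * 10)
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 3.803
        cons = build_constraints(distance_map(CaTrace(coords)), ss, PARAMS)
        assert len(cons.strand_a) == 0

    def test_native_under_own_map_has_zero_map_and_strand_terms(self, mixed_fold):
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        # total energy minus bond term must vanish: map distances match
        # exactly and native strands sit inside their intervals
        e = pseudo_energy(trace, cons, PARAMS)
        bonds = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
        bond_term = np.sum((bonds - PARAMS.bond_length) ** 2)
        assert e == pytest.approx(bond_term, abs=1e-9)

    def test_binary_contact_within_threshold_has_flat_bottom(self):
        contacts = np.ones((2, 2), dtype=bool)
        bmap = BinaryMap(contacts, threshold=12.0)
        ss = SecondaryStructure("CC")
        cons = build_constraints(bmap, ss, PARAMS)
        # two bonded residues at 11 A: map term zero (flat bottom), only the
        # bond term remains
        coords = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        e = pseudo_energy(CaTrace(coords), cons, PARAMS)
        assert e == pytest.approx((11.0 - PARAMS.bond_length) ** 2, abs=1e-12)

    def test_length_mismatch_is_an_error(self, mixed_fold):
        trace, _ = mixed_fold
        with pytest.raises(ValueError):
            build_constraints(distance_map(trace),
                              SecondaryStructure("C" * (len(trace) + 1)),
                              PARAMS)


class TestPseudoEnergy:
    def test_native_with_ideal_bonds_is_zero(self, coil_fold):
        """All four terms vanish on a native with ideal bonds; the only
        residual is double-precision roundoff in the bond distances
        (~1e-30), far below any physical scale."""
        trace, ss = coil_fold
        bonds = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, PARAMS.bond_length, atol=1e-12)
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        assert pseudo_energy(trace, cons, PARAMS) == pytest.approx(0.0, abs=1e-18)

    def test_clash_term_hand_value(self):
        # residues 0 and 2 at 3 A (< 4 A cutoff), bonds exactly 3.803 A and
        # an exact map except for that pair: E = 0.5 * 10 * (4 - 3) = 5
        h = np.sqrt(3.803**2 - 1.5**2)
        coords = np.array([[-1.5, 0, 0], [0.0, h, 0], [1.5, 0, 0]])
        trace = CaTrace(coords)
        cons = build_constraints(distance_map(trace), SecondaryStructure("CCC"),
                                 PARAMS)
        assert pseudo_energy(trace, cons, PARAMS) == pytest.approx(5.0, abs=1e-9)

    def test_bond_term_hand_value(self):
        coords = np.array([[0.0, 0, 0], [4.803, 0, 0]])
        trace = CaTrace(coords)
        cons = build_constraints(distance_map(trace), SecondaryStructure("CC"),
                                 PARAMS)
        assert pseudo_energy(trace, cons, PARAMS) == pytest.approx(1.0, abs=1e-12)

    def test_energy_is_non_negative_for_perturbed_conformations(self, mixed_fold, rng):
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        for _ in range(5):
            noisy = trace.with_coords(trace.coords + rng.normal(scale=2.0,
                                                                size=(len(trace), 3)))
            assert pseudo_energy(noisy, cons, PARAMS) >= 0.0

    def test_exp_clash_alternative(self):
        params = PseudoEnergyParams(clash_form="exp10")
        h = np.sqrt(3.803**2 - 1.5**2)
        coords = np.array([[-1.5, 0, 0], [0.0, h, 0], [1.5, 0, 0]])
        trace = CaTrace(coords)
        cons = build_constraints(distance_map(trace), SecondaryStructure("CCC"),
                                 params)
        e = pseudo_energy(trace, cons, params)
        # clash pair at d=3: 0.5 * 10^(4-3) = 5; non-clashing pairs add their
        # exponentially small tails
        assert e == pytest.approx(0.5 * 10.0, rel=0.01)


class TestInitConformation:
    def test_coil_bond_lengths_within_tolerance(self):
        ss = SecondaryStructure("C" * 10)
        trace = init_conformation(ss, seed=4)
        bonds = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
        assert np.all(bonds >= 3.803 - 0.07 - 1e-12)
        assert np.all(bonds <= 3.803 + 0.07 + 1e-12)

    def test_helix_run_has_ideal_geometry(self):
        ss = SecondaryStructure("H" * 12)
        trace = init_conformation(ss, seed=4)
        v = distance_map(trace).values
        d13 = [v[i, i + 3] for i in range(9)]
        assert all(5.0 <= d <= 5.6 for d in d13)

    def test_same_seed_is_deterministic(self):
        ss = SecondaryStructure("CCHHHHCCEEC")
        a = init_conformation(ss, seed=9)
        b = init_conformation(ss, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = init_conformation(ss, seed=10)
        assert not np.array_equal(a.coords, c.coords)


class TestAnneal:
    def test_zero_iterations_returns_start(self, mixed_fold):
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        start = init_conformation(ss, seed=1)
        out, e = anneal(start, cons, PARAMS, n_iterations=0)
        np.testing.assert_array_equal(out.coords, start.coords)
        assert e == pytest.approx(pseudo_energy(start, cons, PARAMS))

    def test_moves_preserve_bond_lengths_exactly(self, mixed_fold):
        """The move operator rotates a residue about its neighbour axis, so
        the multiset of bond lengths can never change during annealing."""
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        start = init_conformation(ss, seed=2)
        bonds_before = np.linalg.norm(np.diff(start.coords, axis=0), axis=1)
        out, _ = anneal(start, cons, PARAMS, seed=3, n_iterations=20_000)
        assert not np.array_equal(out.coords, start.coords)
        bonds_after = np.linalg.norm(np.diff(out.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds_after, bonds_before, atol=1e-9)

    def test_converges_on_exact_map(self, mixed_fold):
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        start = init_conformation(ss, seed=5)
        e_start = pseudo_energy(start, cons, PARAMS)
        _, e_end = anneal(start, cons, PARAMS,
                          config=AnnealingConfig(), seed=6)
        assert np.isfinite(e_end)
        assert e_end < 0.01 * e_start

    def test_same_seed_bitwise_reproducible(self, mixed_fold):
        trace, ss = mixed_fold
        cons = build_constraints(distance_map(trace), ss, PARAMS)
        start = init_conformation(ss, seed=5)
        a, ea = anneal(start, cons, PARAMS, seed=8, n_iterations=50_000)
        b, eb = anneal(start, cons, PARAMS, seed=8, n_iterations=50_000)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert ea == eb


class TestMirror:
    def test_distances_preserved(self, mixed_fold, rng):
        trace, _ = mixed_fold
        a = distance_map(trace).values
        b = distance_map(mirror(trace)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_involution(self, mixed_fold):
        trace, _ = mixed_fold
        np.testing.assert_array_equal(mirror(mirror(trace)).coords, trace.coords)

    def test_helix_handedness_flips(self):
        """The signed dihedral of four consecutive Calpha changes sign."""
        ss = SecondaryStructure("H" * 10)
        trace = init_conformation(ss, seed=1)

        def dihedral(p):
            b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n0, n1 = np.cross(b0, b1), np.cross(b1, b2)
            m = np.cross(n0, b1 / np.linalg.norm(b1))
            return np.arctan2(m @ n1, n0 @ n1)

        d_orig = dihedral(trace.coords[:4])
        d_mirr = dihedral(mirror(trace).coords[:4])
        assert d_orig == pytest.approx(-d_mirr)
        assert abs(d_orig) > 0.1


class TestReconstruct:
    def test_single_run_exact_map_converges(self, mixed_fold):
        trace, ss = mixed_fold
        res = reconstruct(distance_map(trace), ss,
                          config=AnnealingConfig(n_runs=1, seed=7),
                          native=trace)
        assert res.best_rmsd < 1.0

    def test_best_energy_is_the_minimum_over_runs(self, mixed_fold):
        trace, ss = mixed_fold
        res = reconstruct(distance_map(trace), ss,
                          config=AnnealingConfig(n_runs=3, seed=11,
                                                 iterations_per_residue=1000))
        assert res.best_energy == min(r.energy for r in res.runs)
        assert all(np.isfinite(r.energy) for r in res.runs)

    def test_blind_selection_is_accurate_up_to_chirality(self):
        """The energy cannot see chirality (mirror images share the map), so
        the blind pick is assessed after folding out the mirror: it lands
        within 1 A of the native on at least 8 of 10 fixtures."""
        from distmap.synthetic import make_fold_suite
        suite = make_fold_suite(10, 24, seed=5)
        good = 0
        for i, (trace, ss) in enumerate(suite):
            res = reconstruct(distance_map(trace), ss,
                              config=AnnealingConfig(n_runs=10, seed=50 + i),
                              native=trace)
            r = min(kabsch(res.best, trace).rmsd,
                    kabsch(mirror(res.best), trace).rmsd)
            good += r < 1.0
        assert good >= 8

    def test_full_determinism(self, mixed_fold):
        trace, ss = mixed_fold
        cfg = AnnealingConfig(n_runs=2, seed=21, iterations_per_residue=2000)
        a = reconstruct(distance_map(trace), ss, config=cfg)
        b = reconstruct(distance_map(trace), ss, config=cfg)
        np.testing.assert_array_equal(a.best.coords, b.best.coords)
        assert a.best_energy == b.best_energy

    def test_coarse_maps_also_reconstruct(self, mixed_fold):
        trace, ss = mixed_fold
        for m in (quantize_4class(distance_map(trace)),
                  binarize(distance_map(trace))):
            res = reconstruct(m, ss,
                              config=AnnealingConfig(n_runs=2, seed=3),
                              native=trace)
            assert res.best_rmsd < 6.0
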
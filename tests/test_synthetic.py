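"""Crystal generator and direct-summation structure-factor tests."""

import numpy as np
import pytest

from helixtps import (
    Atom,
    CrystalModel,
    HelixSpec,
    SpaceGroupOps,
    UnitCell,
    build_aform_duplex,
    calc_structure_factors,
    perturb_turns,
    place_in_cell,
    random_atom_structure,
    simulate_reference_pair,
    translation_rmsd,
)
from helixtps.synthetic import DSRNA_CELL, unique_reflections


def brute_force_F(model, hkl):
    """Independent oracle: literal symmetry + atom double sum for one index."""
    total = 0.0 + 0.0j
    s2 = 1.0 / model.cell.d_spacings(np.array([hkl]))[0] ** 2
    sym = model.symmetry
    for rot, tran in zip(sym.rotations, sym.translations):
        for a in model.atoms:
            x = rot @ a.position + tran
            w = a.scattering_weight * a.occupancy * np.exp(-a.b_iso * s2 / 4.0)
            total += w * np.exp(2j * np.pi * np.dot(hkl, x))
    return total


class TestDuplexBuilder:
    def test_turn_annotation_partitions_32bp_as_11_11_10(self):
        model = build_aform_duplex(HelixSpec(n_bp=32))
        turns = model.turns()
        bp = np.array([a.bp_index for a in model.atoms])
        counts = [len(np.unique(bp[turns == t])) for t in (0, 1, 2)]
        assert counts == [11, 11, 10]

    def test_single_base_pair_is_degenerate_turn_zero(self):
        model = build_aform_duplex(HelixSpec(n_bp=1, sequence="G"))
        assert set(model.turns()) == {0}
        assert len({a.strand for a in model.atoms}) == 2

    def test_unknown_base_is_rejected_naming_position(self):
        with pytest.raises(ValueError, match="position 2"):
            build_aform_duplex(HelixSpec(n_bp=4, sequence="AGXU"))

    def test_consecutive_p_atoms_separated_by_rise(self):
        spec = HelixSpec(n_bp=8)
        model = build_aform_duplex(spec)
        pz = sorted(a.position[2] for a in model.atoms
                    if a.name == "P" and a.strand == 0)
        assert np.allclose(np.diff(pz), spec.rise, atol=1e-9)


class TestPlacement:
    def test_identity_placement_in_p1_fractionalizes(self):
        frag = build_aform_duplex(HelixSpec(n_bp=2))
        cell = UnitCell(30.0, 30.0, 30.0)
        model = place_in_cell(frag, cell, "P1", origin_offset=(0.5, 0.5, 0.5))
        cart = frag.positions() @ cell.frac_matrix.T + [0.5, 0.5, 0.5]
        assert np.allclose(model.positions(), cart % 1.0, atol=1e-12)

    def test_fractionalize_orthogonalize_round_trip(self):
        cell = DSRNA_CELL
        rng = np.random.default_rng(0)
        cart = rng.uniform(-20, 20, (50, 3))
        assert np.allclose(cell.orthogonalize(cell.fractionalize(cart)), cart,
                           atol=1e-9)

    def test_duplex_fits_inside_cell_cross_section(self):
        frag = build_aform_duplex(HelixSpec(n_bp=32))
        model = place_in_cell(frag, DSRNA_CELL, "R32:H",
                              origin_offset=(0.25, 0.0, 0.0), asu_strand=0)
        # minimal-image displacement of every atom from the duplex axis stays
        # within half a cell edge (the duplex does not overlap its images)
        axis = np.array([0.25, 0.0, 0.0])
        rel = (model.positions() - axis + 0.5) % 1.0 - 0.5
        radial = np.linalg.norm(model.cell.orthogonalize(rel)[:, :2], axis=1)
        assert radial.max() < DSRNA_CELL.a / 2

    def test_unsupported_space_group_lists_alternatives(self):
        frag = build_aform_duplex(HelixSpec(n_bp=2))
        with pytest.raises(ValueError, match="P1, R32:H, P43"):
            place_in_cell(frag, UnitCell(30, 30, 30), "C2")


class TestPerturbation:
    def test_zero_imperfection_is_identity(self, asu_duplex):
        model, _ = asu_duplex
        out = perturb_turns(model, 0.0, 0.0, seed=3)
        assert np.array_equal(out.positions(), model.positions())
        assert np.array_equal(out.weights(), model.weights())

    def test_same_seed_is_bit_identical(self, asu_duplex):
        model, _ = asu_duplex
        a = perturb_turns(model, 0.4, 0.2, seed=11)
        b = perturb_turns(model, 0.4, 0.2, seed=11)
        assert np.array_equal(a.positions(), b.positions())
        assert np.array_equal(a.weights(), b.weights())

    def test_displacive_sigma_sets_interturn_rmsd(self, asu_duplex):
        """Two independently jittered turns differ by ~sigma*sqrt(2)."""
        model, partition = asu_duplex
        sigma = 0.9
        vals = [translation_rmsd(perturb_turns(model, sigma, 0.0, seed=s),
                                 partition, 0, 1, "backbone").rmsd
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(2), rel=0.10)

    def test_rmsd_vanishes_as_sigma_decreases(self, asu_duplex):
        model, partition = asu_duplex
        rmsds = [np.mean([translation_rmsd(perturb_turns(model, s, 0.0, seed=i),
                                           partition, 0, 1, "all").rmsd
                          for i in range(3)])
                 for s in (1.0, 0.1, 0.01, 0.001)]
        assert all(a > b for a, b in zip(rmsds, rmsds[1:]))
        assert rmsds[-1] < 0.01

    def test_replacive_changes_weights_not_backbone_positions(self, asu_duplex):
        model, _ = asu_duplex
        out = perturb_turns(model, 0.0, 0.5, seed=2)
        assert np.array_equal(out.positions(), model.positions())
        assert not np.array_equal(out.weights(), model.weights())

    def test_missing_turn_annotations_rejected(self):
        model = random_atom_structure(5, UnitCell(10, 10, 10), seed=0)
        with pytest.raises(ValueError, match="turn annotations"):
            perturb_turns(model, 0.1, 0.0, seed=0)


class TestRandomAtoms:
    def test_reproducible_and_uniform(self):
        cell = UnitCell(40.0, 45.0, 50.0)
        a = random_atom_structure(675, cell, seed=9)
        b = random_atom_structure(675, cell, seed=9)
        assert np.array_equal(a.positions(), b.positions())
        assert len(a.atoms) == 675

    def test_nearest_neighbour_distance_matches_uniform_oracle(self):
        """Mean NN distance agrees with a direct Monte-Carlo resampling."""
        from scipy.spatial import cKDTree

        cell = UnitCell(30.0, 30.0, 30.0)

        def mean_nn(seed):
            m = random_atom_structure(400, cell, seed=seed)
            cart = m.positions() * 30.0  # orthogonal cell
            d, _ = cKDTree(cart, boxsize=30.0).query(cart, k=2)
            return d[:, 1].mean()

        mine = np.mean([mean_nn(s) for s in range(5)])
        rng = np.random.default_rng(123)
        oracle = np.mean([
            cKDTree(p, boxsize=30.0).query(p, k=2)[0][:, 1].mean()
            for p in (rng.uniform(0, 30, (400, 3)) for _ in range(5))
        ])
        assert mine == pytest.approx(oracle, rel=0.03)


class TestStructureFactors:
    def test_point_atom_at_origin_gives_flat_amplitudes(self):
        cell = UnitCell(10, 10, 10)
        model = CrystalModel(cell, SpaceGroupOps("P1"),
                             [Atom("C", np.zeros(3), 1.0, 0.0)])
        rs = calc_structure_factors(model, d_min=2.0)
        assert np.allclose(rs.F, 6.0, atol=1e-9)
        assert np.allclose(rs.phase, 0.0, atol=1e-9)

    def test_shift_theorem_preserves_amplitudes(self):
        cell = UnitCell(12, 13, 14)
        rng = np.random.default_rng(4)
        pos = rng.random((6, 3))
        shift = np.array([0.137, 0.421, 0.777])
        m1 = CrystalModel(cell, SpaceGroupOps("P1"),
                          [Atom("O", p, 1.0, 5.0) for p in pos])
        m2 = CrystalModel(cell, SpaceGroupOps("P1"),
                          [Atom("O", (p + shift) % 1.0, 1.0, 5.0) for p in pos])
        r1 = calc_structure_factors(m1, d_min=2.5)
        r2 = calc_structure_factors(m2, d_min=2.5)
        assert np.allclose(r1.F, r2.F, atol=1e-9 * r1.F.max())

    def test_friedel_mates_have_equal_amplitudes(self, three_copy_set):
        model, rs = three_copy_set
        sel = np.arange(0, len(rs), max(1, len(rs) // 40))
        for i in sel:
            F_minus = brute_force_F(model, -rs.hkl[i])
            assert abs(F_minus) == pytest.approx(rs.F[i], abs=1e-8 * (1 + rs.F[i]))

    def test_direct_sum_matches_brute_force_in_r32(self, dsrna_pair):
        model, rs = dsrna_pair
        for i in (0, len(rs) // 3, len(rs) - 1):
            oracle = brute_force_F(model, rs.hkl[i])
            assert abs(oracle) == pytest.approx(rs.F[i], rel=1e-8, abs=1e-6)

    def test_two_scatterers_ninth_apart_closed_form(self):
        """|F(hkl)|^2 = 2 f^2 (1 + cos(2 pi l / 9)): maxima at l = 9n,
        near-extinction at l = 9n +/- 4, 5."""
        cell = UnitCell(20, 20, 90)
        model = CrystalModel(cell, SpaceGroupOps("P1"), [
            Atom("C", np.array([0.1, 0.2, 0.0]), 1.0, 0.0),
            Atom("C", np.array([0.1, 0.2, 1.0 / 9.0]), 1.0, 0.0),
        ])
        rs = calc_structure_factors(model, d_min=3.0)
        l = rs.hkl[:, 2]
        pred = 2 * 36.0 * (1 + np.cos(2 * np.pi * l / 9.0))
        assert np.allclose(rs.F**2, pred, atol=1e-9)
        mean_by_class = {r: (rs.F[np.abs(l) % 9 == r] ** 2).mean()
                         for r in range(9) if np.any(np.abs(l) % 9 == r)}
        assert mean_by_class[0] == max(mean_by_class.values())
        assert mean_by_class[4] < 0.15 * mean_by_class[0]
        assert mean_by_class[5] < 0.15 * mean_by_class[0]

    def test_perfect_m_copy_translation_extinguishes_off_classes(self, three_copy_set):
        _, rs = three_copy_set
        off = rs.hkl[:, 2] % 3 != 0
        assert rs.F[off].max() < 1e-9 * rs.F.max()

    def test_empty_model_rejected(self):
        model = CrystalModel(UnitCell(10, 10, 10), SpaceGroupOps("P1"), [])
        with pytest.raises(ValueError, match="empty"):
            calc_structure_factors(model, d_min=2.0)

    def test_unique_reflection_set_matches_gemmi_asu(self):
        """Cross-check the unique-index generator against gemmi's ASU."""
        import gemmi

        sym = SpaceGroupOps("R32:H")
        mine = unique_reflections(DSRNA_CELL, sym, 2.0)
        ref = np.asarray(gemmi.make_miller_array(
            DSRNA_CELL.gemmi(), sym.gemmi_sg(), 2.0))
        assert len(mine) == len(ref)
        # same reflections up to choice of asymmetric-unit representative
        canon_mine = {tuple(h) for h in sym.canonical(mine)}
        canon_ref = {tuple(h) for h in sym.canonical(ref)}
        assert canon_mine == canon_ref


class TestReferencePair:
    def test_fixed_seed_reproduces_reflections(self):
        _, a = simulate_reference_pair("hairpin-like", seed=7, d_min=3.0)
        _, b = simulate_reference_pair("hairpin-like", seed=7, d_min=3.0)
        assert np.array_equal(a.hkl, b.hkl)
        assert np.array_equal(a.F, b.F)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            simulate_reference_pair("nonsense", seed=0)
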
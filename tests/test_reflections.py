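"""Normalization, intensity-distribution and scattering-power tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixtps import (
    ReflectionSet,
    SpaceGroupOps,
    UnitCell,
    cdf_perfect_tps,
    cdf_wilson_acentric,
    cumulative_power,
    delete_top_n,
    detect_period,
    empirical_zcdf,
    l_profile,
    normalize,
    read_reflections,
    wilson_fit,
)
from helixtps.reflections import LProfile, merge_equivalents


def _toy_set(n=600, seed=0, cell=None):
    rng = np.random.default_rng(seed)
    cell = cell or UnitCell(20.0, 22.0, 24.0)
    sym = SpaceGroupOps("P1")
    hkl = rng.integers(-8, 9, (4 * n, 3))
    hkl = np.unique(hkl[np.any(hkl != 0, axis=1)], axis=0)[:n]
    F = rng.exponential(10.0, len(hkl))
    return ReflectionSet(cell, sym, hkl, F, 0.05 * F + 0.1)


class TestIO:
    def test_hkl_text_round_trip(self, tmp_path, hairpin_pair):
        _, rset = hairpin_pair
        path = tmp_path / "a.hkl"
        rset.write_hkl(path)
        back = read_reflections(path, "hkl-text", cell=rset.cell, spacegroup="P43")
        assert len(back) == len(rset)
        key = lambda s: np.lexsort(s.hkl.T)
        assert np.allclose(np.sort(back.F), np.sort(rset.F), atol=1e-5)

    def test_sf_mmcif_round_trip(self, tmp_path, hairpin_pair):
        _, rset = hairpin_pair
        path = tmp_path / "a-sf.cif"
        rset.write_sf_mmcif(path)
        back = read_reflections(path, "sf-mmcif")
        assert len(back) == len(rset)
        assert back.cell.a == pytest.approx(rset.cell.a, abs=1e-3)
        assert np.allclose(np.sort(back.F), np.sort(rset.F), atol=1e-5)

    def test_mtz_round_trip(self, tmp_path, hairpin_pair):
        _, rset = hairpin_pair
        path = tmp_path / "a.mtz"
        rset.write_mtz(path)
        back = read_reflections(path, "mtz")
        assert len(back) == len(rset)

    def test_duplicate_symmetry_mate_is_merged(self, tmp_path):
        cell = UnitCell(20, 20, 30)
        lines = ["1 2 3 10.0 0.5", "-1 -2 -3 10.0 0.5", "2 0 0 5.0 0.2"]
        path = tmp_path / "dup.hkl"
        path.write_text("\n".join(lines) + "\n")
        rset = read_reflections(path, "hkl-text", cell=cell, spacegroup="P1")
        assert len(rset) == 2  # Friedel mate merged

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "x.dat"
        path.write_text("1 1 1 1.0\n")
        with pytest.raises(ValueError, match="unknown format"):
            read_reflections(path, "xds")


class TestWilsonFit:
    def test_recovers_generator_b_factor(self, random_control):
        _, rset = random_control  # built with uniform B = 10
        fit = wilson_fit(rset, shells=20)
        assert 9.0 <= fit.B <= 11.0

    def test_point_atom_data_give_flat_wilson_plot(self, three_copy_set):
        _, rset = three_copy_set  # B = 0 throughout
        fit = wilson_fit(rset, shells=15)
        assert abs(fit.B) < 0.5

    def test_scale_equivariance(self, random_control):
        _, rset = random_control
        doubled = ReflectionSet(rset.cell, rset.symmetry, rset.hkl,
                                2.0 * rset.F, rset.sigma)
        f1 = wilson_fit(rset, shells=12)
        f2 = wilson_fit(doubled, shells=12)
        assert f2.scale == pytest.approx(4.0 * f1.scale, rel=1e-6)
        assert f2.B == pytest.approx(f1.B, abs=1e-6)


class TestNormalization:
    @pytest.mark.parametrize("fixture", ["dsrna_pair", "hairpin_pair",
                                         "random_control", "three_copy_set"])
    def test_per_shell_mean_z_is_one(self, fixture, request):
        _, rset = request.getfixturevalue(fixture)
        nset = normalize(rset, shells=20)
        for sh in np.unique(nset.shell_index):
            assert np.mean(nset.Z[nset.shell_index == sh]) == pytest.approx(1.0, abs=0.01)

    def test_toy_input_mean_z_is_one(self):
        nset = normalize(_toy_set(), shells=8)
        assert np.mean(nset.Z) == pytest.approx(1.0, abs=0.01)

    def test_record_view_is_consistent(self):
        nset = normalize(_toy_set(n=120), shells=2)
        rec = next(iter(nset))
        assert rec.Z == pytest.approx(rec.E**2)

    def test_empty_set_rejected(self):
        rset = _toy_set().select(np.zeros(600, dtype=bool))
        with pytest.raises(ValueError):
            normalize(rset)


class TestTheoreticalLaws:
    def test_wilson_cdf_limits_and_monte_carlo(self):
        assert cdf_wilson_acentric(0.0) == 0.0
        assert cdf_wilson_acentric(50.0) == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(0)
        draws = rng.exponential(1.0, 100_000)
        for z in (0.2, 1.0, 3.0):
            assert cdf_wilson_acentric(z) == pytest.approx(
                np.mean(draws <= z), abs=0.01)

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            cdf_wilson_acentric(-0.1)
        with pytest.raises(ValueError):
            cdf_perfect_tps(-0.1, 3)

    def test_tps_law_reduces_to_wilson_at_m1(self):
        z = np.linspace(0, 8, 100)
        assert np.allclose(cdf_perfect_tps(z, 1), cdf_wilson_acentric(z), atol=1e-12)

    def test_tps_law_m3_extinct_fraction(self):
        assert cdf_perfect_tps(0.0, 3) == pytest.approx(2.0 / 3.0)

    @given(m=st.integers(min_value=1, max_value=8))
    @settings(deadline=None, max_examples=8, derandomize=True)
    def test_tps_law_mean_z_is_one(self, m):
        # E[Z] = (1/m) * m = 1 by numerical integration of the mixture tail
        z = np.linspace(0, 400, 400_001)
        mean = np.trapezoid(1.0 - cdf_perfect_tps(z, m), z)
        assert mean == pytest.approx(1.0, rel=1e-3)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            cdf_perfect_tps(1.0, 0)


class TestEmpiricalZcdf:
    def test_exponential_sample_prefers_wilson_law(self, random_control):
        _, rset = random_control
        res = empirical_zcdf(normalize(rset), acentric_only=True, tps_m=3)
        assert res.d_wilson < res.d_tps

    def test_perfect_three_copy_matches_mixture_law(self, three_copy_set):
        _, rset = three_copy_set
        res = empirical_zcdf(normalize(rset), tps_m=3)
        assert res.d_tps < 0.02
        assert res.d_wilson > 0.5

    def test_single_reflection_degenerates_without_error(self):
        rset = _toy_set(n=60, seed=3)
        nset = normalize(rset, shells=1)
        one = nset.base.select(np.arange(60) == 0)
        from helixtps.reflections import NormalizedSet
        res = empirical_zcdf(NormalizedSet(one, nset.E[:1], nset.epsilon[:1],
                                           nset.centric[:1], nset.shell_index[:1]))
        assert len(res.z_sorted) == 1


class TestLProfile:
    def test_constant_ratio_gives_flat_profile(self):
        rset = _toy_set(n=400, seed=2)
        rset = ReflectionSet(rset.cell, rset.symmetry, rset.hkl,
                             np.full(len(rset), 7.0), np.full(len(rset), 1.0))
        prof = l_profile(rset)
        pop = np.isfinite(prof.mean_F_over_sigma)
        assert np.allclose(prof.mean_F_over_sigma[pop], 7.0, atol=1e-12)
        assert prof.counts.sum() == len(rset)

    def test_flat_profile_detects_no_period(self):
        prof = LProfile(np.arange(30), np.full(30, 3.0), np.full(30, 5))
        period, score = detect_period(prof)
        assert period is None

    def test_period_nine_from_two_scatterer_closed_form(self):
        l = np.arange(0, 60)
        prof = LProfile(l, np.sqrt(2 * (1 + np.cos(2 * np.pi * l / 9))),
                        np.full(60, 10))
        period, score = detect_period(prof)
        assert period == 9
        assert score > 3

    def test_dsrna_profile_has_period_nine(self, dsrna_pair):
        _, rset = dsrna_pair
        period, score = detect_period(l_profile(rset))
        assert period == 9

    def test_hairpin_profile_has_no_alternation(self, hairpin_pair):
        _, rset = hairpin_pair
        period, _ = detect_period(l_profile(rset))
        assert period is None

    def test_detect_period_is_scale_invariant(self, dsrna_pair):
        _, rset = dsrna_pair
        prof = l_profile(rset)
        scaled = LProfile(prof.l_values, 137.0 * prof.mean_F_over_sigma,
                          prof.counts)
        p1, s1 = detect_period(prof)
        p2, s2 = detect_period(scaled)
        assert p1 == p2
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_too_few_classes_rejected(self):
        prof = LProfile(np.arange(2), np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            detect_period(prof)


class TestPowerCurve:
    def test_equal_amplitudes_give_linear_curve(self):
        rset = _toy_set(n=200, seed=5)
        rset = ReflectionSet(rset.cell, rset.symmetry, rset.hkl,
                             np.full(len(rset), 3.0), np.full(len(rset), 0.1))
        curve = cumulative_power(rset)
        assert np.allclose(curve.sorted_fractions,
                           np.arange(1, curve.n + 1) / curve.n, atol=1e-12)

    def test_dominant_amplitude_takes_most_power(self):
        cell = UnitCell(20, 20, 20)
        hkl = np.column_stack([np.arange(1, 102), np.zeros(101, int),
                               np.zeros(101, int)])
        F = np.ones(101)
        F[57] = 100.0
        rset = ReflectionSet(cell, SpaceGroupOps("P1"), hkl, F, 0.1 * F)
        curve = cumulative_power(rset)
        assert curve.sorted_fractions[0] > 0.99

    def test_curve_is_monotone_and_ends_at_one(self, dsrna_pair):
        _, rset = dsrna_pair
        curve = cumulative_power(rset)
        assert np.all(np.diff(curve.sorted_fractions) >= 0)
        assert curve.sorted_fractions[-1] == pytest.approx(1.0, abs=1e-12)

    def test_tps_set_outpowers_control_at_matched_rank(self, dsrna_pair,
                                                       hairpin_pair):
        _, ds = dsrna_pair
        _, hp = hairpin_pair
        c_ds = cumulative_power(ds)
        c_hp = cumulative_power(hp)
        for k in (10, 50, 100, 200):
            assert c_ds.fraction_of_top(k) > c_hp.fraction_of_top(k)


class TestDeletion:
    def test_zero_deletion_is_identity(self):
        rset = _toy_set()
        kept, manifest = delete_top_n(rset, 0)
        assert len(kept) == len(rset)
        assert manifest.empty

    def test_deleting_81_from_large_set_leaves_expected_count(self):
        rset = _toy_set(n=600)
        kept, manifest = delete_top_n(rset, 81)
        assert len(kept) == len(rset) - 81
        assert len(manifest) == 81

    def test_removed_amplitudes_dominate_remaining(self):
        rset = _toy_set(seed=8)
        kept, manifest = delete_top_n(rset, 25)
        assert kept.F.max() <= manifest["F"].min()

    def test_removed_power_bookkeeping_is_exact(self):
        rset = _toy_set(seed=9)
        total = np.sum(rset.F**2)
        kept, manifest = delete_top_n(rset, 40)
        removed_fraction = 1.0 - np.sum(kept.F**2) / total
        assert removed_fraction == pytest.approx(
            np.sum(manifest["F"] ** 2) / total, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delete_top_n(_toy_set(), 601)


class TestMerge:
    def test_merge_is_idempotent(self, hairpin_pair):
        _, rset = hairpin_pair
        merged, absorbed = merge_equivalents(rset)
        assert absorbed == 0
        assert len(merged) == len(rset)
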
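"""Condensed local descriptors: populations, Fukui functions, local
softness, the four local-hardness forms, and residue condensation."""

import numpy as np
import pytest

from cdftfold.cdft_global import GlobalDescriptors, global_descriptors
from cdftfold.cdft_local import (condense_to_residues, fukui_composites,
                                 fukui_ew, fukui_finite_difference,
                                 fukui_foa, fukui_potential,
                                 local_hardness_fw, local_hardness_lcp,
                                 local_hardness_tfd, local_softness,
                                 mulliken_populations, orbital_density)
from cdftfold.constants import ANGSTROM_TO_BOHR
from cdftfold.qm_io import ElectronicStructure
from cdftfold.structures import MolecularStructure
from cdftfold.synthetic import (SyntheticSpec, make_tight_binding_chain,
                                make_toy_electronic_structure)

from conftest import es_from_energies, point_structure, random_rotation

BOHR_IN_ANG = 1.0 / ANGSTROM_TO_BOHR


def mulliken_oracle(C, occ, S, ao_map, n_atoms):
    """Element-by-element triple-loop Mulliken condensation."""
    n_ao, n_mo = C.shape
    rho = np.zeros(n_atoms)
    for mu in range(n_ao):
        for nu in range(n_ao):
            p = sum(occ[i] * C[mu, i] * C[nu, i] for i in range(n_mo))
            rho[ao_map[mu]] += p * S[nu, mu]
    return rho


class TestMulliken:
    def test_h2_symmetric_split(self):
        c = np.array([[1 / np.sqrt(2)], [1 / np.sqrt(2)]])
        es = es_from_energies([-10.0], [2.0], coefficients=c,
                              ao_atom_map=[0, 1])
        np.testing.assert_allclose(
            mulliken_populations(es).values, [1.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_conservation(self, seed):
        mode = "random_spd" if seed % 2 else "identity"
        _, es = make_toy_electronic_structure(
            SyntheticSpec(seed=seed, overlap_mode=mode))
        rho = mulliken_populations(es)
        assert rho.values.sum() == pytest.approx(es.n_electrons, abs=1e-8)

    def test_matches_triple_loop_oracle(self):
        _, es = make_toy_electronic_structure(
            SyntheticSpec(seed=9, n_atoms=3, aos_per_atom=2,
                          overlap_mode="random_spd"))
        expected = mulliken_oracle(es.coefficients, es.occupations,
                                   es.overlap, es.ao_atom_map, 3)
        np.testing.assert_allclose(mulliken_populations(es).values,
                                   expected, atol=1e-10)

    def test_lowdin_also_conserves(self):
        _, es = make_toy_electronic_structure(
            SyntheticSpec(seed=4, overlap_mode="random_spd"))
        rho = mulliken_populations(es, scheme="lowdin")
        assert rho.values.sum() == pytest.approx(es.n_electrons, abs=1e-8)


class TestOrbitalDensity:
    def test_localized_mo(self):
        C = np.eye(4)
        es = es_from_energies([-12, -10, -8, -2], [2, 2, 2, 0],
                              coefficients=C)
        np.testing.assert_allclose(orbital_density(es, 2).values,
                                   [0, 0, 1, 0], atol=1e-12)

    def test_uniform_coefficients(self):
        k = 5
        C = np.full((k, 1), 1 / np.sqrt(k))
        C = np.hstack([C, np.eye(k)[:, :1]])  # second MO irrelevant filler
        es = es_from_energies([-10.0, -2.0], [2.0, 0.0], coefficients=C)
        np.testing.assert_allclose(orbital_density(es, 0).values,
                                   np.full(k, 1 / k), atol=1e-12)

    def test_butadiene_like_chain_homo(self):
        _, es = make_tight_binding_chain(4, alpha=0.0, beta=-1.0)
        np.testing.assert_allclose(
            orbital_density(es, es.homo_index).values,
            [0.3618034, 0.1381966, 0.1381966, 0.3618034], atol=1e-6)

    def test_bad_index(self):
        _, es = make_tight_binding_chain(4)
        with pytest.raises(ValueError, match="out of range"):
            orbital_density(es, 99)


class TestFukui:
    def test_foa_indicator_vectors(self):
        C = np.eye(3)
        es = es_from_energies([-10, -8, -2], [2, 2, 0], coefficients=C)
        f_minus, f_plus = fukui_foa(es)
        np.testing.assert_allclose(f_minus.values, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f_plus.values, [0, 0, 1], atol=1e-12)
        assert f_minus.values.sum() == pytest.approx(1.0)
        assert f_plus.values.sum() == pytest.approx(1.0)

    def test_ew_window_zero_reduces_to_foa(self):
        _, es = make_toy_electronic_structure(SyntheticSpec(seed=11))
        f_minus0, f_plus0 = fukui_ew(es, window=0.0)
        f_minus, f_plus = fukui_foa(es)
        np.testing.assert_allclose(f_minus0.values, f_minus.values,
                                   atol=1e-12)
        np.testing.assert_allclose(f_plus0.values, f_plus.values,
                                   atol=1e-12)

    def test_ew_two_levels_one_ev_apart(self):
        # occupied MOs at E_HOMO and E_HOMO − 1 eV localized on separate
        # atoms: weights 1 and e⁻¹, renormalized
        C = np.eye(3)
        es = es_from_energies([-6.0, -5.0, 0.0], [2, 2, 0], coefficients=C)
        f_minus, _ = fukui_ew(es, window=1.0)
        w = np.exp(-1.0)
        np.testing.assert_allclose(
            f_minus.values, [w / (1 + w), 1 / (1 + w), 0.0], atol=1e-12)
        assert f_minus.values[1] == pytest.approx(0.7310585786, abs=1e-9)

    def test_ew_degenerate_homo_pair_is_half_half(self):
        _, es = make_toy_electronic_structure(
            SyntheticSpec(seed=3, degenerate_homo_atoms=(0, 1)))
        f_minus, _ = fukui_ew(es, window=1.0)
        assert f_minus.values[0] == pytest.approx(0.5, abs=1e-12)
        assert f_minus.values[1] == pytest.approx(0.5, abs=1e-12)

    def test_finite_difference_identity_and_localization(self):
        from cdftfold.cdft_local import CondensedField
        rho_n = CondensedField("rho", [2.0, 2.0, 2.0])
        f_minus, _ = fukui_finite_difference(
            rho_n, CondensedField("rho", [2.0, 2.0, 2.0]),
            CondensedField("rho", [3.0, 2.0, 2.0]))
        np.testing.assert_allclose(f_minus.values, 0.0, atol=1e-15)
        f_minus2, _ = fukui_finite_difference(
            rho_n, CondensedField("rho", [2.0, 1.0, 2.0]),
            CondensedField("rho", [2.0, 2.0, 3.0]))
        np.testing.assert_allclose(f_minus2.values, [0, 1, 0], atol=1e-15)

    def test_finite_difference_frozen_orbital_consistency(self):
        """ρ_{N±1} built by removing/adding the frontier orbital density
        reproduces the frozen-orbital Fukui functions."""
        _, es = make_toy_electronic_structure(SyntheticSpec(seed=21))
        from cdftfold.cdft_local import CondensedField
        rho_n = mulliken_populations(es)
        f_minus_foa, f_plus_foa = fukui_foa(es)
        rho_m = CondensedField("rho", rho_n.values - f_minus_foa.values)
        rho_p = CondensedField("rho", rho_n.values + f_plus_foa.values)
        f_minus, f_plus = fukui_finite_difference(rho_n, rho_m, rho_p)
        np.testing.assert_allclose(f_minus.values, f_minus_foa.values,
                                   atol=1e-10)
        np.testing.assert_allclose(f_plus.values, f_plus_foa.values,
                                   atol=1e-10)

    def test_composites(self):
        from cdftfold.cdft_local import CondensedField
        f_minus = CondensedField("f_minus", [1.0, 0.0])
        f_plus = CondensedField("f_plus", [0.0, 1.0])
        f_zero, f_dual = fukui_composites(f_minus, f_plus)
        np.testing.assert_allclose(f_zero.values, [0.5, 0.5])
        np.testing.assert_allclose(f_dual.values, [-1.0, 1.0])
        assert f_zero.values.sum() == pytest.approx(1.0)
        assert f_dual.values.sum() == pytest.approx(0.0)


class TestLocalSoftness:
    def test_scaling(self):
        from cdftfold.cdft_local import CondensedField
        f = CondensedField("f_minus", [0.5, 0.5])
        s = local_softness(f, 0.125)
        np.testing.assert_allclose(s.values, [0.0625, 0.0625])
        assert s.name == "softness_minus"

    def test_sum_equals_global_softness(self):
        _, es = make_toy_electronic_structure(SyntheticSpec(seed=13))
        g = global_descriptors(es)
        f_minus, _ = fukui_ew(es)
        s = local_softness(f_minus, g.softness)
        assert s.values.sum() == pytest.approx(g.softness, abs=1e-10)


def pairwise_oracle(coords_ang, weights, prefactor):
    """Brute-force double loop over atom pairs, distances in bohr."""
    xyz = np.asarray(coords_ang) * ANGSTROM_TO_BOHR
    n = len(xyz)
    out = np.zeros(n)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            out[a] += weights[b] / np.linalg.norm(xyz[a] - xyz[b])
    return prefactor * out


class TestHardnessTfd:
    def test_two_atoms_one_bohr(self):
        from cdftfold.cdft_local import CondensedField
        s = point_structure([[0, 0, 0], [BOHR_IN_ANG, 0, 0]])
        eta = local_hardness_tfd(s, CondensedField("rho", [1.0, 1.0]), 2)
        np.testing.assert_allclose(eta.values, [0.25, 0.25], atol=1e-12)

    def test_inverse_distance_scaling(self, rng):
        from cdftfold.cdft_local import CondensedField
        pts = rng.standard_normal((5, 3)) * 3
        rho = CondensedField("rho", rng.uniform(0.5, 2.0, 5))
        e1 = local_hardness_tfd(point_structure(pts), rho, 4)
        e2 = local_hardness_tfd(point_structure(pts * 2), rho, 4)
        np.testing.assert_allclose(e2.values, e1.values / 2, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        from cdftfold.cdft_local import CondensedField
        pts = rng.standard_normal((8, 3)) * 4
        rho_vals = rng.uniform(0.2, 2.0, 8)
        n_elec = 8
        eta = local_hardness_tfd(point_structure(pts),
                                 CondensedField("rho", rho_vals), n_elec)
        np.testing.assert_allclose(
            eta.values,
            pairwise_oracle(pts, rho_vals, 1.0 / (2 * n_elec)), atol=1e-12)

    def test_overlapping_centers_rejected(self):
        from cdftfold.cdft_local import CondensedField
        s = point_structure([[0, 0, 0], [0.01, 0, 0]])
        with pytest.raises(ValueError, match="overlapping"):
            local_hardness_tfd(s, CondensedField("rho", [1.0, 1.0]), 2)

    def test_rotation_invariance(self, rng):
        from cdftfold.cdft_local import CondensedField
        pts = rng.standard_normal((6, 3)) * 3
        rho = CondensedField("rho", rng.uniform(0.5, 2.0, 6))
        e1 = local_hardness_tfd(point_structure(pts), rho, 6)
        R = random_rotation(rng)
        e2 = local_hardness_tfd(point_structure(pts @ R.T + 5.0), rho, 6)
        np.testing.assert_allclose(e2.values, e1.values, atol=1e-10)


class TestFukuiPotential:
    def test_two_atoms_self_excluded(self):
        from cdftfold.cdft_local import CondensedField
        s = point_structure([[0, 0, 0], [BOHR_IN_ANG, 0, 0]])
        eta = fukui_potential(s, CondensedField("f_minus", [1.0, 0.0]))
        np.testing.assert_allclose(eta.values, [0.0, 1.0], atol=1e-12)

    def test_polygon_symmetry(self):
        from cdftfold.cdft_local import CondensedField
        k = 6
        theta = 2 * np.pi * np.arange(k) / k
        pts = np.stack([np.cos(theta), np.sin(theta),
                        np.zeros(k)], axis=1) * 2.0
        eta = fukui_potential(point_structure(pts),
                              CondensedField("f_minus", np.full(k, 1 / k)))
        np.testing.assert_allclose(eta.values, eta.values[0], atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        from cdftfold.cdft_local import CondensedField
        pts = rng.standard_normal((7, 3)) * 4
        f = rng.dirichlet(np.ones(7))
        eta = fukui_potential(point_structure(pts),
                              CondensedField("f_minus", f))
        np.testing.assert_allclose(eta.values, pairwise_oracle(pts, f, 1.0),
                                   atol=1e-12)


class TestHardnessLcp:
    def _worked_es(self):
        # 2 atoms, 3 AOs: occupied MOs at −6 (atom 1) and −5 (atom 0,
        # HOMO), one virtual; fractional occupations give ρ = (1, 1)
        C = np.eye(3)
        return es_from_energies([-6.0, -5.0, 3.0], [1.0, 1.0, 0.0],
                                coefficients=C, ao_atom_map=[1, 0, 1])

    def test_worked_example(self):
        from cdftfold.cdft_local import CondensedField
        es = self._worked_es()
        rho = CondensedField("rho", [1.0, 1.0])
        g = GlobalDescriptors(ip=9.0, ea=1.0, mu=-5.0, eta=8.0,
                              softness=0.125, omega=1.5625, n_max=0.625)
        eta = local_hardness_lcp(es, rho, g)
        np.testing.assert_allclose(eta.values, [3.375, 4.625], atol=1e-12)
        assert eta.values.sum() == pytest.approx(g.eta, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_sum_equals_global_hardness(self, seed):
        _, es = make_toy_electronic_structure(SyntheticSpec(seed=seed))
        g = global_descriptors(es)
        rho = mulliken_populations(es)
        eta = local_hardness_lcp(es, rho, g)
        assert eta.values.sum() == pytest.approx(g.eta, abs=1e-10)

    def test_uniform_distributions_give_equal_split(self):
        from cdftfold.cdft_local import CondensedField
        # HOMO spread uniformly over 2 atoms, uniform density
        C = np.array([[1 / np.sqrt(2), 0.0],
                      [1 / np.sqrt(2), 0.0],
                      [0.0, 1.0]])
        es = es_from_energies([-5.0, 3.0], [2.0, 0.0], coefficients=C,
                              ao_atom_map=[0, 1, 1])
        rho = CondensedField("rho", [1.0, 1.0])
        g = global_descriptors(es)
        eta = local_hardness_lcp(es, rho, g)
        np.testing.assert_allclose(eta.values, g.eta / 2, atol=1e-12)


class TestHardnessFw:
    def test_worked_example(self):
        from cdftfold.cdft_local import CondensedField
        eta = local_hardness_fw(CondensedField("f_minus", [0.5, 0.5]),
                                CondensedField("f_plus", [1.0, 0.0]),
                                ip=9.0, ea=1.0)
        np.testing.assert_allclose(eta.values, [3.5, 4.5])
        assert eta.values.sum() == pytest.approx(8.0)

    def test_zero_ea_degenerate_case(self):
        from cdftfold.cdft_local import CondensedField
        f_minus = CondensedField("f_minus", [0.3, 0.7])
        eta = local_hardness_fw(f_minus,
                                CondensedField("f_plus", [0.5, 0.5]),
                                ip=10.0, ea=0.0)
        np.testing.assert_allclose(eta.values, 10.0 * f_minus.values)

    def test_equal_fukui_factorizes(self):
        from cdftfold.cdft_local import CondensedField
        f = [0.2, 0.8]
        eta = local_hardness_fw(CondensedField("f_minus", f),
                                CondensedField("f_plus", f),
                                ip=9.0, ea=1.0)
        np.testing.assert_allclose(eta.values, 8.0 * np.array(f))


class TestCondensation:
    def test_single_residue_is_total(self, rng):
        from cdftfold.cdft_local import CondensedField
        n = 5
        s = point_structure(rng.standard_normal((n, 3)) * 3)
        s.residue_index = np.zeros(n, dtype=int)
        s.residue_names = ["GLY"]
        s.residue_seq = ["1"]
        s.residue_chain = ["A"]
        f = CondensedField("f_minus", rng.dirichlet(np.ones(n)))
        rf = condense_to_residues(f, s)
        assert len(rf.values) == 1
        assert rf.values[0] == pytest.approx(f.values.sum())

    def test_normalization_survives(self):
        _, es = make_toy_electronic_structure(SyntheticSpec(seed=17))
        mol, _ = make_toy_electronic_structure(SyntheticSpec(seed=17))
        f_minus, _ = fukui_ew(es)
        rf = condense_to_residues(f_minus, mol)
        assert rf.values.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_group_by_oracle(self, rng):
        from cdftfold.cdft_local import CondensedField
        n = 12
        s = point_structure(rng.standard_normal((n, 3)) * 5)
        part = rng.integers(0, 4, n)
        # renumber so residues appear contiguously labeled
        s.residue_index = part
        s.residue_names = ["ALA", "GLY", "SER", "VAL"]
        s.residue_seq = ["1", "2", "3", "4"]
        s.residue_chain = ["A"] * 4
        vals = rng.standard_normal(n)
        rf = condense_to_residues(CondensedField("x", vals), s)
        expected = np.zeros(4)
        for i, p in enumerate(part):
            expected[p] += vals[i]
        np.testing.assert_allclose(rf.values, expected, atol=1e-12)
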
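"""Unit cell, atomic model, structure factors and displacement profiles."""

import cmath
import math

import numpy as np
import pytest

import bootsfx as bx
from bootsfx.crystal import Atom, AtomicModel, UnitCell
from bootsfx.sfcalc import structure_factors_at


def textbook_orth(a, b, c, alpha, beta, gamma):
    """Independent PDB-convention orthogonalization matrix."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


class TestUnitCell:
    def test_orthogonalization_matches_textbook_matrix(self):
        cell = UnitCell(18.0, 21.0, 25.0, 83.0, 97.0, 102.0)
        np.testing.assert_allclose(
            cell.orth_matrix, textbook_orth(18, 21, 25, 83, 97, 102), atol=1e-9
        )
        v = np.linalg.det(textbook_orth(18, 21, 25, 83, 97, 102))
        assert cell.volume == pytest.approx(v, rel=1e-10)

    def test_d_spacing_matches_reciprocal_metric(self):
        cell = UnitCell(18.0, 21.0, 25.0, 83.0, 97.0, 102.0)
        m = textbook_orth(18, 21, 25, 83, 97, 102)
        f = np.linalg.inv(m)
        hkl = np.array([[1, 0, 0], [0, 2, 0], [1, -2, 3], [4, 1, -1]])
        inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), f @ f.T, hkl.astype(float))
        np.testing.assert_allclose(cell.d_spacings(hkl), 1 / np.sqrt(inv_d2), rtol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a=-1, b=2, c=3),
            dict(a=1, b=2, c=3, alpha=0.0),
            dict(a=1, b=2, c=3, gamma=180.0),
        ],
    )
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(ValueError):
            UnitCell(**{"alpha": 90, "beta": 90, "gamma": 90, **kwargs})


class TestModelInvariants:
    def test_conformer_occupancies_must_be_complementary(self):
        cell = UnitCell(10, 10, 10)
        atoms = [
            Atom("CA1", "C", 6, [0.1, 0.1, 0.1], occ=0.7, conformer="A"),
            Atom("CA1", "C", 6, [0.2, 0.1, 0.1], occ=0.6, conformer="B"),
        ]
        with pytest.raises(ValueError, match="occupancy"):
            AtomicModel(cell=cell, atoms=atoms)

    def test_atom_validation(self):
        with pytest.raises(ValueError):
            Atom("X", "C", 6, [0, 0, 0], occ=1.5)
        with pytest.raises(ValueError):
            Atom("X", "C", 6, [0, 0, 0], b_iso=-1)
        with pytest.raises(ValueError):
            Atom("X", "C", 0, [0, 0, 0])


class TestStructureFactors:
    def test_origin_atom_gives_flat_amplitude_and_zero_phase(self):
        cell = UnitCell(10, 10, 10)
        model = AtomicModel(cell, [Atom("O1", "O", 8, [0, 0, 0], b_iso=0.0)])
        refls = bx.structure_factors(model, 3.0)
        np.testing.assert_allclose(refls.amplitude, 8.0, rtol=1e-12)
        np.testing.assert_allclose(refls.phase, 0.0, atol=1e-12)

    def test_half_cell_translation_flips_phase(self):
        cell = UnitCell(10, 10, 10)
        model = AtomicModel(cell, [Atom("O1", "O", 8, [0.5, 0, 0], b_iso=0.0)])
        refls = bx.structure_factors(model, 3.0)
        i100 = np.flatnonzero(np.all(refls.hkl == [1, 0, 0], axis=1))[0]
        assert refls.amplitude[i100] == pytest.approx(8.0)
        assert abs(refls.phase_degrees[i100]) == pytest.approx(180.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        cell = UnitCell(12.0, 13.0, 14.0, 90.0, 100.0, 90.0)
        atoms = [
            Atom(f"X{i}", "C", float(rng.integers(6, 17)), rng.random(3),
                 b_iso=float(rng.uniform(5, 30)), occ=float(rng.uniform(0.3, 1.0)))
            for i in range(5)
        ]
        model = AtomicModel(cell, atoms)
        refls = bx.structure_factors(model, 2.0)
        f_inv = np.linalg.inv(textbook_orth(12, 13, 14, 90, 100, 90))
        gstar = f_inv @ f_inv.T
        for i in rng.choice(len(refls), size=60, replace=False):
            h, k, l = (int(x) for x in refls.hkl[i])
            s2 = float(np.array([h, k, l]) @ gstar @ np.array([h, k, l]))
            f = 0j
            for atom in atoms:
                f += (
                    atom.occ
                    * atom.z_electrons
                    * math.exp(-atom.b_iso * s2 / 4.0)
                    * cmath.exp(2j * math.pi * (h * atom.frac[0] + k * atom.frac[1] + l * atom.frac[2]))
                )
            got = refls.amplitude[i] * cmath.exp(1j * refls.phase[i])
            assert got == pytest.approx(f, rel=1e-10)

    def test_friedel_half_sphere_and_cutoff(self, toy_sf):
        F_dark, _, _ = toy_sf
        hkl = F_dark.hkl
        assert np.all(
            (hkl[:, 0] > 0)
            | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
            | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
        )
        assert np.all(F_dark.d_spacings() >= 2.5 - 1e-9)

    def test_empty_model_and_hopeless_cutoff_raise(self):
        cell = UnitCell(10, 10, 10)
        with pytest.raises(ValueError, match="empty"):
            bx.structure_factors(AtomicModel(cell, []), 2.0)
        model = AtomicModel(cell, [Atom("O1", "O", 8, [0, 0, 0])])
        with pytest.raises(ValueError, match="zero reflections"):
            bx.structure_factors(model, 50.0)

    def test_occupancy_linearity(self):
        cell = UnitCell(11, 12, 13)
        a_full = AtomicModel(cell, [Atom("O1", "O", 8, [0.3, 0.4, 0.1], b_iso=12.0, occ=1.0)])
        a_part = AtomicModel(cell, [Atom("O1", "O", 8, [0.3, 0.4, 0.1], b_iso=12.0, occ=0.37)])
        f_full = bx.structure_factors(a_full, 3.0)
        f_part = bx.structure_factors(a_part, 3.0)
        np.testing.assert_allclose(f_part.amplitude, 0.37 * f_full.amplitude, rtol=1e-12)


class TestMixStates:
    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_endpoint_identities(self, toy_sf, f):
        F_dark, F_light, _ = toy_sf
        mixed = bx.mix_states(F_dark, F_light, f)
        target = F_dark if f == 0.0 else F_light
        np.testing.assert_allclose(mixed.amplitude, target.amplitude, rtol=1e-12)

    def test_complex_arithmetic_oracle(self, toy_sf):
        F_dark, F_light, F_mix = toy_sf
        expected = np.abs(
            0.73 * F_dark.complex_values + 0.27 * F_light.complex_values
        )
        np.testing.assert_allclose(F_mix.amplitude, expected, rtol=1e-12)

    def test_equals_merged_two_conformer_model(self, toy_models):
        dark, light = toy_models
        f = 0.41
        merged = bx.two_state_model(dark, light, f)
        F_merged = bx.structure_factors(merged, 2.5)
        F_mixed = bx.mix_states(
            bx.structure_factors(dark, 2.5), bx.structure_factors(light, 2.5), f
        )
        np.testing.assert_allclose(
            F_merged.complex_values, F_mixed.complex_values, atol=1e-8
        )

    def test_mismatched_hkl_sets_name_first_mismatch(self, toy_sf):
        F_dark, F_light, _ = toy_sf
        trimmed = F_light.take(np.arange(len(F_light) - 1))
        with pytest.raises(ValueError, match="mismatch"):
            bx.mix_states(F_dark, trimmed, 0.5)


class TestRmsdProfile:
    def test_identical_models_zero(self, toy_models):
        dark, _ = toy_models
        prof = bx.rmsd_profile(dark, dark)
        np.testing.assert_allclose(prof.displacements, 0.0, atol=1e-14)

    def test_metric_forces_half_angstrom(self):
        cell = UnitCell(50, 50, 50)
        m1 = AtomicModel(cell, [Atom("CA1", "C", 6, [0.2, 0.2, 0.2]),
                                Atom("CA2", "C", 6, [0.6, 0.6, 0.6])])
        m2 = m1.copy()
        m2.atoms[0].frac = m2.atoms[0].frac + np.array([0.01, 0, 0])
        prof = bx.rmsd_profile(m1, m2)
        np.testing.assert_allclose(prof.displacements, [0.5, 0.0], atol=1e-12)

    def test_matches_orthogonalization_oracle(self):
        rng = np.random.default_rng(11)
        cell = UnitCell(15, 17, 19, 90, 105, 90)
        m = textbook_orth(15, 17, 19, 90, 105, 90)
        base = AtomicModel(
            cell, [Atom(f"CA{i}", "C", 6, rng.random(3)) for i in range(10)]
        )
        moved = base.copy()
        deltas = rng.normal(0, 0.01, size=(10, 3))
        for atom, d in zip(moved.atoms, deltas):
            atom.frac = atom.frac + d
        prof = bx.rmsd_profile(base, moved)
        expected = np.linalg.norm(deltas @ m.T, axis=1)
        np.testing.assert_allclose(prof.displacements, expected, rtol=1e-10)

    def test_symmetric_and_selection_errors(self, toy_models):
        dark, light = toy_models
        a = bx.rmsd_profile(dark, light).displacements
        b = bx.rmsd_profile(light, dark).displacements
        np.testing.assert_allclose(a, b, rtol=1e-12)
        with pytest.raises(ValueError, match="selection"):
            bx.rmsd_profile(dark, light, selection="NOPE")


class TestPdbRoundTrip:
    def test_round_trip_preserves_model(self, toy_models, tmp_path):
        dark, light = toy_models
        model = bx.two_state_model(dark, light, 0.27)
        path = tmp_path / "model.pdb"
        bx.write_pdb(model, path)
        back = bx.read_pdb(path)
        assert len(back) == len(model)
        # PDB groups by residue: compare per (name, conformer) key
        orig = {(a.name, a.conformer): a for a in model.atoms}
        for atom in back.atoms:
            ref = orig[(atom.name, atom.conformer)]
            cart_ref = model.cell.orthogonalize(ref.frac)
            cart_back = back.cell.orthogonalize(atom.frac)
            np.testing.assert_allclose(cart_back, cart_ref, atol=2e-3)
            assert atom.occ == pytest.approx(ref.occ, abs=0.01)
            assert atom.b_iso == pytest.approx(ref.b_iso, abs=0.01)
            assert atom.z_electrons == ref.z_electrons

    def test_cell_round_trips(self, toy_models, tmp_path):
        dark, _ = toy_models
        bx.write_pdb(dark, tmp_path / "d.pdb")
        back = bx.read_pdb(tmp_path / "d.pdb")
        assert back.cell.a == pytest.approx(dark.cell.a, abs=1e-3)
        assert back.cell.volume == pytest.approx(dark.cell.volume, rel=1e-4)
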
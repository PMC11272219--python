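"""Refinement engine, occupancy scans, coordinate-error estimation."""

import numpy as np
import pytest

import bootsfx as bx
from bootsfx.appraisal import free_set_mask
from bootsfx.framesim import simulate_frames, two_state_frameset
from conftest import D_MIN, F_TRUE


class TestSigmaFree:
    def test_pinned_hand_evaluation(self):
        # sqrt(0.65 * (1800/180000) * 0.187^2 * 2.0^2 * 0.99^-1.5)
        got = bx.sigma_free(1800, 180000, 0.187, 2.0, 0.99)
        assert got == pytest.approx(0.030380987399365216, abs=1e-12)

    def test_full_completeness_is_exponent_independent(self):
        a = bx.sigma_free(100, 1000, 0.2, 2.0, 1.0, completeness_exponent=-1.5)
        b = bx.sigma_free(100, 1000, 0.2, 2.0, 1.0, completeness_exponent=+1.5)
        assert a == b

    def test_homogeneous_in_r_free(self):
        a = bx.sigma_free(100, 1000, 0.1, 2.0, 0.9)
        b = bx.sigma_free(100, 1000, 0.2, 2.0, 0.9)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            bx.sigma_free(100, 0, 0.2, 2.0, 0.9)
        with pytest.raises(ValueError):
            bx.sigma_free(100, 1000, 0.2, 2.0, 1.5)


class TestBToU:
    def test_unit_cases(self):
        assert bx.b_to_u(0.0) == 0.0
        assert bx.b_to_u(8 * np.pi**2) == pytest.approx(1.0, rel=1e-12)

    def test_mean_b_of_41_gives_0p7(self):
        assert round(bx.b_to_u(41.0), 1) == 0.7

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bx.b_to_u(-1.0)


class TestFreeSet:
    def test_deterministic_and_order_independent(self):
        hkl = np.array([(h, k, l) for h in range(1, 6) for k in range(-4, 5)
                        for l in range(-4, 5)])
        m1 = free_set_mask(hkl, 0.05, seed=3)
        m2 = free_set_mask(hkl, 0.05, seed=3)
        np.testing.assert_array_equal(m1, m2)
        perm = np.random.default_rng(0).permutation(len(hkl))
        m3 = free_set_mask(hkl[perm], 0.05, seed=3)
        np.testing.assert_array_equal(m3, m1[perm])
        assert 0.0 < m1.mean() < 0.15


class TestRefine:
    def test_truth_is_a_fixed_point(self, toy_models, toy_obs):
        """Initialized at the generating truth with exact data, refinement
        does not move the model."""
        dark, light = toy_models
        obs, _ = toy_obs
        model = bx.two_state_model(dark, light, F_TRUE)
        res = bx.refine(obs, model,
                        bx.RefinementOptions(mode="partial_occupancy", f=F_TRUE))
        prof = bx.rmsd_profile(light, res.model.select(conformer="B"))
        assert prof.displacements.max() < 1e-6
        assert res.r_factor < 1e-6
        assert res.r_free < 1e-6

    def test_target_trace_is_nonincreasing(self, toy_models, toy_obs):
        dark, _ = toy_models
        obs, _ = toy_obs
        model = bx.two_state_model(dark, dark.copy(), F_TRUE)
        res = bx.refine(obs, model,
                        bx.RefinementOptions(mode="partial_occupancy", f=F_TRUE))
        trace = np.array(res.target_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_partial_mode_recovers_light_model(self, toy_models, toy_obs):
        dark, light = toy_models
        obs, _ = toy_obs
        model = bx.two_state_model(dark, dark.copy(), F_TRUE)
        res = bx.refine(obs, model,
                        bx.RefinementOptions(mode="partial_occupancy", f=F_TRUE))
        prof = bx.rmsd_profile(light, res.model.select(conformer="B"))
        assert prof.displacements.max() < 0.05

    def test_extrapolated_mode_recovers_light_model(self, toy_models, toy_obs):
        dark, light = toy_models
        obs, ref = toy_obs
        F_ext = bx.extrapolate(obs, ref, F_TRUE).F_ext
        res = bx.refine(F_ext, dark.copy(),
                        bx.RefinementOptions(mode="extrapolated"))
        prof = bx.rmsd_profile(light, res.model)
        assert prof.displacements.max() < 0.05

    def test_partial_mode_requires_free_conformer(self, toy_models, toy_obs):
        dark, _ = toy_models
        obs, _ = toy_obs
        with pytest.raises(ValueError, match="free conformer"):
            bx.refine(obs, dark,
                      bx.RefinementOptions(mode="partial_occupancy", f=0.3))

    def test_invalid_options(self):
        with pytest.raises(ValueError):
            bx.RefinementOptions(mode="bogus")
        with pytest.raises(ValueError):
            bx.RefinementOptions(f=0.0)
        with pytest.raises(ValueError):
            bx.RefinementOptions(free_fraction=0.7)


class TestOccupancyScan:
    def test_single_point_grid_flagged(self, toy_models, toy_obs):
        dark, _ = toy_models
        obs, _ = toy_obs
        scan = bx.occupancy_scan(obs, dark, dark.copy(), np.array([F_TRUE]))
        assert scan.correlations[0] == 1.0
        assert scan.flags.get("single_point_grid")

    def test_inverse_occupancy_law_pointwise(self):
        """In the first-order regime the refined displacement at modeled f is
        (f_true/f) times the true displacement."""
        from bootsfx.synthetic import make_two_state_models

        dark, light = make_two_state_models(seed=11, displacement=0.15,
                                            transient_water=False)
        F_dark = bx.structure_factors(dark, D_MIN)
        F_light = bx.structure_factors(light, D_MIN)
        F_mix = bx.mix_states(F_dark, F_light, F_TRUE)
        obs = bx.ReflectionSet(hkl=F_mix.hkl, amplitude=F_mix.amplitude,
                               cell=dark.cell, d_min=D_MIN)
        true_mean = bx.rmsd_profile(dark, light).mean
        grid = np.array([0.25, 0.4, 0.6, 0.8, 1.0])
        scan = bx.occupancy_scan(obs, dark, dark.copy(), grid)
        expected = (F_TRUE / grid) * true_mean
        np.testing.assert_allclose(scan.mean_displacement, expected, rtol=0.05)

    def test_argmax_correlation_near_true_occupancy_on_noisy_data(self, toy_models):
        dark, light = toy_models
        fs_dark, fs_light = two_state_frameset(dark, light, F_TRUE, 3.0,
                                               n_frames=400, seed=6)
        merged = bx.intensities_to_amplitudes(
            bx.merge_frames(fs_light, np.arange(400), 3), cell=dark.cell, d_min=3.0
        )
        grid = np.arange(0.09, 1.0, 0.1)
        scan = bx.occupancy_scan(merged, dark, dark.copy(), grid)
        assert abs(scan.f_best - F_TRUE) <= 0.1 + 1e-9
        assert scan.f_best_range[0] <= scan.f_best <= scan.f_best_range[1]

    def test_grid_validation(self, toy_models, toy_obs):
        dark, _ = toy_models
        obs, _ = toy_obs
        with pytest.raises(ValueError):
            bx.occupancy_scan(obs, dark, dark.copy(), np.array([0.0, 0.5]))


class TestCoordinateSpread:
    def test_identical_models_have_zero_spread(self, toy_models):
        dark, _ = toy_models
        sp = bx.coordinate_spread([dark, dark.copy(), dark.copy()])
        np.testing.assert_allclose(sp.spread, 0.0, atol=1e-14)

    def test_two_point_formula(self):
        from bootsfx.crystal import Atom, AtomicModel, UnitCell

        cell = UnitCell(20, 20, 20)
        d = 0.6  # Angstrom
        base = AtomicModel(cell, [Atom("CA1", "C", 6, [0.5, 0.5, 0.5]),
                                  Atom("CA2", "C", 6, [0.2, 0.2, 0.2])])
        plus = base.copy()
        plus.atoms[0].frac = plus.atoms[0].frac + np.array([d / 2 / 20, 0, 0])
        minus = base.copy()
        minus.atoms[0].frac = minus.atoms[0].frac - np.array([d / 2 / 20, 0, 0])
        sp = bx.coordinate_spread([plus, minus])
        np.testing.assert_allclose(sp.spread, [d / 2, 0.0], atol=1e-12)

    def test_ordering_mismatch_rejected(self, toy_models):
        dark, _ = toy_models
        scrambled = dark.copy()
        scrambled.atoms = scrambled.atoms[::-1]
        with pytest.raises(ValueError, match="ordering"):
            bx.coordinate_spread([dark, scrambled])

    def test_spread_shrinks_with_sample_size(self, toy_models):
        """Bootstrap coordinate spread follows the N^-1/2 law."""
        dark, _ = toy_models
        F_dark = bx.structure_factors(dark, 3.0)
        frames = simulate_frames(F_dark, 320, seed=21)
        spreads = []
        sizes = [40, 160]
        for s in sizes:
            plan = bx.bootstrap_plan(320, s, 6, seed=50 + s)
            models = [
                bx.refine(
                    bx.intensities_to_amplitudes(bx.merge_frames(frames, idx, 3),
                                                 cell=dark.cell, d_min=3.0),
                    dark.copy(), bx.RefinementOptions(mode="extrapolated"),
                )
                for idx in plan
            ]
            spreads.append(bx.coordinate_spread(models).mean)
        assert spreads[1] < spreads[0]


class TestCompareApproaches:
    def test_same_set_twice_gives_zero_separation(self, toy_models, toy_obs):
        dark, _ = toy_models
        obs, ref = toy_obs
        rng_models = []
        for seed in (0, 1, 2):
            model = dark.copy()
            rng = np.random.default_rng(seed)
            for a in model.atoms:
                a.frac = a.frac + rng.normal(0, 0.002, 3)
            rng_models.append(model)
        # use the same perturbed set for "partial" (as conformer B) and "extrapolated"
        partial = []
        for m in rng_models:
            tm = bx.two_state_model(dark, m, 0.3)
            partial.append(tm)
        table, corr = bx.compare_approaches(partial, rng_models, reference=dark)
        np.testing.assert_allclose(table["separation"], 0.0, atol=1e-12)
        assert table["agree"].all() or np.allclose(table["summed_bars"], 0)
        assert corr == pytest.approx(1.0, abs=1e-9)

    def test_flags_match_direct_recomputation(self, toy_models):
        dark, _ = toy_models
        rng = np.random.default_rng(3)
        set_a, set_b = [], []
        for _ in range(4):
            ma = dark.copy()
            mb = dark.copy()
            for a, b in zip(ma.atoms, mb.atoms):
                a.frac = a.frac + rng.normal(0, 0.003, 3)
                b.frac = b.frac + rng.normal(0, 0.003, 3)
            set_a.append(bx.two_state_model(dark, ma, 0.3))
            set_b.append(mb)
        table, _ = bx.compare_approaches(set_a, set_b)
        sp = bx.coordinate_spread(set_a, conformer="B")
        se = bx.coordinate_spread(set_b)
        sep = np.linalg.norm(
            dark.cell.min_image_cart(sp.mean_frac - se.mean_frac), axis=1
        )
        np.testing.assert_allclose(table["separation"], sep, rtol=1e-12)
        np.testing.assert_array_equal(table["agree"], sep < sp.spread + se.spread)
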
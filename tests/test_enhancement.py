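"""Unit tests for the sum-over-states enhancement machinery."""

import numpy as np
import pytest
from dataclasses import replace

from enhvcd import (
    ResonanceError,
    enhance,
    enhancement_factor,
    mode_moments,
    nac_to_normal,
    rotational_strength,
    total_strengths,
)
from conftest import micro_bundle
from oracles import brute_enhancement, brute_nac_projection


class TestNacToNormal:
    def test_zero_cartesian_nac_projects_to_zero(self, small_bundle):
        state = replace(
            small_bundle.states[0],
            nac_cartesian=np.zeros(3 * small_bundle.n_atoms),
        )
        assert np.all(nac_to_normal(state, small_bundle.modes) == 0.0)

    def test_unit_column_selects_one_component(self, small_bundle):
        # an S column equal to a Cartesian unit vector picks out that entry
        from enhvcd import NormalModes

        n3 = 3 * small_bundle.n_atoms
        s = np.zeros((n3, 1))
        s[4, 0] = 1.0
        modes = NormalModes(s_matrix=s, frequencies=[1234.0])
        nac = np.arange(1.0, n3 + 1)
        state = replace(small_bundle.states[0], nac_cartesian=nac)
        np.testing.assert_array_equal(nac_to_normal(state, modes), [nac[4]])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_explicit_double_loop(self, seed):
        b = micro_bundle(seed)
        for state in b.states:
            np.testing.assert_allclose(
                nac_to_normal(state, b.modes),
                brute_nac_projection(state, b.modes),
                rtol=1e-12,
                atol=1e-300,
            )

    def test_length_mismatch_raises(self, small_bundle):
        state = replace(small_bundle.states[0], nac_cartesian=np.zeros(6))
        with pytest.raises(ValueError, match="NAC length"):
            nac_to_normal(state, small_bundle.modes)


class TestEnhancementFactor:
    def test_large_gap_limit_vanishes(self):
        assert abs(enhancement_factor(1500.0, 1e9)) < 1e-5

    def test_sqrt_two_ratio_gives_exactly_one(self):
        nu = 1500.0
        assert enhancement_factor(nu, np.sqrt(2.0) * nu) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_converged_dd_state_value(self):
        # 0.23 eV ~ 1855.07 cm^-1 against a 1500 cm^-1 mode
        assert enhancement_factor(1500.0, 1855.07) == pytest.approx(1.889, abs=1e-3)

    def test_below_band_is_negative(self):
        assert enhancement_factor(1500.0, 800.0) < 0.0

    def test_pole_guard_raises(self):
        with pytest.raises(ResonanceError):
            enhancement_factor(1500.0, 1520.0)


class TestEnhance:
    def test_empty_state_list_gives_all_zero(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        enh = enhance([], small_bundle.tensors, small_bundle.modes, mom)
        assert np.all(enh.r_enh == 0.0)
        assert np.all(enh.e_enh == 0.0) and np.all(enh.m_enh == 0.0)
        assert enh.per_state_r.shape == (0, small_bundle.modes.n_modes)

    def test_zero_edtm_kills_electric_channel(self, demo_bundle):
        # d-d states: Laporte-forbidden EDTMs, magnetic channel carries it all
        mom = mode_moments(demo_bundle.tensors, demo_bundle.modes)
        enh = enhance(
            list(demo_bundle.states), demo_bundle.tensors, demo_bundle.modes, mom
        )
        assert np.all(enh.electric_channel == 0.0)
        np.testing.assert_array_equal(enh.r_enh, enh.magnetic_channel)
        assert np.max(np.abs(enh.magnetic_channel)) > 0.0

    def test_two_states_sum_of_single_state_runs(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        states = list(small_bundle.states)
        both = enhance(states, small_bundle.tensors, small_bundle.modes, mom)
        singles = [
            enhance([s], small_bundle.tensors, small_bundle.modes, mom)
            for s in states
        ]
        np.testing.assert_allclose(
            both.r_enh, singles[0].r_enh + singles[1].r_enh, rtol=1e-12, atol=1e-300
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_cross_terms(self, seed):
        b = micro_bundle(seed)
        mom = mode_moments(b.tensors, b.modes)
        enh = enhance(list(b.states), b.tensors, b.modes, mom)
        e_ref, m_ref, r_ref = brute_enhancement(
            list(b.states), b.modes, mom.electric, mom.magnetic
        )
        np.testing.assert_allclose(enh.e_enh, e_ref, rtol=1e-12, atol=1e-300)
        np.testing.assert_allclose(enh.m_enh, m_ref, rtol=1e-12, atol=1e-300)
        np.testing.assert_allclose(enh.r_enh, r_ref, rtol=1e-11, atol=1e-300)

    def test_pole_guard_violation_names_pair(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        nu0 = small_bundle.modes.frequencies[0]
        bad = replace(
            small_bundle.states[0],
            energy=(nu0 + 10.0) / 219474.6313632,  # 10 cm^-1 detuning, in hartree
        )
        with pytest.raises(ResonanceError, match="S1"):
            enhance([bad], small_bundle.tensors, small_bundle.modes, mom)

    def test_nac_locality_contributions_are_atomwise_additive(self, small_bundle):
        # splitting the Cartesian NAC over disjoint atom sets splits r_enh
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        state = small_bundle.states[0]
        nac = state.nac_cartesian.reshape(-1, 3).copy()
        half_a, half_b = nac.copy(), nac.copy()
        half_a[3:] = 0.0
        half_b[:3] = 0.0
        full = enhance([state], small_bundle.tensors, small_bundle.modes, mom)
        part_a = enhance(
            [replace(state, nac_cartesian=half_a.ravel())],
            small_bundle.tensors, small_bundle.modes, mom,
        )
        part_b = enhance(
            [replace(state, nac_cartesian=half_b.ravel())],
            small_bundle.tensors, small_bundle.modes, mom,
        )
        np.testing.assert_allclose(
            full.r_enh, part_a.r_enh + part_b.r_enh, rtol=1e-10, atol=1e-300
        )


class TestTotalStrengths:
    def test_zero_enhancement_recovers_mfp(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        enh = enhance([], small_bundle.tensors, small_bundle.modes, mom)
        total = total_strengths(mom, enh)
        mfp = rotational_strength(mom)
        np.testing.assert_array_equal(total.rotational, mfp.rotational)
        np.testing.assert_array_equal(total.dipole, mfp.dipole)

    def test_component_bookkeeping_is_exact(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        enh = enhance(
            list(small_bundle.states), small_bundle.tensors, small_bundle.modes, mom
        )
        total = total_strengths(mom, enh)
        np.testing.assert_array_equal(
            total.components["mfp"] + total.components["enhancement"],
            total.rotational,
        )

    def test_mfp_recovery_monotone_in_inverse_energy(self, small_bundle):
        # single state pushed upward: deviation from MFP shrinks monotonically
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        mfp = rotational_strength(mom).rotational
        state = small_bundle.states[0]
        devs = []
        for e_ev in (0.5, 1.0, 2.0, 4.0, 8.0):
            s = replace(state, energy=e_ev / 27.211386245988)
            enh = enhance([s], small_bundle.tensors, small_bundle.modes, mom)
            total = total_strengths(mom, enh)
            devs.append(np.max(np.abs(total.rotational - mfp)))
        assert all(a > b for a, b in zip(devs, devs[1:]))

    def test_ir_enhancement_flag_augments_dipole(self, small_bundle):
        mom = mode_moments(small_bundle.tensors, small_bundle.modes)
        states = [
            replace(s, edtm=np.array([0.02, -0.01, 0.03]))
            for s in small_bundle.states
        ]
        enh = enhance(states, small_bundle.tensors, small_bundle.modes, mom)
        off = total_strengths(mom, enh, include_ir_enhancement=False)
        on = total_strengths(mom, enh, include_ir_enhancement=True)
        expected = np.einsum(
            "ib,ib->i", mom.electric + enh.e_enh, mom.electric + enh.e_enh
        )
        np.testing.assert_allclose(on.dipole, expected, rtol=1e-12)
        assert np.any(on.dipole != off.dipole)
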
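"""Tests of the excitation-energy fit and assignment protocol."""

from dataclasses import replace

import numpy as np
import pytest

from enhvcd import (
    FixtureSpec,
    OptimizationConfig,
    Spectrum,
    VcdBundle,
    assign_configuration,
    make_bundle,
    make_reference,
    mirror_bundle,
    model_spectrum,
    objective,
    optimize,
    sensitivity_scan,
    similarity,
)


@pytest.fixture(scope="module")
def fit_setup():
    bundle = make_bundle(FixtureSpec(n_atoms=8, n_modes=10, n_states=2, seed=3))
    truth = [0.21, 0.34]
    reference = make_reference(bundle, truth, noise_level=0.01, seed=11)
    config = OptimizationConfig(n_starts=8, seed=5)
    return bundle, truth, reference, config


class TestObjective:
    def test_truth_energies_score_one_on_clean_reference(self, fit_setup):
        bundle, truth, _, config = fit_setup
        clean = make_reference(bundle, truth, noise_level=0.0)
        assert objective(truth, bundle, clean, config) == pytest.approx(1.0, abs=1e-6)

    def test_far_detuned_states_reduce_to_mfp_score(self, fit_setup):
        bundle, _, reference, config = fit_setup
        mfp_spec = model_spectrum(bundle, mode="mfp")
        mfp_score = similarity(mfp_spec, reference, config.window)
        wide = OptimizationConfig(upper_bound=15.0)
        far = objective([12.4, 12.4], bundle, reference, wide)  # ~1e5 cm^-1
        assert far == pytest.approx(mfp_score, abs=1e-3)
        # residual influence decays monotonically with the detuning
        at_one_ev = objective([1.0, 1.0], bundle, reference, config)
        assert abs(at_one_ev - mfp_score) < 0.05
        assert abs(far - mfp_score) < abs(at_one_ev - mfp_score)

    def test_energy_inside_pole_guard_returns_penalty(self, fit_setup):
        bundle, _, reference, config = fit_setup
        nu0 = float(bundle.modes.frequencies[5])
        inside = (nu0 + 10.0) / 8065.543937  # 10 cm^-1 detuning, in eV
        assert (
            objective([inside, 0.4], bundle, reference, config)
            == config.pole_penalty
        )


class TestOptimize:
    def test_recovers_planted_energies(self, fit_setup):
        bundle, truth, reference, config = fit_setup
        res = optimize(bundle, reference, config)
        assert res.score > 0.95
        np.testing.assert_allclose(res.energies, truth, atol=0.01)
        assert res.bound_hits == (False, False)

    def test_deterministic_for_fixed_seed(self, fit_setup):
        bundle, _, reference, _ = fit_setup
        config = OptimizationConfig(n_starts=1, seed=9)
        a = optimize(bundle, reference, config)
        b = optimize(bundle, reference, config)
        np.testing.assert_array_equal(a.energies, b.energies)
        assert a.score == b.score
        assert a.trace == b.trace

    def test_score_never_below_best_start(self, fit_setup):
        bundle, _, reference, config = fit_setup
        res = optimize(bundle, reference, config)
        assert res.score >= max(res.trace) - 1e-12

    def test_energies_stay_within_bounds(self, fit_setup):
        bundle, _, reference, _ = fit_setup
        config = OptimizationConfig(n_starts=4, seed=2, lower_bound=0.15,
                                    upper_bound=0.5)
        res = optimize(bundle, reference, config)
        assert np.all(res.energies >= 0.15) and np.all(res.energies <= 0.5)

    def test_zero_coupling_state_parked_at_upper_bound(self, fit_setup):
        bundle, truth, _, _ = fit_setup
        dead = replace(
            bundle.states[1], nac_cartesian=np.zeros(3 * bundle.n_atoms)
        )
        b2 = VcdBundle(
            system=bundle.system,
            modes=bundle.modes,
            tensors=bundle.tensors,
            states=(bundle.states[0], dead),
            meta=bundle.meta,
        )
        reference = make_reference(b2, truth, noise_level=0.0)
        config = OptimizationConfig(n_starts=6, seed=4)
        res = optimize(b2, reference, config)
        assert res.bound_hits[1]
        assert res.energies[1] == pytest.approx(config.upper_bound)
        assert res.energies[0] == pytest.approx(truth[0], abs=0.01)

    def test_mirror_antisymmetry_reproduces_score_exactly(self, fit_setup):
        bundle, _, reference, _ = fit_setup
        config = OptimizationConfig(n_starts=4, seed=6)
        direct = optimize(bundle, reference, config)
        mirrored = optimize(mirror_bundle(bundle), reference.negate(), config)
        assert mirrored.score == direct.score
        np.testing.assert_array_equal(mirrored.energies, direct.energies)

    def test_reference_not_covering_window_raises(self, fit_setup):
        bundle, _, _, config = fit_setup
        short = Spectrum(
            grid=np.linspace(1200.0, 1400.0, 50), values=np.zeros(50)
        )
        with pytest.raises(ValueError, match="not covered"):
            optimize(bundle, short, config)


class TestSensitivityScan:
    def test_amplitude_grows_approaching_resonance_from_above(self, fit_setup):
        # amplitude of the band nearest the scanned state grows strictly as
        # its energy descends toward the band (the resonance factor grows)
        bundle, _, _, config = fit_setup
        nu_max = float(bundle.modes.frequencies.max())  # highest mode, cm^-1
        offsets = np.array([300.0, 200.0, 120.0, 75.0])
        e_grid = np.sort((nu_max + offsets) / 8065.543937)
        scan = sensitivity_scan(
            bundle, (0, 1), e_grid, [0.45],
            subwindow=(nu_max - 40.0, nu_max + 40.0), config=config,
        )
        col = scan.max_abs[:, 0][::-1]  # descending energy toward the band
        assert np.all(np.diff(col) > 0.0)

    def test_identical_states_give_symmetric_map(self, fit_setup):
        bundle, _, _, config = fit_setup
        twin = replace(bundle.states[0], label="S1b")
        b2 = VcdBundle(
            system=bundle.system,
            modes=bundle.modes,
            tensors=bundle.tensors,
            states=(bundle.states[0], twin),
            meta=bundle.meta,
        )
        grid = [0.25, 0.30, 0.40]
        scan = sensitivity_scan(b2, (0, 1), grid, grid, config=config)
        np.testing.assert_allclose(scan.max_abs, scan.max_abs.T, rtol=1e-10)

    def test_pole_guard_cells_masked_not_raised(self, fit_setup):
        bundle, _, _, config = fit_setup
        nu0 = float(bundle.modes.frequencies[0])
        inside = nu0 / 8065.543937  # exactly on a mode
        scan = sensitivity_scan(bundle, (0, 1), [inside], [0.45], config=config)
        assert scan.masked[0, 0]
        assert np.isnan(scan.max_abs[0, 0])

    def test_small_shift_near_resonance_amplifies_strongly(self, demo_bundle):
        # a 0.02 eV move toward the band more than doubles the peak response
        nu_max = float(demo_bundle.modes.frequencies.max())
        near = (nu_max + 75.0) / 8065.543937
        far = near + 0.02
        scan = sensitivity_scan(
            demo_bundle, (0, 1), [near, far], [0.42],
            subwindow=(nu_max - 40.0, nu_max + 40.0),
        )
        assert scan.max_abs[0, 0] > 2.0 * scan.max_abs[1, 0]


class TestAssignment:
    def test_self_reference_assigned_as_given(self, fit_setup):
        bundle, _, reference, config = fit_setup
        report = assign_configuration(bundle, reference, config)
        assert report.verdict == "assigned-as-given"
        assert report.winner == "direct"
        assert report.direct.score > 0.95
        assert report.margin > config.assign_margin

    def test_mirrored_reference_assigned_as_mirror(self, fit_setup):
        bundle, truth, _, config = fit_setup
        mref = make_reference(
            mirror_bundle(bundle), truth, noise_level=0.01, seed=12
        )
        report = assign_configuration(bundle, mref, config)
        assert report.verdict == "assigned-as-mirror"
        assert report.winner == "mirrored"

    def test_pure_noise_reference_is_inconclusive(self, fit_setup):
        bundle, _, reference, config = fit_setup
        rng = np.random.default_rng(0)
        noise = Spectrum(
            grid=reference.grid,
            values=rng.normal(0.0, np.abs(reference.values).max(),
                              reference.grid.size),
        )
        report = assign_configuration(bundle, noise, config)
        assert report.verdict == "inconclusive"
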
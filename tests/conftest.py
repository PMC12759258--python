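import numpy as np
import pytest

from enhvcd import FixtureSpec, demo_spec, make_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Compact 8-atom, 10-mode, 2-state bundle used across the suite."""
    return make_bundle(FixtureSpec(n_atoms=8, n_modes=10, n_states=2, seed=3))


@pytest.fixture(scope="session")
def demo_bundle():
    """The sparteine-like demonstration fixture (30 atoms, 3 d-d states)."""
    return make_bundle(demo_spec())


def micro_bundle(seed, n_states=2):
    """Tiny random bundle (<=3 atoms, <=2 modes) for brute-force checks."""
    rng = np.random.default_rng(seed)
    n_atoms = int(rng.integers(1, 4))
    n_modes = int(rng.integers(1, min(2, 3 * n_atoms) + 1))
    return make_bundle(
        FixtureSpec(
            n_atoms=n_atoms,
            n_modes=n_modes,
            n_states=n_states,
            # keep planted states clear of the 950-1650 cm^-1 mode band
            state_energies=(0.25, 0.45)[:n_states],
            nac_mask=tuple(range(n_atoms)),
            magnitude_scales={"edtm": 0.02},
            seed=seed,
        )
    )
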
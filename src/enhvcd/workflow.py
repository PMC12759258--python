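"""Convenience composition of the pipeline: bundle -> strengths -> spectrum.

Thin glue used by the fixture generator, the optimizer and the CLI so that
every consumer broadens and scores spectra through the exact same code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import ModeMoments, ModeStrengths, mode_moments, rotational_strength
from .enhancement import (
    DEFAULT_POLE_GUARD_CM,
    EnhancementResult,
    enhance,
    total_strengths,
)
from .io import VcdBundle
from .spectra import DEFAULT_HALFWIDTH_CM, Spectrum, broaden
from .constants import HARTREE_TO_EV

__all__ = ["states_with_energies", "bundle_strengths", "model_spectrum"]


def states_with_energies(bundle: VcdBundle, energies_ev, indices=None):
    """Copy of the bundle's states with selected excitation energies replaced.

    ``energies_ev`` are in eV; ``indices`` selects which states are replaced
    (default: the first ``len(energies_ev)`` states).
    """
    states = list(bundle.states)
    energies_ev = np.atleast_1d(np.asarray(energies_ev, dtype=float))
    if indices is None:
        indices = list(range(len(energies_ev)))
    if len(indices) != energies_ev.size:
        raise ValueError("indices and energies length mismatch")
    for idx, e_ev in zip(indices, energies_ev):
        states[idx] = replace(states[idx], energy=float(e_ev) / HARTREE_TO_EV)
    return tuple(states)


def bundle_strengths(
    bundle: VcdBundle,
    mode: str = "enhanced",
    energies_ev=None,
    state_indices=None,
    pole_guard: float = DEFAULT_POLE_GUARD_CM,
) -> tuple[ModeStrengths, ModeMoments, EnhancementResult | None]:
    """Per-mode strengths for a bundle, MFP-only or with SOS enhancement."""
    moments = mode_moments(bundle.tensors, bundle.modes)
    if mode == "mfp":
        return rotational_strength(moments), moments, None
    if mode != "enhanced":
        raise ValueError(f"unknown mode {mode!r}")
    states = (
        states_with_energies(bundle, energies_ev, state_indices)
        if energies_ev is not None
        else bundle.states
    )
    enh = enhance(list(states), bundle.tensors, bundle.modes, moments, pole_guard)
    return total_strengths(moments, enh), moments, enh


def model_spectrum(
    bundle: VcdBundle,
    mode: str = "enhanced",
    energies_ev=None,
    state_indices=None,
    halfwidth: float = DEFAULT_HALFWIDTH_CM,
    grid=None,
    kind: str = "vcd",
    pole_guard: float = DEFAULT_POLE_GUARD_CM,
) -> Spectrum:
    """Broadened spectrum of a bundle (the standard display pipeline)."""
    strengths, _, _ = bundle_strengths(
        bundle, mode=mode, energies_ev=energies_ev,
        state_indices=state_indices, pole_guard=pole_guard,
    )
    return broaden(strengths, bundle.modes, halfwidth=halfwidth, grid=grid, kind=kind)
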
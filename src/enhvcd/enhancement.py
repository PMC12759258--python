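"""Sum-over-states vibronic enhancement of VCD from low-lying excited states.

Open-shell transition-metal complexes carry electronic states a few tenths of
an eV above the ground state. These couple to the vibrational fundamentals and
add frequency-dependent corrections to the APT and AAT, producing the
well-known VCD intensity enhancement. The correction to the rotational
strength of mode *i* is the cross term

    R_i^enh = Im[ E_i^tot . M_i^enh + E_i^enh . M_i^tot ]

with

    E_{i,b}^enh = 2 (hbar/2w_i)^{1/2}  sum_e f_ie  <g|mu_b|e> <e|dg/dQ_i>
    M_{i,b}^enh = -(2 hbar^3 w_i)^{1/2} sum_e f_ie (<e|m_b|g>/w_eg) <e|dg/dQ_i>

and the resonance factor

    f_ie = w_i^2 / (w_eg^2 - w_i^2).

``<e|dg/dQ_i>`` is the Cartesian non-adiabatic coupling projected onto normal
mode *i*. Only excited states whose energy nearly coincides with a vibrational
frequency produce significant enhancement; the factor diverges at exact
resonance, which is excluded by a configurable pole guard.

The vertical approximation is assumed throughout: excited-state surfaces are
treated as undisplaced copies of the ground-state surface, so no vibrational
overlap (Franck-Condon) weights appear. This biases the predicted enhancement
whenever excited states relax appreciably, which is the motivation for
treating excitation energies as tunable parameters (see
:mod:`enhvcd.optimize`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HARTREE_TO_CM
from .core import (
    AtomicTensorSet,
    ModeMoments,
    ModeStrengths,
    NormalModes,
    _as_array,
)

__all__ = [
    "ExcitedState",
    "EnhancementResult",
    "ResonanceError",
    "DEFAULT_POLE_GUARD_CM",
    "nac_to_normal",
    "enhancement_factor",
    "enhance",
    "total_strengths",
    "near_resonance_report",
]

#: default half-width of the excluded detuning band around exact resonance
DEFAULT_POLE_GUARD_CM = 50.0


class ResonanceError(ValueError):
    """An excitation energy fell inside the pole guard of a vibrational mode."""

    def __init__(self, state_label: str, mode_index: int, detuning_cm: float):
        self.state_label = state_label
        self.mode_index = mode_index
        self.detuning_cm = detuning_cm
        super().__init__(
            f"state '{state_label}' is {detuning_cm:.2f} cm^-1 from mode "
            f"{mode_index}: inside the resonance pole guard"
        )


@dataclass(frozen=True)
class ExcitedState:
    """A low-lying electronic excited state entering the sum over states.

    Parameters
    ----------
    label : text identifier.
    energy : vertical excitation energy in hartree.
    edtm : electric dipole transition moment <g|mu|e>, a.u., shape (3,).
    mdtm : magnetic dipole transition moment <e|m|g> stored as its real-valued
        imaginary part (1/c-absorbed a.u.), shape (3,).
    nac_cartesian : derivative coupling <e| dg/dR_la >, a.u., shape (3*n_atoms,),
        atom-major x/y/z ordering.
    """

    label: str
    energy: float
    edtm: np.ndarray
    mdtm: np.ndarray
    nac_cartesian: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.energy) and self.energy > 0):
            raise ValueError(f"state '{self.label}': energy must be positive")
        object.__setattr__(self, "edtm", _as_array(self.edtm, (3,), "edtm"))
        object.__setattr__(self, "mdtm", _as_array(self.mdtm, (3,), "mdtm"))
        nac = _as_array(self.nac_cartesian, name="nac_cartesian")
        if nac.ndim != 1 or nac.size % 3 != 0:
            raise ValueError(
                f"state '{self.label}': nac_cartesian must be a flat 3N vector"
            )
        object.__setattr__(self, "nac_cartesian", nac)

    @property
    def energy_cm(self) -> float:
        return self.energy * HARTREE_TO_CM

    @property
    def energy_ev(self) -> float:
        from .constants import HARTREE_TO_EV

        return self.energy * HARTREE_TO_EV


@dataclass(frozen=True)
class EnhancementResult:
    """Per-mode enhancement moments, strengths and their decompositions.

    ``r_enh = magnetic_channel + electric_channel`` exactly, and each
    ``per_state_*`` array sums over its first axis to the corresponding total
    (the sum over states is linear).
    """

    e_enh: np.ndarray                 # (n_modes, 3)
    m_enh: np.ndarray                 # (n_modes, 3), imaginary part
    r_enh: np.ndarray                 # (n_modes,)
    magnetic_channel: np.ndarray      # Im[E_tot . M_enh]
    electric_channel: np.ndarray      # Im[E_enh . M_tot]
    per_state_r: np.ndarray           # (n_states, n_modes)
    per_state_magnetic: np.ndarray    # (n_states, n_modes)
    per_state_electric: np.ndarray    # (n_states, n_modes)
    state_labels: tuple[str, ...]

    @property
    def n_modes(self) -> int:
        return self.r_enh.shape[0]


def nac_to_normal(state: ExcitedState, modes: NormalModes) -> np.ndarray:
    """Project a Cartesian NAC vector onto the normal modes.

    ``NAC_i = sum_la S_la,i nac_la`` — the derivative coupling with respect to
    normal coordinate Q_i.
    """
    if state.nac_cartesian.size != modes.s_matrix.shape[0]:
        raise ValueError(
            f"state '{state.label}': NAC length {state.nac_cartesian.size} "
            f"does not match 3*n_atoms = {modes.s_matrix.shape[0]}"
        )
    return modes.s_matrix.T @ state.nac_cartesian


def enhancement_factor(
    mode_freq: float,
    excitation: float,
    pole_guard: float = DEFAULT_POLE_GUARD_CM,
) -> float:
    """Resonance factor ``w_a^2 / (w_eg^2 - w_a^2)`` (both in cm^-1).

    Negative when the excitation lies below the mode. Raises
    :class:`ResonanceError` when the detuning is within ``pole_guard``.
    """
    if mode_freq <= 0 or excitation <= 0:
        raise ValueError("mode_freq and excitation must be positive")
    detuning = abs(excitation - mode_freq)
    if detuning < pole_guard:
        raise ResonanceError("<scalar>", -1, detuning)
    return mode_freq**2 / (excitation**2 - mode_freq**2)


def _factor_matrix(
    states: list[ExcitedState],
    modes: NormalModes,
    pole_guard: float,
) -> np.ndarray:
    """Resonance factors f[e, i]; raises on any pole-guard violation."""
    nu_i = modes.frequencies                      # (n_modes,)
    nu_eg = np.array([s.energy_cm for s in states])  # (n_states,)
    detuning = np.abs(nu_eg[:, None] - nu_i[None, :])
    bad = np.argwhere(detuning < pole_guard)
    if bad.size:
        e, i = bad[0]
        raise ResonanceError(states[e].label, int(i), float(detuning[e, i]))
    return nu_i[None, :] ** 2 / (nu_eg[:, None] ** 2 - nu_i[None, :] ** 2)


def near_resonance_report(
    states: list[ExcitedState],
    modes: NormalModes,
    window_cm: float = 3 * DEFAULT_POLE_GUARD_CM,
) -> dict[str, list[int]]:
    """Per-state list of mode indices within ``window_cm`` of resonance."""
    out: dict[str, list[int]] = {}
    for s in states:
        close = np.nonzero(np.abs(s.energy_cm - modes.frequencies) < window_cm)[0]
        out[s.label] = [int(i) for i in close]
    return out


def enhance(
    states: list[ExcitedState],
    tensors: AtomicTensorSet,
    modes: NormalModes,
    moments: ModeMoments,
    pole_guard: float = DEFAULT_POLE_GUARD_CM,
) -> EnhancementResult:
    """Sum-over-states enhancement moments and rotational-strength correction.

    Only the cross terms Im[E_tot.M_enh + E_enh.M_tot] are formed; the
    second-order product E_enh.M_enh is not part of the correction.
    """
    n_modes = modes.n_modes
    if moments.n_modes != n_modes:
        raise ValueError("moments and modes disagree on mode count")
    if not states:
        z = np.zeros((n_modes, 3))
        zi = np.zeros(n_modes)
        empty = np.zeros((0, n_modes))
        return EnhancementResult(
            e_enh=z, m_enh=z.copy(), r_enh=zi,
            magnetic_channel=zi.copy(), electric_channel=zi.copy(),
            per_state_r=empty, per_state_magnetic=empty.copy(),
            per_state_electric=empty.copy(), state_labels=(),
        )

    f = _factor_matrix(states, modes, pole_guard)          # (n_states, n_modes)
    nac = np.stack([nac_to_normal(s, modes) for s in states])  # (n_states, n_modes)
    edtm = np.stack([s.edtm for s in states])              # (n_states, 3)
    mdtm = np.stack([s.mdtm for s in states])              # (n_states, 3)
    w_eg = np.array([s.energy for s in states])            # hartree
    omega = modes.omega_au                                 # (n_modes,)

    pref_e = 2.0 * np.sqrt(1.0 / (2.0 * omega))            # (n_modes,)
    pref_m = -np.sqrt(2.0 * omega)

    # per-state moment contributions, shape (n_states, n_modes, 3)
    e_parts = pref_e[None, :, None] * (f * nac)[:, :, None] * edtm[:, None, :]
    m_parts = (
        pref_m[None, :, None]
        * (f * nac)[:, :, None]
        * (mdtm / w_eg[:, None])[:, None, :]
    )

    per_state_magnetic = np.einsum("ib,sib->si", moments.electric, m_parts)
    per_state_electric = np.einsum("sib,ib->si", e_parts, moments.magnetic)
    per_state_r = per_state_magnetic + per_state_electric

    # r_enh is formed as the sum of the two channel totals so the channel
    # decomposition is exact; the per-state split re-sums to it within
    # floating-point reassociation error only
    magnetic_channel = per_state_magnetic.sum(axis=0)
    electric_channel = per_state_electric.sum(axis=0)
    return EnhancementResult(
        e_enh=e_parts.sum(axis=0),
        m_enh=m_parts.sum(axis=0),
        r_enh=magnetic_channel + electric_channel,
        magnetic_channel=magnetic_channel,
        electric_channel=electric_channel,
        per_state_r=per_state_r,
        per_state_magnetic=per_state_magnetic,
        per_state_electric=per_state_electric,
        state_labels=tuple(s.label for s in states),
    )


def total_strengths(
    moments: ModeMoments,
    enh: EnhancementResult,
    include_ir_enhancement: bool = False,
) -> ModeStrengths:
    """Total (MFP + enhancement) strengths with a labelled breakdown.

    ``rotational = R_mfp + R_enh``. The dipole strength is the MFP
    ``|E_tot|^2`` by default; with ``include_ir_enhancement`` the APT
    enhancement enters the electric moment too (``|E_tot + E_enh|^2``).
    """
    if moments.n_modes != enh.n_modes:
        raise ValueError("moments and enhancement disagree on mode count")
    from .core import rotational_strength

    mfp = rotational_strength(moments)
    total_r = mfp.rotational + enh.r_enh
    if include_ir_enhancement:
        e_full = moments.electric + enh.e_enh
        dipole = np.einsum("ib,ib->i", e_full, e_full)
    else:
        dipole = mfp.dipole
    return ModeStrengths(
        rotational=total_r,
        dipole=dipole,
        mode_frequencies=moments.mode_frequencies,
        components={"mfp": mfp.rotational, "enhancement": enh.r_enh},
    )
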
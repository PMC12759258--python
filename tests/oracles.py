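"""Independent index-by-index reference implementations.

Deliberately written as explicit Python loops over atoms, Cartesian
components, modes and states — no vectorisation shared with the package — so
they can serve as brute-force oracles for the contraction machinery.
"""

import numpy as np

from enhvcd.constants import HARTREE_TO_CM


def brute_mode_moments(tensors, modes):
    """Loop version of the APT/AAT -> per-mode moment contraction."""
    n_atoms = tensors.n_atoms
    n_modes = modes.n_modes
    omega = modes.frequencies / HARTREE_TO_CM
    electric = np.zeros((n_modes, 3))
    magnetic = np.zeros((n_modes, 3))
    apt = tensors.apt_electronic + tensors.apt_nuclear
    aat = tensors.aat_electronic + tensors.aat_nuclear
    for i in range(n_modes):
        for beta in range(3):
            acc_e = 0.0
            acc_m = 0.0
            for lam in range(n_atoms):
                for alpha in range(3):
                    s = modes.s_matrix[3 * lam + alpha, i]
                    acc_e += apt[lam, alpha, beta] * s
                    acc_m += aat[lam, alpha, beta] * s
            electric[i, beta] = np.sqrt(1.0 / (2.0 * omega[i])) * acc_e
            magnetic[i, beta] = -np.sqrt(2.0 * omega[i]) * acc_m
    return electric, magnetic


def brute_nac_projection(state, modes):
    """Loop version of the Cartesian-NAC -> normal-mode projection."""
    out = np.zeros(modes.n_modes)
    for i in range(modes.n_modes):
        acc = 0.0
        for la in range(modes.s_matrix.shape[0]):
            acc += modes.s_matrix[la, i] * state.nac_cartesian[la]
        out[i] = acc
    return out


def brute_enhancement(states, modes, electric_tot, magnetic_tot):
    """Loop version of the sum-over-states enhancement cross terms.

    Returns (e_enh, m_enh, r_enh) with r_enh the per-mode correction
    Im[E_tot . M_enh + E_enh . M_tot] under the imaginary-part storage
    convention.
    """
    n_modes = modes.n_modes
    omega = modes.frequencies / HARTREE_TO_CM
    e_enh = np.zeros((n_modes, 3))
    m_enh = np.zeros((n_modes, 3))
    for i in range(n_modes):
        nu_i = modes.frequencies[i]
        for state in states:
            nu_eg = state.energy * HARTREE_TO_CM
            factor = nu_i**2 / (nu_eg**2 - nu_i**2)
            nac_i = 0.0
            for la in range(modes.s_matrix.shape[0]):
                nac_i += modes.s_matrix[la, i] * state.nac_cartesian[la]
            for beta in range(3):
                e_enh[i, beta] += (
                    2.0
                    * np.sqrt(1.0 / (2.0 * omega[i]))
                    * factor
                    * state.edtm[beta]
                    * nac_i
                )
                m_enh[i, beta] += (
                    -np.sqrt(2.0 * omega[i])
                    * factor
                    * (state.mdtm[beta] / state.energy)
                    * nac_i
                )
    r_enh = np.zeros(n_modes)
    for i in range(n_modes):
        for beta in range(3):
            r_enh[i] += (
                electric_tot[i, beta] * m_enh[i, beta]
                + e_enh[i, beta] * magnetic_tot[i, beta]
            )
    return e_enh, m_enh, r_enh
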
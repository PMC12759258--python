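"""Domain types and the magnetic-field-perturbation (MFP) strength machinery.

The MFP rotational strength of normal mode *i* is

    R_i = Im[ E_i^tot . M_i^tot ]

with transition moments built by contracting the atomic polar tensor (APT,
``P = E + N``) and atomic axial tensor (AAT, ``A = I + J``) with the
Cartesian-to-normal-mode transformation matrix ``S``:

    E_{i,b}^tot = (hbar / 2 w_i)^{1/2}   sum_{la} P_{ab}^l S_{la,i}
    M_{i,b}^tot = -(2 hbar^3 w_i)^{1/2}  sum_{la} A_{ab}^l S_{la,i}

Everything here is in Hartree atomic units; AAT-type and magnetic-moment-type
quantities are purely imaginary for real ground-state wavefunctions and are
stored as their real-valued imaginary parts, so Im[...] reduces to a real dot
product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU_TO_ME,
    D_AU_TO_CGS40,
    HARTREE_TO_CM,
    R_AU_TO_CGS44,
    SPEED_OF_LIGHT_AU,
)

__all__ = [
    "MolecularSystem",
    "NormalModes",
    "AtomicTensorSet",
    "ModeMoments",
    "ModeStrengths",
    "nuclear_apt",
    "nuclear_aat",
    "mode_moments",
    "rotational_strength",
]


def _as_array(x, shape=None, name="array"):
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    if shape is not None and a.shape != shape:
        raise ValueError(f"{name} has shape {a.shape}, expected {shape}")
    return a


@dataclass(frozen=True)
class MolecularSystem:
    """Nuclear frame of the complex.

    Parameters
    ----------
    atom_symbols : element labels, one per atom.
    charges : nuclear charges Z (units of e), positive integers.
    masses : atomic masses in amu.
    coordinates : equilibrium Cartesian positions in bohr, shape (n_atoms, 3),
        expressed relative to the gauge origin named in ``origin_note``.
    origin_note : free text describing the gauge / coordinate origin used
        upstream. AATs and MDTMs are origin dependent; bundles with different
        origin notes must never be mixed.
    """

    atom_symbols: tuple[str, ...]
    charges: np.ndarray
    masses: np.ndarray
    coordinates: np.ndarray
    origin_note: str = "unspecified"

    def __post_init__(self):
        n = len(self.atom_symbols)
        object.__setattr__(self, "atom_symbols", tuple(self.atom_symbols))
        charges = _as_array(self.charges, (n,), "charges")
        if np.any(charges <= 0) or np.any(charges != np.round(charges)):
            raise ValueError("charges must be positive integers")
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "masses", _as_array(self.masses, (n,), "masses"))
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(
            self, "coordinates", _as_array(self.coordinates, (n, 3), "coordinates")
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    @property
    def masses_au(self) -> np.ndarray:
        """Atomic masses in electron masses."""
        return self.masses * AMU_TO_ME


@dataclass(frozen=True)
class NormalModes:
    """Harmonic normal modes.

    ``s_matrix`` (shape 3*n_atoms x n_modes, rows atom-major x/y/z) transforms
    Cartesian displacements to normal coordinates and is expected to be
    orthonormal under mass weighting in atomic units:
    ``sum_la m_la[me] S_la,i S_la,j = delta_ij``.

    ``frequencies`` are harmonic wavenumbers in cm^-1; ``scale_factor``
    records any global multiplicative scaling already applied (see
    :func:`enhvcd.spectra.apply_scale`).
    """

    s_matrix: np.ndarray
    frequencies: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        s = _as_array(self.s_matrix, name="s_matrix")
        if s.ndim != 2:
            raise ValueError("s_matrix must be 2-D (3*n_atoms x n_modes)")
        if s.shape[0] % 3 != 0:
            raise ValueError("s_matrix row count must be a multiple of 3")
        freqs = _as_array(self.frequencies, (s.shape[1],), "frequencies")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be strictly positive")
        if s.shape[1] > s.shape[0]:
            raise ValueError("more modes than Cartesian degrees of freedom")
        object.__setattr__(self, "s_matrix", s)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def n_modes(self) -> int:
        return self.s_matrix.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.s_matrix.shape[0] // 3

    @property
    def omega_au(self) -> np.ndarray:
        """Angular mode frequencies in hartree (hbar = 1)."""
        return self.frequencies / HARTREE_TO_CM

    def validate_orthonormality(
        self, system: MolecularSystem, tol: float = 1e-6
    ) -> float:
        """Check mass-weighted orthonormality of the S-matrix columns.

        Returns the maximum deviation |S^T M S - I|; emits a warning (never an
        error — upstream normalisation conventions vary) when it exceeds
        ``tol``.
        """
        m = np.repeat(system.masses_au, 3)
        gram = self.s_matrix.T @ (m[:, None] * self.s_matrix)
        dev = float(np.max(np.abs(gram - np.eye(self.n_modes))))
        if dev > tol:
            warnings.warn(
                f"normal modes deviate from mass-weighted orthonormality "
                f"by {dev:.3e} (tol {tol:.1e})",
                stacklevel=2,
            )
        return dev


@dataclass(frozen=True)
class AtomicTensorSet:
    """Per-atom APT and AAT blocks, split into electronic and nuclear parts.

    All arrays have shape (n_atoms, 3, 3) indexed [atom, alpha, beta] with
    alpha the nuclear-displacement and beta the field Cartesian component.
    AAT blocks are stored as real-valued imaginary parts.
    """

    apt_electronic: np.ndarray
    apt_nuclear: np.ndarray
    aat_electronic: np.ndarray
    aat_nuclear: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.apt_electronic).shape[0]
        for fname in ("apt_electronic", "apt_nuclear", "aat_electronic", "aat_nuclear"):
            a = _as_array(getattr(self, fname), (n, 3, 3), fname)
            object.__setattr__(self, fname, a)
        anti = self.aat_nuclear + np.transpose(self.aat_nuclear, (0, 2, 1))
        if np.max(np.abs(anti)) > 1e-10:
            raise ValueError("nuclear AAT blocks must be antisymmetric")

    @property
    def n_atoms(self) -> int:
        return self.apt_electronic.shape[0]

    @property
    def apt(self) -> np.ndarray:
        """Total APT, P = E + N (Eq. of the Stephens partition)."""
        return self.apt_electronic + self.apt_nuclear

    @property
    def aat(self) -> np.ndarray:
        """Total AAT, A = I + J (imaginary part, stored real)."""
        return self.aat_electronic + self.aat_nuclear


@dataclass(frozen=True)
class ModeMoments:
    """Per-mode total electric and magnetic transition-moment vectors (a.u.).

    ``magnetic`` holds the imaginary parts (real-valued storage convention).
    """

    electric: np.ndarray
    magnetic: np.ndarray
    mode_frequencies: np.ndarray

    def __post_init__(self):
        e = _as_array(self.electric, name="electric")
        if e.ndim != 2 or e.shape[1] != 3:
            raise ValueError("electric must have shape (n_modes, 3)")
        object.__setattr__(self, "electric", e)
        object.__setattr__(
            self, "magnetic", _as_array(self.magnetic, e.shape, "magnetic")
        )
        object.__setattr__(
            self,
            "mode_frequencies",
            _as_array(self.mode_frequencies, (e.shape[0],), "mode_frequencies"),
        )

    @property
    def n_modes(self) -> int:
        return self.electric.shape[0]


@dataclass(frozen=True)
class ModeStrengths:
    """Per-mode rotational and dipole strengths.

    Values are internal atomic units; use :meth:`rotational_cgs` /
    :meth:`dipole_cgs` for the conventional 10^-44 / 10^-40 esu^2 cm^2 scales.
    ``components`` is an optional labelled additive breakdown of
    ``rotational`` (e.g. ``{"mfp": ..., "enhancement": ...}``).
    """

    rotational: np.ndarray
    dipole: np.ndarray
    mode_frequencies: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        r = _as_array(self.rotational, name="rotational")
        object.__setattr__(self, "rotational", r)
        d = _as_array(self.dipole, r.shape, "dipole")
        if np.any(d < -1e-300):
            raise ValueError("dipole strengths must be non-negative")
        object.__setattr__(self, "dipole", d)
        object.__setattr__(
            self,
            "mode_frequencies",
            _as_array(self.mode_frequencies, r.shape, "mode_frequencies"),
        )
        comps = {k: _as_array(v, r.shape, k) for k, v in self.components.items()}
        object.__setattr__(self, "components", comps)
        if comps:
            total = sum(comps.values())
            scale = max(float(np.max(np.abs(r))), 1e-300)
            if np.max(np.abs(total - r)) > 1e-10 * scale:
                raise ValueError("labelled components do not sum to the total")

    @property
    def n_modes(self) -> int:
        return self.rotational.shape[0]

    def rotational_cgs(self) -> np.ndarray:
        """Rotational strengths in 10^-44 esu^2 cm^2."""
        return self.rotational * R_AU_TO_CGS44

    def dipole_cgs(self) -> np.ndarray:
        """Dipole strengths in 10^-40 esu^2 cm^2."""
        return self.dipole * D_AU_TO_CGS40


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def nuclear_apt(system: MolecularSystem) -> np.ndarray:
    """Nuclear APT blocks, ``N_ab^l = e Z_l delta_ab`` (a.u., e = 1)."""
    eye = np.eye(3)
    return system.charges[:, None, None] * eye[None, :, :]


def nuclear_aat(system: MolecularSystem) -> np.ndarray:
    """Nuclear AAT blocks (imaginary part, stored real).

    ``J_ab^l = (Z_l / 4c) sum_g eps_abg R0_lg`` with coordinates relative to
    the declared gauge origin; each block is exactly antisymmetric.
    """
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
    eps[0, 2, 1] = eps[2, 1, 0] = eps[1, 0, 2] = -1.0
    pref = system.charges / (4.0 * SPEED_OF_LIGHT_AU)
    blocks = np.einsum("abg,lg->lab", eps, system.coordinates)
    return pref[:, None, None] * blocks


def mode_moments(tensors: AtomicTensorSet, modes: NormalModes) -> ModeMoments:
    """Contract total APT/AAT with the S matrix into per-mode moment vectors."""
    if tensors.n_atoms != modes.n_atoms:
        raise ValueError(
            f"tensor set has {tensors.n_atoms} atoms but s_matrix implies "
            f"{modes.n_atoms}"
        )
    omega = modes.omega_au
    # reshape blocks (atom, alpha, beta) -> (la, beta), la atom-major x/y/z
    p = tensors.apt.reshape(3 * tensors.n_atoms, 3)
    a = tensors.aat.reshape(3 * tensors.n_atoms, 3)
    contr_p = modes.s_matrix.T @ p          # (n_modes, 3)
    contr_a = modes.s_matrix.T @ a
    electric = np.sqrt(1.0 / (2.0 * omega))[:, None] * contr_p
    magnetic = -np.sqrt(2.0 * omega)[:, None] * contr_a
    return ModeMoments(
        electric=electric, magnetic=magnetic, mode_frequencies=modes.frequencies
    )


def rotational_strength(moments: ModeMoments) -> ModeStrengths:
    """MFP rotational and dipole strengths from the mode moments.

    ``R_i = Im[E_i . M_i]`` — with the imaginary-part storage convention this
    is the real dot product of ``electric`` with ``magnetic``. The dipole
    strength is the standard ``D_i = |E_i|^2``.
    """
    r = np.einsum("ib,ib->i", moments.electric, moments.magnetic)
    d = np.einsum("ib,ib->i", moments.electric, moments.electric)
    return ModeStrengths(
        rotational=r, dipole=d, mode_frequencies=moments.mode_frequencies
    )
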
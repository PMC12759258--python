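"""Synthetic, physically consistent VCD bundles with known ground truth.

The generator emulates the data regime of an open-shell transition-metal
complex with a chiral ligand cage: one metal centre with a few directly
bonded ligand atoms carrying all the non-adiabatic coupling (the locality of
the enhancement), d-d-like excited states a few tenths of an eV up with
magnetic-dipole-allowed but (optionally) electric-dipole-forbidden character,
and fingerprint-region normal modes. Magnitudes are drawn at physically
motivated scales:

* electronic APT blocks ``-Z 1 + N(0, 0.3 e)`` — screened effective charges;
* electronic AAT blocks ``N(0, 0.05)`` — comparable to the nuclear AAT of
  second-row ligand atoms a few bohr from the origin;
* MDTM components ``N(0, 8e-3)`` in the 1/c-absorbed a.u. (vector norms of a
  few Bohr magnetons, typical of spin-allowed d-d transitions);
* NAC components ``N(0, 0.5)`` bohr^-1, nonzero only on the masked atoms —
  strong derivative coupling, as expected for states a few tenths of an eV
  above the ground state.

With these scales the vibronic correction at the default state energies is
comparable to the baseline MFP signal, i.e. the band intensities change
visibly once the states are included — the regime in which enhanced VCD is
actually observed for open-shell complexes.

Everything is seeded; the same spec always yields bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AMU_TO_ME, BOHR_TO_ANGSTROM, HARTREE_TO_EV
from .core import (
    AtomicTensorSet,
    MolecularSystem,
    NormalModes,
    nuclear_aat,
    nuclear_apt,
)
from .enhancement import ExcitedState
from .io import VcdBundle
from .spectra import DEFAULT_WINDOW_CM, Spectrum
from .workflow import model_spectrum

__all__ = [
    "FixtureSpec",
    "DEFAULT_SCALES",
    "make_bundle",
    "mirror_bundle",
    "make_reference",
    "demo_spec",
]

_ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "Cl": (17, 35.45),
    "Co": (27, 58.933),
    "Ni": (28, 58.693),
    "Zn": (30, 65.38),
}

#: physically motivated magnitude scales (see module docstring)
DEFAULT_SCALES = {
    "apt": 0.3,     # e, spread of effective-charge deviations
    "aat": 0.05,    # 1/c-absorbed a.u.
    "edtm": 0.0,    # e*a0; 0 emulates Laporte-forbidden d-d states
    "mdtm": 8e-3,   # 1/c-absorbed a.u. (a few Bohr magnetons per vector)
    "nac": 0.5,     # bohr^-1 per component, masked atoms only
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic bundle; the seed fixes all randomness."""

    n_atoms: int = 12
    n_modes: int = 12
    n_states: int = 2
    freq_range: tuple[float, float] = (950.0, 1650.0)
    state_energies: tuple[float, ...] | None = None   # planted, eV
    nac_mask: tuple[int, ...] | None = None           # atoms carrying NAC
    magnitude_scales: dict = field(default_factory=dict)
    noise_level: float = 0.0
    seed: int = 0

    def resolved_scales(self) -> dict:
        scales = dict(DEFAULT_SCALES)
        scales.update(self.magnitude_scales)
        return scales

    def resolved_mask(self) -> tuple[int, ...]:
        if self.nac_mask is not None:
            mask = tuple(self.nac_mask)
            if any(i < 0 or i >= self.n_atoms for i in mask):
                raise ValueError("nac_mask must index atoms of the cluster")
            return mask
        return tuple(range(min(5, self.n_atoms)))

    def resolved_energies(self) -> tuple[float, ...]:
        if self.state_energies is not None:
            if len(self.state_energies) != self.n_states:
                raise ValueError("state_energies length must equal n_states")
            return tuple(float(e) for e in self.state_energies)
        # spread above the fingerprint band, in the regime where the
        # resonance factor is significant but finite
        return tuple(0.25 + 0.11 * k for k in range(self.n_states))


def demo_spec(seed: int = 7) -> FixtureSpec:
    """The shipped demonstration fixture, emulating a sparteine-like complex.

    A ~30-atom cluster with a 5-atom coupling mask (metal + two N + two Cl),
    three d-d-like states at (0.23, 0.23, 0.42) eV with zero EDTMs — magnetic
    channel dominant, two nearly degenerate states in the resonance window and
    an inert third state.
    """
    return FixtureSpec(
        n_atoms=30,
        n_modes=30,
        n_states=3,
        state_energies=(0.23, 0.23, 0.42),
        nac_mask=(0, 1, 2, 3, 4),
        seed=seed,
    )


def _composition(n_atoms: int) -> list[str]:
    symbols = ["Co", "N", "N", "Cl", "Cl"]
    fillers = ["C", "H"]
    for k in range(max(0, n_atoms - 5)):
        symbols.append(fillers[k % 2])
    return symbols[:n_atoms]


def make_bundle(spec: FixtureSpec) -> VcdBundle:
    """Generate a physically consistent bundle from a fixture spec.

    Normal modes are exactly orthonormal under mass weighting by
    construction; nuclear APT/AAT blocks are computed (not drawn); NACs are
    nonzero only on the masked atoms.
    """
    if spec.n_modes > 3 * spec.n_atoms:
        raise ValueError(
            f"{spec.n_modes} modes infeasible for {spec.n_atoms} atoms (> 3N)"
        )
    rng = np.random.default_rng(spec.seed)
    scales = spec.resolved_scales()
    mask = spec.resolved_mask()

    symbols = _composition(spec.n_atoms)
    charges = np.array([_ELEMENTS[s][0] for s in symbols], dtype=float)
    masses = np.array([_ELEMENTS[s][1] for s in symbols], dtype=float)

    # compact cluster (angstrom): metal at the origin, ligand shell around it
    coords_ang = np.zeros((spec.n_atoms, 3))
    if spec.n_atoms > 1:
        directions = rng.normal(size=(spec.n_atoms - 1, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = np.concatenate([
            rng.uniform(2.0, 2.4, size=min(4, spec.n_atoms - 1)),
            rng.uniform(2.5, 4.5, size=max(0, spec.n_atoms - 5)),
        ])
        coords_ang[1:] = directions * radii[:, None]
    system = MolecularSystem(
        atom_symbols=tuple(symbols),
        charges=charges,
        masses=masses,
        coordinates=coords_ang / BOHR_TO_ANGSTROM,
        origin_note="synthetic cluster; gauge origin at the metal atom",
    )

    # exactly mass-weighted-orthonormal modes: S = M^(-1/2) U, U orthonormal
    n3 = 3 * spec.n_atoms
    raw = rng.normal(size=(n3, n3))
    u, r = np.linalg.qr(raw)
    u = u * np.sign(np.diag(r))        # deterministic sign convention
    m_sqrt = np.sqrt(np.repeat(masses * AMU_TO_ME, 3))
    s_matrix = u[:, : spec.n_modes] / m_sqrt[:, None]
    frequencies = np.sort(rng.uniform(*spec.freq_range, size=spec.n_modes))
    modes = NormalModes(s_matrix=s_matrix, frequencies=frequencies)

    apt_el = -charges[:, None, None] * np.eye(3)[None] + rng.normal(
        0.0, scales["apt"], size=(spec.n_atoms, 3, 3)
    )
    aat_el = rng.normal(0.0, scales["aat"], size=(spec.n_atoms, 3, 3))
    tensors = AtomicTensorSet(
        apt_electronic=apt_el,
        apt_nuclear=nuclear_apt(system),
        aat_electronic=aat_el,
        aat_nuclear=nuclear_aat(system),
    )

    states = []
    for k, e_ev in enumerate(spec.resolved_energies()):
        nac = np.zeros((spec.n_atoms, 3))
        if mask:
            nac[list(mask)] = rng.normal(0.0, scales["nac"], size=(len(mask), 3))
        edtm = (
            rng.normal(0.0, scales["edtm"], size=3)
            if scales["edtm"] > 0
            else np.zeros(3)
        )
        states.append(
            ExcitedState(
                label=f"S{k + 1}",
                energy=e_ev / HARTREE_TO_EV,
                edtm=edtm,
                mdtm=rng.normal(0.0, scales["mdtm"], size=3),
                nac_cartesian=nac.ravel(),
            )
        )

    return VcdBundle(
        system=system,
        modes=modes,
        tensors=tensors,
        states=tuple(states),
        meta={
            "method": "synthetic",
            "origin_note": system.origin_note,
            "fixture_seed": spec.seed,
        },
    )


def mirror_bundle(bundle: VcdBundle) -> VcdBundle:
    """The enantiomer's bundle: all axial quantities sign-flipped.

    Negating every AAT block (electronic and nuclear) and every MDTM is the
    algebraic image of reflecting the geometry: axial vectors and magnetic
    moments are pseudovectors and change sign under improper rotation while
    polar quantities (APT, EDTM, NAC contractions) do not. This guarantees
    R -> -R downstream exactly. An involution: mirroring twice restores the
    original bundle.
    """
    tensors = AtomicTensorSet(
        apt_electronic=bundle.tensors.apt_electronic,
        apt_nuclear=bundle.tensors.apt_nuclear,
        aat_electronic=-bundle.tensors.aat_electronic,
        aat_nuclear=-bundle.tensors.aat_nuclear,
    )
    states = tuple(replace(s, mdtm=-s.mdtm) for s in bundle.states)
    meta = dict(bundle.meta)
    meta["mirrored"] = not meta.get("mirrored", False)
    return VcdBundle(
        system=bundle.system,
        modes=bundle.modes,
        tensors=tensors,
        states=states,
        meta=meta,
    )


def make_reference(
    bundle: VcdBundle,
    true_energies,
    noise_level: float = 0.0,
    seed: int = 0,
    halfwidth: float = 6.0,
    grid=None,
    noise_window: tuple[float, float] = DEFAULT_WINDOW_CM,
) -> Spectrum:
    """Reference VCD spectrum at planted excitation energies plus noise.

    Stands in for a digitized experimental spectrum. Gaussian noise is added
    with standard deviation ``noise_level`` times the maximum |signal| inside
    ``noise_window`` (the fingerprint region being scored) — the way
    experimental signal-to-noise is quoted — falling back to the global
    maximum if the window misses the grid. The planted truth is recorded in
    ``meta`` for recovery scoring.
    """
    spec = model_spectrum(
        bundle, mode="enhanced", energies_ev=true_energies,
        halfwidth=halfwidth, grid=grid, kind="vcd",
    )
    values = spec.values
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        sel = (spec.grid >= noise_window[0]) & (spec.grid <= noise_window[1])
        ref_scale = float(
            np.max(np.abs(values[sel])) if np.any(sel) else np.max(np.abs(values))
        )
        sigma = noise_level * ref_scale
        values = values + rng.normal(0.0, sigma, size=values.shape)
    meta = dict(spec.meta)
    meta.update(
        {
            "planted_energies_ev": [float(e) for e in np.atleast_1d(true_energies)],
            "noise_level": noise_level,
            "noise_seed": seed,
            "source": "synthetic reference",
        }
    )
    return Spectrum(grid=spec.grid, values=values, kind="vcd", meta=meta)
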
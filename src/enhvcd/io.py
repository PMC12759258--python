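"""Versioned JSON interchange format for VCD bundles.

A *bundle* collects every quantum-chemistry-derived quantity the enhanced-VCD
pipeline needs for one molecule: nuclear frame, normal modes, APT/AAT blocks
and the excited-state data (energy, EDTM, MDTM, Cartesian NAC) for each
low-lying state. JSON is used for inspectability at the relevant scale
(hundreds of atoms, tens of states); arrays are row-major, atom-major with
x/y/z fastest.

Unit declarations are explicit — there are no silent defaults. The loader
accepts coordinates in angstrom or bohr and energies in eV, cm-1 or hartree,
converting to atomic units internally; the saver writes atomic units (bohr /
hartree), declared as such, so that a save/load round trip is exact to the
last bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import BOHR_TO_ANGSTROM, HARTREE_TO_CM, HARTREE_TO_EV
from .core import AtomicTensorSet, MolecularSystem, NormalModes
from .enhancement import ExcitedState

__all__ = ["VcdBundle", "BundleFormatError", "load_bundle", "save_bundle"]

SCHEMA_VERSION = 1

_KNOWN_TOP = {"schema_version", "meta", "units", "system", "modes", "tensors", "states"}

_LENGTH_TO_BOHR = {"bohr": 1.0, "angstrom": 1.0 / BOHR_TO_ANGSTROM}
_ENERGY_TO_HARTREE = {
    "hartree": 1.0,
    "ev": 1.0 / HARTREE_TO_EV,
    "cm-1": 1.0 / HARTREE_TO_CM,
}


class BundleFormatError(ValueError):
    """A bundle file failed validation; the message carries a JSON-pointer path."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


@dataclass(frozen=True)
class VcdBundle:
    """A molecule's complete input set for enhanced-VCD calculations."""

    system: MolecularSystem
    modes: NormalModes
    tensors: AtomicTensorSet
    states: tuple[ExcitedState, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        n = self.system.n_atoms
        if self.modes.n_atoms != n:
            raise BundleFormatError(
                "/modes/s_matrix",
                f"implies {self.modes.n_atoms} atoms, system has {n}",
            )
        if self.tensors.n_atoms != n:
            raise BundleFormatError(
                "/tensors", f"has {self.tensors.n_atoms} atom blocks, system has {n}"
            )
        for k, s in enumerate(self.states):
            if s.nac_cartesian.size != 3 * n:
                raise BundleFormatError(
                    f"/states/{k}/nac",
                    f"state '{s.label}' NAC length {s.nac_cartesian.size}, "
                    f"expected {3 * n}",
                )

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms


def _get(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise BundleFormatError(f"{pointer}/{key}", "missing required field")
    return obj[key]


def _num_array(raw, pointer: str) -> np.ndarray:
    try:
        a = np.asarray(raw, dtype=float)
    except (TypeError, ValueError):
        raise BundleFormatError(pointer, "not a numeric array") from None
    if not np.all(np.isfinite(a)):
        raise BundleFormatError(pointer, "contains non-finite numbers")
    return a


def load_bundle(path) -> VcdBundle:
    """Load and fully validate a bundle file, converting to atomic units."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)

    version = _get(raw, "schema_version", "")
    if version != SCHEMA_VERSION:
        raise BundleFormatError("/schema_version", f"unknown version {version!r}")

    units = _get(raw, "units", "")
    length_unit = str(_get(units, "coordinates", "/units")).lower()
    energy_unit = str(_get(units, "energies", "/units")).lower()
    if length_unit not in _LENGTH_TO_BOHR:
        raise BundleFormatError("/units/coordinates", f"unknown unit {length_unit!r}")
    if energy_unit not in _ENERGY_TO_HARTREE:
        raise BundleFormatError("/units/energies", f"unknown unit {energy_unit!r}")
    to_bohr = _LENGTH_TO_BOHR[length_unit]
    to_hartree = _ENERGY_TO_HARTREE[energy_unit]

    sys_raw = _get(raw, "system", "")
    try:
        system = MolecularSystem(
            atom_symbols=tuple(_get(sys_raw, "atom_symbols", "/system")),
            charges=_num_array(_get(sys_raw, "charges", "/system"), "/system/charges"),
            masses=_num_array(_get(sys_raw, "masses", "/system"), "/system/masses"),
            coordinates=_num_array(
                _get(sys_raw, "coordinates", "/system"), "/system/coordinates"
            )
            * to_bohr,
            origin_note=str(sys_raw.get("origin_note", "unspecified")),
        )
    except ValueError as exc:
        raise BundleFormatError("/system", str(exc)) from None

    modes_raw = _get(raw, "modes", "")
    try:
        modes = NormalModes(
            s_matrix=_num_array(
                _get(modes_raw, "s_matrix", "/modes"), "/modes/s_matrix"
            ),
            frequencies=_num_array(
                _get(modes_raw, "frequencies", "/modes"), "/modes/frequencies"
            ),
            scale_factor=float(modes_raw.get("scale_factor", 1.0)),
        )
    except ValueError as exc:
        raise BundleFormatError("/modes", str(exc)) from None

    t_raw = _get(raw, "tensors", "")
    try:
        tensors = AtomicTensorSet(
            apt_electronic=_num_array(
                _get(t_raw, "apt_electronic", "/tensors"), "/tensors/apt_electronic"
            ),
            apt_nuclear=_num_array(
                _get(t_raw, "apt_nuclear", "/tensors"), "/tensors/apt_nuclear"
            ),
            aat_electronic=_num_array(
                _get(t_raw, "aat_electronic", "/tensors"), "/tensors/aat_electronic"
            ),
            aat_nuclear=_num_array(
                _get(t_raw, "aat_nuclear", "/tensors"), "/tensors/aat_nuclear"
            ),
        )
    except ValueError as exc:
        raise BundleFormatError("/tensors", str(exc)) from None

    states = []
    for k, s_raw in enumerate(_get(raw, "states", "")):
        ptr = f"/states/{k}"
        try:
            states.append(
                ExcitedState(
                    label=str(s_raw.get("label", f"state-{k}")),
                    energy=float(_get(s_raw, "energy", ptr)) * to_hartree,
                    edtm=_num_array(_get(s_raw, "edtm", ptr), f"{ptr}/edtm"),
                    mdtm=_num_array(_get(s_raw, "mdtm_im", ptr), f"{ptr}/mdtm_im"),
                    nac_cartesian=_num_array(_get(s_raw, "nac", ptr), f"{ptr}/nac"),
                )
            )
        except ValueError as exc:
            raise BundleFormatError(ptr, str(exc)) from None

    meta = dict(raw.get("meta", {}))
    extras = {k: raw[k] for k in raw if k not in _KNOWN_TOP}
    if extras:
        meta.setdefault("extras", {}).update(extras)

    bundle = VcdBundle(
        system=system, modes=modes, tensors=tensors, states=tuple(states), meta=meta
    )
    # warn (not error) on oddly-normalised imported modes
    bundle.modes.validate_orthonormality(bundle.system)
    return bundle


def save_bundle(bundle: VcdBundle, path) -> None:
    """Write a bundle as schema-v1 JSON in atomic units (exact round trip).

    Keys are emitted in a stable order for diff-friendliness; unknown fields
    previously collected under ``meta["extras"]`` are preserved verbatim.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "meta": dict(bundle.meta),
        "units": {
            "coordinates": "bohr",
            "energies": "hartree",
            "frequencies": "cm-1",
            "tensors": "au",
            "nac": "au",
        },
        "system": {
            "atom_symbols": list(bundle.system.atom_symbols),
            "charges": bundle.system.charges.tolist(),
            "masses": bundle.system.masses.tolist(),
            "coordinates": bundle.system.coordinates.tolist(),
            "origin_note": bundle.system.origin_note,
        },
        "modes": {
            "s_matrix": bundle.modes.s_matrix.tolist(),
            "frequencies": bundle.modes.frequencies.tolist(),
            "scale_factor": bundle.modes.scale_factor,
        },
        "tensors": {
            "apt_electronic": bundle.tensors.apt_electronic.tolist(),
            "apt_nuclear": bundle.tensors.apt_nuclear.tolist(),
            "aat_electronic": bundle.tensors.aat_electronic.tolist(),
            "aat_nuclear": bundle.tensors.aat_nuclear.tolist(),
        },
        "states": [
            {
                "label": s.label,
                "energy": s.energy,
                "edtm": s.edtm.tolist(),
                "mdtm_im": s.mdtm.tolist(),
                "nac": s.nac_cartesian.tolist(),
            }
            for s in bundle.states
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
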
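# VCD bundle JSON, schema v1

A bundle is one molecule's complete input set for enhanced-VCD
calculations. It is plain JSON (UTF-8), small enough to inspect and diff at
the relevant problem scale (hundreds of atoms, tens of states). A machine-
readable JSON Schema lives next to this file (`bundle_schema.json`);
`enhvcd validate <file>` checks a bundle and reports failures with
JSON-pointer paths.

## Layout

```json
{
 "schema_version": 1,
 "meta": {
   "method": "upstream method label, e.g. a CASSCF active space or functional",
   "origin_note": "gauge / coordinate origin used upstream",
   "extras": { "anything unknown is preserved here verbatim" }
 },
 "units": {
   "coordinates": "angstrom | bohr",
   "energies":    "eV | cm-1 | hartree",
   "frequencies": "cm-1",
   "tensors":     "au",
   "nac":         "au"
 },
 "system": {
   "atom_symbols": ["Co", "N", "..."],
   "charges":      [27, 7, ...],
   "masses":       [58.933, 14.007, ...],
   "coordinates":  [[x, y, z], ...],
   "origin_note":  "same convention as meta.origin_note"
 },
 "modes": {
   "s_matrix":    [[...], ...],
   "frequencies": [1000.0, ...],
   "scale_factor": 1.0
 },
 "tensors": {
   "apt_electronic": [[[3x3]], ...],
   "apt_nuclear":    [[[3x3]], ...],
   "aat_electronic": [[[3x3]], ...],
   "aat_nuclear":    [[[3x3]], ...]
 },
 "states": [
   {
     "label":  "S1",
     "energy": 0.23,
     "edtm":   [x, y, z],
     "mdtm_im": [x, y, z],
     "nac":    [3N numbers]
   }
 ]
}
```

## Conventions

* **Index order.** Everything Cartesian is atom-major with x/y/z fastest:
  the `s_matrix` has `3*n_atoms` rows (atom 0 x, atom 0 y, atom 0 z,
  atom 1 x, ...) and one column per mode; each `nac` vector is flat in the
  same order. Tensor blocks are `[atom][alpha][beta]` with `alpha` the
  nuclear-displacement and `beta` the field component.
* **Units are declared, never defaulted.** The loader converts coordinates
  to bohr and energies to hartree internally. `save_bundle` writes atomic
  units (declared as `bohr` / `hartree`) so a round trip is bit-exact.
* **Imaginary parts stored real.** AAT blocks and `mdtm_im` (the MDTM
  `<e|m|g>`) are purely imaginary for real ground-state wavefunctions and
  are stored as their real-valued imaginary parts, in units where the 1/c of
  the magnetic dipole operator is absorbed into the number.
* **S-matrix normalisation.** Columns should be orthonormal under mass
  weighting in atomic units (masses in electron masses). Deviations are
  warned about (tolerance 1e-6), not repaired.
* **Gauge origin.** AATs and MDTMs depend on the coordinate origin. The
  `origin_note` travels with the bundle; the package never re-origins data,
  and mixing bundles with different origin notes is a user error.
* **Validation.** Cross-field dimension consistency is enforced: atom count
  across symbols/charges/masses/coordinates/tensor blocks, `3N` rows in the
  S-matrix and in every NAC, one frequency per mode, finite numbers
  everywhere, positive excitation energies, antisymmetric nuclear AATs.
* **Forward compatibility.** Unknown top-level fields are preserved under
  `meta.extras` and written back on save.

Program-specific quantum-chemistry output parsing is deliberately out of
scope: convert your program's output to this intermediate representation
with your own script.
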
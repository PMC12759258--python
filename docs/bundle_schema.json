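{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "VCD bundle, schema v1",
 "type": "object",
 "required": ["schema_version", "units", "system", "modes", "tensors", "states"],
 "properties": {
  "schema_version": {"const": 1},
  "meta": {
   "type": "object",
   "properties": {
    "method": {"type": "string"},
    "origin_note": {"type": "string"},
    "extras": {"type": "object"}
   }
  },
  "units": {
   "type": "object",
   "required": ["coordinates", "energies"],
   "properties": {
    "coordinates": {"enum": ["angstrom", "bohr"]},
    "energies": {"enum": ["eV", "cm-1", "hartree"]},
    "frequencies": {"const": "cm-1"},
    "tensors": {"const": "au"},
    "nac": {"const": "au"}
   }
  },
  "system": {
   "type": "object",
   "required": ["atom_symbols", "charges", "masses", "coordinates"],
   "properties": {
    "atom_symbols": {"type": "array", "items": {"type": "string"}},
    "charges": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}},
    "masses": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}},
    "coordinates": {
     "type": "array",
     "items": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3}
    },
    "origin_note": {"type": "string"}
   }
  },
  "modes": {
   "type": "object",
   "required": ["s_matrix", "frequencies"],
   "properties": {
    "s_matrix": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}},
    "frequencies": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}},
    "scale_factor": {"type": "number", "exclusiveMinimum": 0.5, "exclusiveMaximum": 1.5}
   }
  },
  "tensors": {
   "type": "object",
   "required": ["apt_electronic", "apt_nuclear", "aat_electronic", "aat_nuclear"],
   "additionalProperties": {
    "type": "array",
    "items": {
     "type": "array",
     "items": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
     "minItems": 3,
     "maxItems": 3
    }
   }
  },
  "states": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["energy", "edtm", "mdtm_im", "nac"],
    "properties": {
     "label": {"type": "string"},
     "energy": {"type": "number", "exclusiveMinimum": 0},
     "edtm": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
     "mdtm_im": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
     "nac": {"type": "array", "items": {"type": "number"}}
    }
   }
  }
 }
}
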
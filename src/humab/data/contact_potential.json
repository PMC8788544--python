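{
  "comment": "Coarse 3-class residue-contact potential (lower = more favourable contact). Classes: H hydrophobic, P polar, C charged. Used by the default contact-based mutation scorer; a transparent, hand-verifiable stand-in for forcefield mutation energies.",
  "classes": {
    "H": "AVLIMFWC",
    "P": "GSTNQYPH",
    "C": "DEKR"
  },
  "pair_potential": {
    "HH": -1.0,
    "HP": 0.3,
    "HC": 0.6,
    "PP": -0.2,
    "PC": 0.0,
    "CC": 0.5
  },
  "cb_contact_cutoff_angstrom": 8.0,
  "min_neighbors_for_scoring": 3
}
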
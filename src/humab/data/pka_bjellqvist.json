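{
  "comment": "Bjellqvist pKa set as used by the Expasy ProtParam pI calculation; N-terminal pKa depends on the first residue.",
  "n_terminus": {
    "A": 7.59,
    "E": 7.70,
    "G": 7.50,
    "M": 7.00,
    "P": 8.36,
    "S": 6.93,
    "T": 6.82,
    "V": 7.44,
    "default": 7.50
  },
  "c_terminus": 3.55,
  "positive_side_chains": {
    "H": 5.98,
    "K": 10.00,
    "R": 12.00
  },
  "negative_side_chains": {
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00
  }
}
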
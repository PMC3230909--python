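{
  "comment": "Additive reversed-phase retention coefficients (minutes per residue occurrence) with a gradient intercept. Defaults follow the classical C18/pH-2 coefficient set of Guo, Mant & Hodges; refit intercept and coefficients to your own gradient before trusting absolute times.",
  "intercept": 0.0,
  "coefficients": {
    "W": 8.8,
    "F": 8.1,
    "L": 8.1,
    "I": 7.4,
    "M": 5.5,
    "V": 5.0,
    "Y": 4.5,
    "C": 2.6,
    "P": 2.0,
    "A": 2.0,
    "E": 1.1,
    "T": 0.6,
    "D": 0.2,
    "Q": 0.0,
    "S": -0.2,
    "G": -0.2,
    "R": -0.6,
    "N": -0.6,
    "H": -2.1,
    "K": -2.1
  }
}
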
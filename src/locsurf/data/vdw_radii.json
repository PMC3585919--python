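{
  "version": 1,
  "comment": "Bondi-style van der Waals radii in Angstrom, keyed by element symbol",
  "radii": {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.0, "ZN": 1.39, "CA": 2.31, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "MN": 2.0, "CU": 1.4, "NI": 1.63, "CO": 2.0, "SE": 1.9, "B": 1.92
  },
  "default": 1.7
}
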
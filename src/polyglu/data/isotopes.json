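{
  "comment": "Pinned monoisotopic masses (Da) and natural abundances (CODATA/IUPAC). Each element lists [mass, abundance] per isotope, most abundant first; the first entry is the principal (monoisotopic) isotope.",
  "electron": 0.000548579909,
  "proton": 1.007276466879,
  "elements": {
    "H":  [[1.0078250319, 0.999885], [2.0141017779, 0.000115]],
    "C":  [[12.0, 0.9893], [13.0033548378, 0.0107]],
    "N":  [[14.0030740052, 0.99636], [15.0001088984, 0.00364]],
    "O":  [[15.9949146221, 0.99757], [16.9991315, 0.00038], [17.9991604, 0.00205]],
    "S":  [[31.97207069, 0.9499], [32.9714585, 0.0075], [33.96786683, 0.0425], [35.96708088, 0.0001]],
    "Na": [[22.98976928, 1.0]]
  },
  "heavy": {
    "2H": 2.0141017779,
    "13C": 13.0033548378,
    "18O": 17.9991604
  }
}
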
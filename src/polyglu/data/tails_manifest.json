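{
  "comment": "C-terminal tail fixtures for tubulin isoforms. last_residue is the full-length residue number of the final tail residue in the mature isoform; numbering_offset = last_residue - len(sequence), so tail position i (1-based) maps to full-length residue i + numbering_offset.",
  "tails": {
    "TUBA1A": {"accession": "Q71U36", "chain_class": "alpha", "last_residue": 451},
    "TUBA1B": {"accession": "P68363", "chain_class": "alpha", "last_residue": 451},
    "TUBB5":  {"accession": "P07437", "chain_class": "beta",  "last_residue": 444},
    "TUBB4B": {"accession": "P68371", "chain_class": "beta",  "last_residue": 445},
    "TUBB2A": {"accession": "Q13885", "chain_class": "beta",  "last_residue": 445},
    "TUBB2B": {"accession": "Q9BVA1", "chain_class": "beta",  "last_residue": 445}
  }
}
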
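{
  "version": "1.0",
  "comment": "Residue-level atom inventories for SLD/contrast calculations. Protein entries are amino-acid residues (free amino acid minus one water, neutral protonation); DNA entries are deoxynucleotide-monophosphate residues in a phosphodiester chain (nucleoside 5'-monophosphate minus one water, phosphate un-protonated). 'labile_h' counts N-H, O-H and S-H hydrogens able to exchange with solvent; it is included in 'atoms.H'.",
  "protein": {
    "G": {"atoms": {"C": 2, "H": 3, "N": 1, "O": 1}, "labile_h": 1},
    "A": {"atoms": {"C": 3, "H": 5, "N": 1, "O": 1}, "labile_h": 1},
    "S": {"atoms": {"C": 3, "H": 5, "N": 1, "O": 2}, "labile_h": 2},
    "P": {"atoms": {"C": 5, "H": 7, "N": 1, "O": 1}, "labile_h": 0},
    "V": {"atoms": {"C": 5, "H": 9, "N": 1, "O": 1}, "labile_h": 1},
    "T": {"atoms": {"C": 4, "H": 7, "N": 1, "O": 2}, "labile_h": 2},
    "C": {"atoms": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}, "labile_h": 2},
    "L": {"atoms": {"C": 6, "H": 11, "N": 1, "O": 1}, "labile_h": 1},
    "I": {"atoms": {"C": 6, "H": 11, "N": 1, "O": 1}, "labile_h": 1},
    "N": {"atoms": {"C": 4, "H": 6, "N": 2, "O": 2}, "labile_h": 3},
    "D": {"atoms": {"C": 4, "H": 5, "N": 1, "O": 3}, "labile_h": 2},
    "Q": {"atoms": {"C": 5, "H": 8, "N": 2, "O": 2}, "labile_h": 3},
    "K": {"atoms": {"C": 6, "H": 12, "N": 2, "O": 1}, "labile_h": 3},
    "E": {"atoms": {"C": 5, "H": 7, "N": 1, "O": 3}, "labile_h": 2},
    "M": {"atoms": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}, "labile_h": 1},
    "H": {"atoms": {"C": 6, "H": 7, "N": 3, "O": 1}, "labile_h": 2},
    "F": {"atoms": {"C": 9, "H": 9, "N": 1, "O": 1}, "labile_h": 1},
    "R": {"atoms": {"C": 6, "H": 12, "N": 4, "O": 1}, "labile_h": 5},
    "Y": {"atoms": {"C": 9, "H": 9, "N": 1, "O": 2}, "labile_h": 2},
    "W": {"atoms": {"C": 11, "H": 10, "N": 2, "O": 1}, "labile_h": 2}
  },
  "dna": {
    "A": {"atoms": {"C": 10, "H": 12, "N": 5, "O": 5, "P": 1}, "labile_h": 2},
    "G": {"atoms": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}, "labile_h": 3},
    "C": {"atoms": {"C": 9, "H": 12, "N": 3, "O": 6, "P": 1}, "labile_h": 2},
    "T": {"atoms": {"C": 10, "H": 13, "N": 2, "O": 7, "P": 1}, "labile_h": 1}
  }
}
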
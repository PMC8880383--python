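{
  "note": "Approximate loop annotation of the 132-residue Qbeta coat-protein fold, used as defaults for loop-displacement measurements; residue ranges are 1-based inclusive and should be overridden per structure when exact boundaries are known.",
  "n_residues": 132,
  "loops": {
    "CD": [48, 57],
    "DE": [62, 69],
    "FG": [76, 86]
  },
  "c_terminus": 132
}
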
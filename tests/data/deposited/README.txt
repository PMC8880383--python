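Deposited-model inputs (not redistributable with the package)
=============================================================

The two deposited-model tests in tests/test_acceptance.py expect the
following files in this directory:

  7lhd.cif                        complete Qbeta virion (PDB 7LHD)
  7lhd_secondary_structure.dbn    genome secondary structure (dot-bracket)
  7lhd_entities.json              EntityConfig: RNA chain, CP dimer chain
                                  pairs with A/B / C/C / internal classes,
                                  Mat chain, genome offset
  7lge.cif  7lgf.cif  7lgg.cif  7lgh.cif
                                  T=4, prolate, oblate and small-prolate VLPs

Obtain the coordinate files from the PDB (https://www.rcsb.org) under the
accession codes above.  Without them the corresponding tests fail with a
message pointing here; everything else in the suite runs on synthetic
fixtures generated at test time.
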
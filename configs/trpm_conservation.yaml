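# Conservation pipeline over the deposited TRPM-family structures.
#
# Coordinate files are NOT shipped with the package; place the mmCIF files
# under data/structures/ (scripts/fetch_structures.py downloads them from
# the PDB when network access is available).
#
# Residue ranges below are this package's documented choices for the
# reference channel (mouse TRPM8, 7wre author numbering):
#   - pre-S1 through the TRP box (the alignment region)
#   - S1-S4 peripheral bundle
#   - S1-S6 transmembrane core (for the region-contrast comparison)
# All are configurable here.

reference:
  id: 7wre            # mouse TRPM8 with cooling agent + Ca2+
  path: data/structures/7wre.cif
  chain: A
  region: [692, 1013]         # pre-S1 -> TRP box
  # the cooling-agent ligand is matched by heavy-atom formula (C16 N3 O4)
  # rather than by chemical component ID
  ligand_formula: {C: 16, N: 3, O: 4}
  ion: CA

# second accepted ligand pose: avian TRPM8 (A805G background) deposition
pose_structures:
  - id: 6nr3
    path: data/structures/6nr3.cif
    chain: A

targets:
  - {id: 7mbq, path: data/structures/7mbq.cif, chain: A}   # zebrafish TRPM5
  - {id: 6bqv, path: data/structures/6bqv.cif, chain: A}   # human TRPM4
  - {id: 6co7, path: data/structures/6co7.cif, chain: A}   # N. vectensis TRPM2
  - {id: 8ddr, path: data/structures/8ddr.cif, chain: A}   # mouse TRPM3
  # distant-subfamily comparisons; accessions are this package's documented
  # choices (highest-resolution full-length depositions)
  - {id: trpa1, path: data/structures/6v9w.cif, chain: A}
  - {id: trpv3, path: data/structures/6ot5.cif, chain: A}

regions:
  S1_S4: [732, 861]
  S1_S6: [732, 988]

pocket_params:
  ligand_cutoff: 4.0
  ion_cutoff: 4.0
  include_ion_coordinators: true

alignment_params:
  gap_open: -0.6
  gap_extend: 0.0
  fragment_len: 8
  column_cutoff: 5.0
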
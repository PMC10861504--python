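# Conserved-network catalog for class B1 receptor activation analysis.
#
# Member syntax:
#   "x.yyb"        generic position on the receptor chain
#   "ECL2:295"     loop residue by author number on the receptor chain
#   "Galpha:392"   partner-chain residue by author number (entity role prefix)
#
# Each expected pair carries its contact kind: "polar" is satisfied by a
# hydrogen bond or salt bridge, "hydrophobic" by a side-chain C-C
# contact.  `allowed` lists the residue types permitted at a position
# (conservation across the three receptors).  Motifs restricted to one
# receptor carry a `receptors` list.

motifs:
  HETY:
    description: >
      Inactive-state polar cluster H2.50b-E3.50b-T6.42b-Y7.57b at the
      receptor base; the TM6 threonine contacts the other three members
      until G-protein coupling pulls TM6 away.
    members: ["2.50b", "3.50b", "6.42b", "7.57b"]
    allowed:
      "2.50b": [HIS]
      "3.50b": [GLU]
      "6.42b": [THR]
      "7.57b": [TYR]
    pairs:
      - ["6.42b", "2.50b", polar]
      - ["6.42b", "3.50b", polar]
      - ["6.42b", "7.57b", polar]

  cytoplasmic:
    description: >
      Cytoplasmic polar network R2.46b-R6.37b-N7.61b-E8.49b locking the
      intracellular face; broken by the outward swing of TM6.
    members: ["2.46b", "6.37b", "7.61b", "8.49b"]
    allowed:
      "2.46b": [ARG]
      "6.37b": [ARG]
      "7.61b": [ASN]
      "8.49b": [GLU]
    pairs:
      - ["6.37b", "2.46b", polar]
      - ["6.37b", "7.61b", polar]
      - ["6.37b", "8.49b", polar]

  central:
    description: >
      Central polar network K/R2.60b-N3.43b-H6.52b-Q7.49b below the
      peptide pocket; compacts upon peptide binding.
    members: ["2.60b", "3.43b", "6.52b", "7.49b"]
    allowed:
      "2.60b": [LYS, ARG]
      "3.43b": [ASN]
      "6.52b": [HIS]
      "7.49b": [GLN]
    pairs:
      - ["2.60b", "3.43b", polar]
      - ["3.43b", "7.49b", polar]
      - ["7.49b", "6.52b", polar]

  PxxG:
    description: >
      P6.47b-x-x-G6.50b motif at the sharp TM6 kink; its inward
      rotation is stabilised by hydrogen bonds to TM5 (G6.50b-N5.50b)
      and TM7 (P6.47b-Q7.49b) plus hydrophobic packing against F5.54b
      and V7.53b.
    members: ["6.47b", "6.48b", "6.49b", "6.50b", "5.50b", "5.54b", "7.49b", "7.53b"]
    allowed:
      "6.47b": [PRO]
      "6.48b": [LEU]
      "6.49b": [LEU]
      "6.50b": [GLY]
      "5.50b": [ASN]
      "5.54b": [PHE]
      "7.49b": [GLN]
      "7.53b": [VAL]
    pairs:
      - ["6.50b", "5.50b", polar]
      - ["6.47b", "7.49b", polar]
      - ["6.48b", "7.53b", hydrophobic]
      - ["6.49b", "5.54b", hydrophobic]

  transmission_relay:
    description: >
      L6.48b-Y7.57b-N7.61b-E8.49b-E392(GalphaH5) relay transmitting the
      peptide-binding signal to the G protein in the fully active state.
    members: ["6.48b", "7.57b", "7.61b", "8.49b", "Galpha:392"]
    allowed:
      "6.48b": [LEU]
      "7.57b": [TYR]
      "7.61b": [ASN]
      "8.49b": [GLU]
      "Galpha:392": [GLU]
    pairs:
      - ["6.48b", "7.57b", hydrophobic]
      - ["7.57b", "7.61b", polar]
      - ["7.61b", "Galpha:392", polar]
      - ["8.49b", "Galpha:392", polar]

  tm5_ecl3_seal:
    description: >
      M/K5.33b-R5.40b-T/D/E(ECL3) interface sealing the pocket rim
      after peptide binding; encoded for GIPR, whose ECL3 glutamate is
      attested.
    receptors: [GIPR]
    members: ["5.33b", "5.40b", "ECL3:363"]
    allowed:
      "5.33b": [MET, LYS]
      "5.40b": [ARG]
      "ECL3:363": [THR, ASP, GLU]
    pairs:
      - ["5.40b", "ECL3:363", polar]
      - ["5.33b", "ECL3:363", polar]

  fw_switch:
    description: >
      GCGR phenylalanine/tryptophan packing switch around the TM4-TM5
      membrane face whose rearrangement pushes ECL2 into the orthosteric
      pocket in the ligand-free Gs-coupled state.
    receptors: [GCGR]
    members: ["3.40b", "4.56b", "4.60b", "4.67b", "5.36b", "5.37b", "5.38b", "5.41b", "ECL2:295", "ECL2:303"]
    allowed:
      "3.40b": [ILE]
      "4.56b": [PHE]
      "4.60b": [TRP]
      "4.67b": [PHE]
      "5.36b": [TRP]
      "5.37b": [TRP]
      "5.38b": [ILE]
      "5.41b": [PHE]
      "ECL2:295": [TRP]
      "ECL2:303": [PHE]
    pairs:
      - ["3.40b", "5.36b", hydrophobic]
      - ["4.56b", "4.60b", hydrophobic]
      - ["4.67b", "ECL2:295", hydrophobic]
      - ["5.37b", "ECL2:295", hydrophobic]
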
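# Full cross-state comparison over the deposited accessions.
#
# Coordinate files are NOT downloaded by the tool; place them under
# data/structures/ (relative to this file's parent directory) as
# <code>.cif or <code>.pdb, then run:
#
#   b1state report --config configs/paper_comparison.yaml --out results/paper
#
# Roles: inactive = antagonist-bound or apo without G protein;
# ligand_free_Gs = the ligand-free Gs-coupled (transitional) complexes;
# peptide_bound_Gs = agonist + Gs.  Chain roles are auto-detected
# (receptor = longest chain >= 200 residues, Galpha by its 380-394
# author numbers, peptide by length + receptor contact); add
# `chain_roles: {A: receptor, ...}` per entry to override.

structures:
  - {label: 8WG7, receptor: GLP1R, role: ligand_free_Gs, path: ../data/structures/8WG7.cif}
  - {label: 8WG8, receptor: GCGR,  role: ligand_free_Gs, path: ../data/structures/8WG8.cif}
  - {label: 8WA3, receptor: GIPR,  role: ligand_free_Gs, path: ../data/structures/8WA3.cif}
  - {label: 6X18, receptor: GLP1R, role: peptide_bound_Gs, path: ../data/structures/6X18.cif}
  - {label: 6LMK, receptor: GCGR,  role: peptide_bound_Gs, path: ../data/structures/6LMK.cif}
  - {label: 7DTY, receptor: GIPR,  role: peptide_bound_Gs, path: ../data/structures/7DTY.cif}
  - {label: 6LN2, receptor: GLP1R, role: inactive, path: ../data/structures/6LN2.cif}
  - {label: 5XEZ, receptor: GCGR,  role: inactive, path: ../data/structures/5XEZ.cif}
  - {label: 5NX2, receptor: GLP1R, role: intermediate, path: ../data/structures/5NX2.cif}
  - {label: 5YQZ, receptor: GCGR,  role: intermediate, path: ../data/structures/5YQZ.cif}

measurements:
  kinks:
    - {structure: 8WG7}
    - {structure: 8WG8}
    - {structure: 8WA3}
    - {structure: 6X18}
    - {structure: 6LMK}
    - {structure: 7DTY}
  displacements:
    # cytoplasmic TM6 opening upon Gs coupling
    - {mobile: 6LN2, reference: 8WG7, position: "6.37b"}
    - {mobile: 5XEZ, reference: 8WG8, position: "6.37b"}
    # extracellular rewiring upon peptide binding
    - {mobile: 6X18, reference: 8WG7, position: "1.33b"}
    - {mobile: 6X18, reference: 8WG7, position: "6.59b"}
    - {mobile: 6X18, reference: 8WG7, position: "7.33b"}
    - {mobile: 6LMK, reference: 8WG8, position: "1.34b"}
    - {mobile: 6LMK, reference: 8WG8, position: "6.57b"}
    - {mobile: 6LMK, reference: 8WG8, position: "7.33b"}
    - {mobile: 7DTY, reference: 8WA3, position: "1.30b"}
    - {mobile: 7DTY, reference: 8WA3, position: "6.55b"}
    - {mobile: 7DTY, reference: 8WA3, position: "7.33b"}
    # GIPR-specific intracellular TM6 difference between free and bound
    - {mobile: 8WA3, reference: 7DTY, position: "6.37b"}
    - {mobile: 8WA3, reference: 7DTY, position: "6.42b"}
  distances:
    # ligand-free trio: ECL3 tip spread
    - {mobile: 8WG7, reference: 8WG8, residue_mobile: "6.59b", residue_reference: "6.59b"}
    - {mobile: 8WG7, reference: 8WA3, residue_mobile: "6.59b", residue_reference: "6.59b"}
  networks:
    - {structure: 6LN2, motifs: [HETY, cytoplasmic]}
    - {structure: 5XEZ, motifs: [HETY, cytoplasmic]}
    - {structure: 8WG7, motifs: [HETY, cytoplasmic, central, PxxG]}
    - {structure: 8WG8, motifs: [HETY, cytoplasmic, central, PxxG, fw_switch]}
    - {structure: 8WA3, motifs: [HETY, cytoplasmic, central, PxxG]}
    - {structure: 6X18, motifs: [HETY, cytoplasmic, central, PxxG, transmission_relay]}
    - {structure: 6LMK, motifs: [HETY, cytoplasmic, central, PxxG, transmission_relay]}
    - {structure: 7DTY, motifs: [HETY, cytoplasmic, central, PxxG, transmission_relay, tm5_ecl3_seal]}
  interfaces: [8WG7, 8WG8, 8WA3, 6X18, 6LMK, 7DTY]
  overlaps:
    - {apo: 8WG8, holo: 6LMK, loop: ECL2}
    - {apo: 8WA3, holo: 7DTY, loop: ECL3}
    - {apo: 8WG7, holo: 6X18, loop: ECL2}
    - {apo: 8WG7, holo: 6X18, loop: ECL3}
  classify: [6LN2, 5XEZ, 8WG7, 8WG8, 8WA3, 6X18, 6LMK, 7DTY, 5NX2, 5YQZ]
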
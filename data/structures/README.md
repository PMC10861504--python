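# Pre-downloaded coordinate files

The library never fetches structures itself.  To run the accession-based
checks (`tests/test_acceptance.py` tiers 2-3 and
`configs/paper_comparison.yaml`), download the deposited models from the
Protein Data Bank into this directory, named `<code>.cif` (or `.pdb`):

    8WG7  8WG8  8WA3   ligand-free receptor-Gs-Nb35 complexes
    6X18  6LMK  7DTY   GLP-1-, glucagon- and GIP-bound Gs complexes
    6LN2  5XEZ         inactive GLP-1R / GCGR
    5NX2  5YQZ         peptide-bound intermediate-state structures

e.g. `curl -O https://files.rcsb.org/download/8WG7.cif` for each code.
Without these files the synthetic planted-truth fixtures cover every
pipeline stage offline.
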
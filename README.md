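# halostruct

Comparative structural and sequence analysis toolkit for halophilic
glutathione-transferase-like proteins. It packages, as one tested pipeline,
the analyses used to characterize a haloarchaeal enzyme against its
mesophilic homologs:

- **structure_io** — fixed-column PDB reading/writing with first-class
  negative author residue numbers (His-tag numbering), SEQRES-vs-modeled
  missing-residue accounting, and unit-cell metadata.
- **superpose** — global sequence alignment (BLOSUM62, affine gaps) driving
  Kabsch C-alpha superposition with iterative outlier rejection; monomer and
  dimer modes (both chain pairings evaluated, the better one reported).
- **composition** — per-amino-acid count deltas between a query and a
  reference sequence, with charge/hydrophobicity category roll-ups.
- **surface** — Shrake–Rupley solvent accessibility on a deterministic
  sphere-point set, relative-SASA surface classification, a permutation
  test for the spatial evenness of charged surface residues, and a
  capped-Coulomb per-residue potential score (qualitative only).
- **ligand_transfer** — transplanting a reference-bound ligand through a
  superposition into the target frame, glutathione → γ-glutamyl-cysteine
  truncation, selection-based distance measurements, and van der Waals
  clash detection.
- **seq_features** — protein motif scanning, alignment-column annotation
  transfer, IUPAC restriction-site scanning, ORF translation checks.
- **phylo** — p-distances with pairwise deletion, Saitou–Nei neighbor
  joining, bootstrap supports with a display threshold, newick I/O.
- **synthetic_data** — deterministic fixtures for everything above:
  helical C-alpha traces, planted rigid transforms, homodimers, a
  GSH-topology ligand, skewed sequences, alignments evolved on known trees.
- **pipeline** / **cli** — a single TOML-configured workflow plus
  subcommands for each stage.

## Command line

```sh
halostruct superpose --target 6gzf.pdb --ref 4g0i.pdb --mode monomer --chains A:A
halostruct superpose --target 6gzf.pdb --ref 4g0i.pdb --mode dimer --chains AB:AB
halostruct compose-delta --query nm.fasta --ref yqjg.fasta
halostruct surface --pdb 6gzf.pdb --perm 999 --seed 1 --out surface.tsv
halostruct transfer-ligand --target 6gzf.pdb --ref yqjg_holo.pdb \
    --ligand GSH --truncate-to GEC --report distances.tsv
halostruct phylo --msa xi.aln --boot 1000 --seed 7 --threshold 40
halostruct make-fixture --kind dimer --n 120 --sigma 0.5 --seed 3 --out fixtures/
halostruct run --config run.toml
```

`run.toml` is a flat key/value file; see `halostruct.pipeline.RunConfig`
for the accepted keys. All randomness is seeded from the config and two
runs with the same config produce byte-identical outputs.

Selections for `transfer-ligand` distance/clash reporting use a small
conjunctive grammar: `chain A and resi 57 and name SG`,
`ligand and name SG2` (keywords: `chain`, `resi`, `resn`, `name`,
`ligand`; `name` accepts `+`-separated alternatives).

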
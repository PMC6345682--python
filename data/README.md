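# data/

Plain-text snapshots of the deposited database entries consumed by the
comparison analyses. This directory ships empty except for this note: the
build environment had no network route to the structure/sequence archives.

Populate it (on a machine with internet access) with:

    python scripts/fetch_data.py

which writes:

    data/pdb/6gzf.pdb          target structure
    data/pdb/4g0i.pdb          E. coli homolog (printed elsewhere as "4GOI")
    data/pdb/3ppu.pdb .. 3m1g.pdb   further comparison entries
    data/pdb/yqjg_holo.pdb     GSH-bound E. coli homolog deposition
    data/fasta/WP_004217051.fasta, data/fasta/P42620.fasta
    data/msa/xi_classes.fasta  mafft alignment of representative sequences

With these present, the red tests in tests/test_acceptance.py turn green and
scripts/acceptance.py reports the full target set.
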
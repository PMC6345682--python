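"""Populate data/ with the deposited entries the comparison analyses need.

Run from the repository root on a machine with internet access:

    python scripts/fetch_data.py

Downloads (plain-text formats only):
  data/pdb/6gzf.pdb      target structure (haloarchaeal GST, His-tagged)
  data/pdb/4g0i.pdb      E. coli YqjG           (printed elsewhere as "4GOI";
                         the deposited code uses the digit zero)
  data/pdb/3ppu.pdb      P. chrysosporium homolog
  data/pdb/5lkb.pdb      S. cerevisiae homolog
  data/pdb/4uss.pdb      P. trichocarpa homolog
  data/pdb/3m1g.pdb      C. glutamicum homolog
  data/pdb/yqjg_holo.pdb first E. coli YqjG deposition found to contain a
                         bound GSH HETATM group (candidates probed in order)
  data/fasta/WP_004217051.fasta  query protein (NCBI)
  data/fasta/P42620.fasta        E. coli YqjG (UniProt)

Without these snapshots the published-value checks in tests/test_acceptance.py
fail and scripts/acceptance.py omits the corresponding targets.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

PDB_URL = "https://files.rcsb.org/download/{code}.pdb"
UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
NCBI_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={acc}&rettype=fasta&retmode=text"
)

ENTRIES = ["6GZF", "4G0I", "3PPU", "5LKB", "4USS", "3M1G"]
#: YqjG depositions probed, in order, for a bound GSH group
HOLO_CANDIDATES = ["4G0K", "4G0I", "4G0J"]

#: representative accessions for the clade-placement check, labelled by
#: family; aligned with mafft (external) into data/msa/xi_classes.fasta
MSA_ACCESSIONS = {
    "Xi_query": ("ncbi", "WP_004217051"),
    "Xi_Hvolcanii": ("ncbi", "WP_004044265"),
    "Xi_Hsalinarum": ("uniprot", "Q9HN26"),
    "Xi_EcYqjG": ("uniprot", "P42620"),
    "Xi_PcpF": ("uniprot", "Q8KN33"),
    "Xi_Scerevisiae": ("uniprot", "P36156"),
    "Omega_Hsapiens": ("ncbi", "NP_004823"),
    "Omega_Rnorvegicus": ("uniprot", "Q9Z339"),
    "Beta_Pmirabilis": ("uniprot", "P15214"),
    "Beta_Ecoli": ("uniprot", "P39100"),
    "Lambda_Athaliana": ("uniprot", "Q6NLB0"),
}


def fetch(url: str) -> str:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    root = Path(__file__).resolve().parent.parent
    pdb_dir = root / "data" / "pdb"
    fasta_dir = root / "data" / "fasta"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    fasta_dir.mkdir(parents=True, exist_ok=True)

    for code in ENTRIES:
        out = pdb_dir / f"{code.lower()}.pdb"
        if not out.exists():
            print(f"fetching {code}")
            out.write_text(fetch(PDB_URL.format(code=code)))

    holo = pdb_dir / "yqjg_holo.pdb"
    if not holo.exists():
        for code in HOLO_CANDIDATES:
            try:
                text = fetch(PDB_URL.format(code=code))
            except Exception as exc:  # candidate may not exist
                print(f"  {code}: {exc}")
                continue
            if any(
                line.startswith("HETATM") and line[17:20].strip() == "GSH"
                for line in text.splitlines()
            ):
                print(f"GSH-bound reference: {code}")
                holo.write_text(text)
                break
        else:
            print("WARNING: no GSH-bound YqjG deposition found", file=sys.stderr)

    for acc, url in [
        ("WP_004217051", NCBI_URL.format(acc="WP_004217051")),
        ("P42620", UNIPROT_URL.format(acc="P42620")),
    ]:
        out = fasta_dir / f"{acc}.fasta"
        if not out.exists():
            print(f"fetching {acc}")
            out.write_text(fetch(url))

    msa_dir = root / "data" / "msa"
    msa_out = msa_dir / "xi_classes.fasta"
    if not msa_out.exists():
        msa_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for label, (db, acc) in MSA_ACCESSIONS.items():
            url = NCBI_URL.format(acc=acc) if db == "ncbi" else UNIPROT_URL.format(acc=acc)
            try:
                text = fetch(url)
            except Exception as exc:
                print(f"  {label} ({acc}): {exc}", file=sys.stderr)
                continue
            seq = "".join(
                line.strip() for line in text.splitlines() if not line.startswith(">")
            )
            records.append(f">{label}\n{seq}\n")
        unaligned = msa_dir / "xi_classes_unaligned.fasta"
        unaligned.write_text("".join(records))
        import shutil
        import subprocess

        if shutil.which("mafft"):
            aligned = subprocess.run(
                ["mafft", "--auto", str(unaligned)],
                check=True, capture_output=True, text=True,
            ).stdout
            msa_out.write_text(aligned)
            print(f"aligned {len(records)} sequences into {msa_out}")
        else:
            print(
                "mafft not found: align data/msa/xi_classes_unaligned.fasta "
                "yourself and save it as data/msa/xi_classes.fasta",
                file=sys.stderr,
            )

    print("done")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
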
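"""Sequence-level feature detection.

Protein motif scanning, alignment-column annotation transfer, restriction
site scanning over IUPAC patterns, and ORF translation checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "MotifHit",
    "AnnotationTransfer",
    "RestrictionSite",
    "scan_protein_motif",
    "transfer_annotations",
    "scan_restriction_sites",
    "translate_orf",
    "IUPAC_DNA",
]

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    pattern: str
    start: int  # 1-based residue position
    match: str


@dataclass
class AnnotationTransfer:
    reference_id: str
    reference_positions: list[int]  # 1-based, ungapped reference numbering
    #: target id -> list of (mapped 1-based position or None, residue or '-')
    mapped: dict[str, list[tuple[int | None, str]]]


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    pattern: str
    offset: int  # 0-based
    strand: str = "+"


def _protein_pattern_to_regex(pattern: str) -> str:
    """Compile a class-based protein pattern ('CP[WFY][AS]') to a regex."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise ValueError(f"unclosed class in pattern {pattern!r}")
            members = pattern[i + 1 : end]
            if not members or not members.isalpha():
                raise ValueError(f"invalid class {pattern[i:end + 1]!r}")
            out.append("[" + members.upper() + "]")
            i = end + 1
        elif ch.isalpha() or ch == ".":
            out.append(ch.upper() if ch.isalpha() else ".")
            i += 1
        else:
            raise ValueError(f"invalid character {ch!r} in pattern {pattern!r}")
    return "".join(out)


def scan_protein_motif(
    sequence: str, pattern: str, sequence_id: str = "seq", offset: int = 0
) -> list[MotifHit]:
    """All (overlapping) occurrences of a class-based motif, 1-based starts.

    ``offset`` shifts reported positions, e.g. to express hits in the native
    numbering of a tagged construct.
    """
    regex = re.compile(_protein_pattern_to_regex(pattern))
    seq = sequence.upper()
    hits = []
    pos = 0
    while True:
        m = regex.search(seq, pos)
        if m is None:
            break
        hits.append(
            MotifHit(sequence_id, pattern, m.start() + 1 + offset, m.group())
        )
        pos = m.start() + 1
    return hits


def _column_map(aligned_seq: str) -> dict[int, int]:
    """Ungapped position (1-based) -> alignment column (0-based)."""
    mapping = {}
    pos = 0
    for col, ch in enumerate(aligned_seq):
        if ch not in "-.":
            pos += 1
            mapping[pos] = col
    return mapping


def transfer_annotations(
    msa: dict[str, str], reference_id: str, positions: list[int]
) -> AnnotationTransfer:
    """Map reference residue positions onto every other sequence in an MSA.

    Positions travel through shared alignment columns.  A target with a gap
    in the column is flagged by a ``None`` mapped position; the residue
    actually present at the mapped position is always reported verbatim.
    """
    if reference_id not in msa:
        raise KeyError(f"reference {reference_id!r} absent from alignment")
    ref_aln = msa[reference_id]
    ref_map = _column_map(ref_aln)
    ref_len = len(ref_map)
    for p in positions:
        if not 1 <= p <= ref_len:
            raise ValueError(f"position {p} outside reference length {ref_len}")
    columns = [ref_map[p] for p in positions]
    mapped: dict[str, list[tuple[int | None, str]]] = {}
    for seq_id, aligned in msa.items():
        if seq_id == reference_id:
            continue
        entries: list[tuple[int | None, str]] = []
        pos = 0
        col_to_pos: dict[int, int] = {}
        for col, ch in enumerate(aligned):
            if ch not in "-.":
                pos += 1
                col_to_pos[col] = pos
        for col in columns:
            ch = aligned[col]
            if ch in "-.":
                entries.append((None, "-"))
            else:
                entries.append((col_to_pos[col], ch))
        mapped[seq_id] = entries
    return AnnotationTransfer(reference_id, list(positions), mapped)


def scan_restriction_sites(
    dna: str, enzymes: dict[str, str]
) -> list[RestrictionSite]:
    """Forward-strand matches of IUPAC recognition patterns, 0-based offsets."""
    seq = dna.upper()
    for pos, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid base {ch!r} at position {pos}")
    sites = []
    for enzyme, pattern in enzymes.items():
        try:
            regex = "".join(IUPAC_DNA[b] for b in pattern.upper())
        except KeyError as exc:
            raise ValueError(f"invalid IUPAC base {exc.args[0]!r} in {enzyme}") from None
        for m in re.finditer(f"(?=({regex}))", seq):
            sites.append(RestrictionSite(enzyme, pattern.upper(), m.start(), "+"))
    sites.sort(key=lambda s: (s.offset, s.enzyme))
    return sites


def translate_orf(dna: str) -> str:
    """Translate a stop-terminated ORF with the standard genetic code.

    The terminal stop codon is consumed; an internal stop raises with its
    codon position.  A non-start first codon only logs a warning via the
    return contract (translation still proceeds).
    """
    seq = dna.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    if len(seq) < 6:
        raise ValueError("ORF must contain at least a start and a stop codon")
    table = standard_dna_table
    protein = []
    n_codons = len(seq) // 3
    for idx in range(n_codons):
        codon = seq[3 * idx : 3 * idx + 3]
        if codon in table.stop_codons:
            if idx == n_codons - 1:
                return "".join(protein)
            raise ValueError(f"internal stop codon {codon} at codon {idx + 1}")
        protein.append(table.forward_table.get(codon, "X"))
    raise ValueError("ORF does not end in a stop codon")
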
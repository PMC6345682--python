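"""PDB-format structure I/O and bookkeeping.

Reads fixed-column PDB files into a light validated model that keeps the
information the downstream analyses need: author residue numbering
(including negative numbers used for purification tags), per-chain SEQRES
records, unit-cell metadata, and HETATM groups kept apart from the polymer
chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "UnitCell",
    "StructureModel",
    "GapSegment",
    "PDBParseError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "missing_residues",
    "chain_sequence",
    "normalize_entry_code",
    "three_to_one",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "U", "PYL": "O",
}

#: residue names treated as solvent, never part of a polymer chain
SOLVENT_RESNAMES = {"HOH", "DOD", "WAT"}


class PDBParseError(ValueError):
    """Raised for a malformed fixed-column record; names the offending line."""


class EmptyStructureError(ValueError):
    """Raised when the input contains no ATOM/HETATM record."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in atom {self.name}")

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    resseq: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainModel:
    chain_id: str
    modeled_residues: list[Residue] = field(default_factory=list)
    seqres: list[str] = field(default_factory=list)

    def residue(self, resseq: int, icode: str = "") -> Residue | None:
        for r in self.modeled_residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        return None


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("unit-cell angles must be in (0, 180)")


@dataclass
class StructureModel:
    id: str
    chains: list[ChainModel] = field(default_factory=list)
    cell: UnitCell | None = None
    space_group: str | None = None
    het_groups: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of SEQRES positions (1-based, inclusive) with no model."""

    start: int
    end: int
    location: str  # "N-terminal" | "internal" | "C-terminal"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# parsing

def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: cannot parse {what} from columns "
            f"{lo + 1}-{hi}: {text!r}"
        ) from None


def _parse_int(line: str, lo: int, hi: int, what: str, lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: cannot parse {what} from columns "
            f"{lo + 1}-{hi}: {text!r}"
        ) from None


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n").rstrip("\r")
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    occ = line[54:60].strip()
    bfac = line[60:66].strip()
    return AtomRecord(
        serial=_parse_int(line, 6, 11, "serial", lineno),
        name=line[12:16].strip(),
        altloc=line[16].strip(),
        resname=line[17:20].strip(),
        chain_id=line[21].strip() or " ",
        resseq=_parse_int(line, 22, 26, "residue number", lineno),
        icode=line[26].strip() if len(line) > 26 else "",
        x=_parse_float(line, 30, 38, "x", lineno),
        y=_parse_float(line, 38, 46, "y", lineno),
        z=_parse_float(line, 46, 54, "z", lineno),
        occupancy=float(occ) if occ else 1.0,
        bfactor=float(bfac) if bfac else 0.0,
        element=line[76:78].strip() if len(line) > 76 else "",
        is_hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """One conformer per atom name: highest occupancy, ties by altloc id."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
            continue
        prev = by_name[atom.name]
        if (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins ties; blank and lexicographically smaller ids win
    if not altloc:
        return 0.0
    return -ord(altloc)


def read_structure(source: str | Path, structure_id: str | None = None) -> StructureModel:
    """Parse PDB-format text (or a path to it) into a :class:`StructureModel`.

    Negative author residue numbers are supported.  Alternate locations are
    resolved per atom to the highest-occupancy conformer (ties broken by the
    lexicographically smallest altloc id).  Waters and other HETATM groups
    are kept out of the polymer chains.
    """
    path: Path | None = None
    if isinstance(source, Path):
        path = source
    elif isinstance(source, str) and "\n" not in source and len(source) < 4096:
        candidate = Path(source)
        if candidate.exists():
            path = candidate
    fallback_id = None
    if path is not None:
        text = path.read_text()
        fallback_id = path.stem.upper()
    else:
        text = str(source)

    cell: UnitCell | None = None
    space_group: str | None = None
    seqres: dict[str, list[str]] = {}
    header_id: str | None = None

    # (chain_id, resseq, icode) -> raw atom list, in file order
    polymer: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    polymer_resnames: dict[tuple[str, int, str], str] = {}
    het: dict[tuple[str, int, str], Residue] = {}
    n_atoms = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            n_atoms += 1
            if atom.is_hetatm:
                key = (atom.chain_id, atom.resseq, atom.icode)
                residue = het.setdefault(
                    key, Residue(atom.resseq, atom.icode, atom.resname)
                )
                residue.atoms.append(atom)
            else:
                chain = polymer.setdefault(atom.chain_id, {})
                rkey = (atom.resseq, atom.icode)
                chain.setdefault(rkey, []).append(atom)
                polymer_resnames[(atom.chain_id, *rkey)] = atom.resname
        elif record == "CRYST1":
            cell = UnitCell(
                a=_parse_float(line, 6, 15, "cell a", lineno),
                b=_parse_float(line, 15, 24, "cell b", lineno),
                c=_parse_float(line, 24, 33, "cell c", lineno),
                alpha=_parse_float(line, 33, 40, "cell alpha", lineno),
                beta=_parse_float(line, 40, 47, "cell beta", lineno),
                gamma=_parse_float(line, 47, 54, "cell gamma", lineno),
            )
            if len(line) > 55:
                space_group = line[55:66].strip() or None
        elif record == "SEQRES":
            chain_id = line[11].strip() or " "
            seqres.setdefault(chain_id, []).extend(line[19:].split())
        elif record == "HEADER" and len(line) >= 63:
            header_id = line[62:66].strip() or None

    if n_atoms == 0:
        raise EmptyStructureError("input contains no ATOM/HETATM record")

    chains: list[ChainModel] = []
    for chain_id, residues in polymer.items():
        chain = ChainModel(chain_id=chain_id, seqres=seqres.get(chain_id, []))
        for rkey in sorted(residues, key=lambda k: (k[0], k[1])):
            resname = polymer_resnames[(chain_id, *rkey)]
            atoms = _resolve_altlocs(residues[rkey])
            chain.modeled_residues.append(Residue(rkey[0], rkey[1], resname, atoms))
        chains.append(chain)

    if len({c.chain_id for c in chains}) != len(chains):
        raise PDBParseError("duplicate chain identifiers")

    model = StructureModel(
        id=structure_id or header_id or fallback_id or "XXXX",
        chains=chains,
        cell=cell,
        space_group=space_group,
    )
    for key in sorted(het):
        residue = het[key]
        residue.atoms = _resolve_altlocs(residue.atoms)
        if residue.resname in SOLVENT_RESNAMES:
            model.waters.append(residue)
        else:
            model.het_groups.append(residue)
    return model


# ---------------------------------------------------------------------------
# writing

def _format_atom(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name
    # standard convention: single-letter element names start in column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    return (
        f"{record}{serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
        f"{atom.resname:>3s} {atom.chain_id:1s}{atom.resseq:4d}"
        f"{atom.icode or ' ':1s}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize a model back to fixed-column PDB text (optionally to a file)."""
    lines: list[str] = []
    if model.id and model.id != "XXXX":
        lines.append(f"HEADER    {'':40s}{'':11s}{model.id[:4]:>4s}")
    if model.cell is not None:
        sg = model.space_group or "P 1"
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}"
        )
    for chain in model.chains:
        for i in range(0, len(chain.seqres), 13):
            chunk = chain.seqres[i : i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {chain.chain_id:1s} "
                f"{len(chain.seqres):4d}  " + " ".join(f"{r:>3s}" for r in chunk)
            )
    serial = 1
    for chain in model.chains:
        for residue in chain.modeled_residues:
            for atom in residue.atoms:
                lines.append(_format_atom(atom, serial))
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for group in (*model.het_groups, *model.waters):
        for atom in group.atoms:
            lines.append(_format_atom(atom, serial))
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# bookkeeping

def three_to_one(resname: str) -> str:
    """3-letter to 1-letter code, 'X' (with a logged warning) for unknowns."""
    try:
        return THREE_TO_ONE[resname.upper()]
    except KeyError:
        logger.warning("unknown residue name %r mapped to 'X'", resname)
        return "X"


def chain_sequence(chain: ChainModel, source: str = "modeled") -> str:
    """One-letter sequence of a chain from its SEQRES or modeled residues."""
    if source == "seqres":
        return "".join(three_to_one(r) for r in chain.seqres)
    if source == "modeled":
        return "".join(three_to_one(r.resname) for r in chain.modeled_residues)
    raise ValueError(f"source must be 'seqres' or 'modeled', got {source!r}")


def _embed_modeled_in_seqres(seqres_seq: str, modeled_seq: str) -> list[int | None]:
    """Map each SEQRES position to a modeled-residue index (or None).

    Alignment that embeds the modeled sequence into SEQRES: matches score 1,
    mismatches are forbidden, and contiguous modeled runs are preferred via a
    small gap-opening cost.  Plain O(n*m) dynamic programming; chains here
    are a few hundred residues.
    """
    n, m = len(seqres_seq), len(modeled_seq)
    NEG = float("-inf")
    gap_open = 0.01  # small cost per gap segment: prefer contiguous gaps
    # M[i][j]: seqres position i matched to modeled j; D[i][j]: i deleted.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0  # virtual start state
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            from_m, from_d = M[i - 1][j], D[i - 1][j]
            D[i][j] = max(from_m - gap_open, from_d)
            if j >= 1 and seqres_seq[i - 1] == modeled_seq[j - 1]:
                best_prev = max(M[i - 1][j - 1], D[i - 1][j - 1])
                if best_prev > NEG:
                    M[i][j] = best_prev + 1.0
    final = max(M[n][m], D[n][m])
    if final == NEG:
        raise ValueError("modeled sequence is not a subsequence of SEQRES")
    mapping: list[int | None] = [None] * n
    i, j = n, m
    state = "M" if M[n][m] >= D[n][m] else "D"
    while i > 0:
        if state == "M":
            mapping[i - 1] = j - 1
            state = "M" if M[i - 1][j - 1] >= D[i - 1][j - 1] else "D"
            i, j = i - 1, j - 1
        else:
            state = "M" if M[i - 1][j] - gap_open >= D[i - 1][j] else "D"
            i -= 1
    return mapping


def missing_residues(chain: ChainModel) -> list[GapSegment]:
    """Maximal runs of SEQRES positions with no modeled residue.

    Requires a non-empty SEQRES.  Modeled residues must occur in SEQRES
    order (deletions only), which holds for deposited entries.
    """
    if not chain.seqres:
        raise ValueError(
            f"chain {chain.chain_id!r} has no SEQRES; missing residues not computable"
        )
    seqres_seq = chain_sequence(chain, "seqres")
    modeled_seq = chain_sequence(chain, "modeled")
    mapping = _embed_modeled_in_seqres(seqres_seq, modeled_seq)
    segments: list[GapSegment] = []
    n = len(mapping)
    i = 0
    while i < n:
        if mapping[i] is None:
            start = i
            while i < n and mapping[i] is None:
                i += 1
            end = i - 1
            if start == 0:
                location = "N-terminal"
            elif end == n - 1:
                location = "C-terminal"
            else:
                location = "internal"
            segments.append(GapSegment(start + 1, end + 1, location))
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# entry-code normalization

def normalize_entry_code(code: str, available: Iterable[str] | None = None) -> str:
    """Normalize a PDB entry code: case-insensitive, letter-O/digit-0 repair.

    Printed entry codes sometimes confuse the letter O with the digit 0.
    With ``available`` (known codes), the first case-insensitive or O<->0
    variant that matches is returned; any repair is logged.
    """
    canon = code.strip().upper()
    if available is None:
        return canon
    known = {c.strip().upper(): c for c in available}
    if canon in known:
        return canon
    variants = {canon.replace("O", "0"), canon.replace("0", "O")}
    for var in sorted(variants):
        if var in known:
            logger.warning("entry code %r normalized to %r", code, var)
            return var
    raise KeyError(f"entry code {code!r} not found among available codes")
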
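"""Homology-based ligand transplantation and steric analysis.

Carries a bound ligand from a reference structure into a superposed target
frame, supports chemically-aware truncation of glutathione to
gamma-glutamyl-cysteine, and measures distances and van der Waals clashes
against the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure_io import AtomRecord, Residue, StructureModel
from .superpose import SuperpositionResult
from .surface import atom_radius

__all__ = [
    "TransplantedLigand",
    "DistanceMeasurement",
    "ClashRecord",
    "GLYCYL_ATOMS",
    "GSH_HEAVY_ATOMS",
    "select",
    "transplant_ligand",
    "truncate_gsh_to_gec",
    "measure_distance",
    "detect_clashes",
]

#: heavy atoms of the glutathione chemical component, tripeptide order
GSH_HEAVY_ATOMS = (
    "N1", "CA1", "C1", "O11", "O12", "CB1", "CG1", "CD1", "OE1",  # glutamyl
    "N2", "CA2", "C2", "O2", "CB2", "SG2",                        # cysteinyl
    "N3", "CA3", "C3", "O31", "O32",                              # glycyl
)

#: the five glycyl-moiety heavy atoms removed when truncating GSH
GLYCYL_ATOMS = frozenset({"N3", "CA3", "C3", "O31", "O32"})


@dataclass
class TransplantedLigand:
    atoms: list[AtomRecord]
    source_entry: str
    resname: str
    transform: tuple[np.ndarray, np.ndarray]  # (rotation, translation)
    edits: list[str] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in transplanted ligand")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass(frozen=True)
class DistanceMeasurement:
    group_a: str
    group_b: str
    mode: str
    value: float


@dataclass(frozen=True)
class ClashRecord:
    ligand_atom: str
    protein_chain: str
    protein_resseq: int
    protein_icode: str
    protein_resname: str
    protein_atom: str
    distance: float
    vdw_overlap: float


# ---------------------------------------------------------------------------
# selection mini-language: conjunctions of chain/resi/resn/name/ligand

def select(
    structure: StructureModel | None,
    expression: str,
    ligand: TransplantedLigand | None = None,
) -> list[AtomRecord]:
    """Evaluate a selection like ``chain A and resi 57 and name SG``.

    Clauses (joined with ``and``): ``chain <id>``, ``resi <int>``,
    ``resn <3-letter>``, ``name <atom>[+<atom>...]``, ``ligand``.  The
    ``ligand`` clause switches the atom source to the transplanted ligand.
    """
    tokens = expression.split()
    clauses: list[tuple[str, str]] = []
    want_ligand = False
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            i += 1
            continue
        if tok == "ligand":
            want_ligand = True
            i += 1
            continue
        if tok in ("chain", "resi", "resn", "name"):
            if i + 1 >= len(tokens):
                raise ValueError(f"selection {expression!r}: missing value for {tok}")
            clauses.append((tok, tokens[i + 1]))
            i += 2
            continue
        raise ValueError(f"selection {expression!r}: unknown keyword {tokens[i]!r}")

    if want_ligand:
        if ligand is None:
            raise ValueError(f"selection {expression!r} needs a ligand but none given")
        pool = [(None, None, a) for a in ligand.atoms]
    else:
        if structure is None:
            raise ValueError(f"selection {expression!r} needs a structure but none given")
        pool = [
            (chain.chain_id, residue, a)
            for chain in structure.chains
            for residue in chain.modeled_residues
            for a in residue.atoms
        ]
        pool += [
            (res.atoms[0].chain_id, res, a)
            for res in structure.het_groups
            for a in res.atoms
        ]

    out: list[AtomRecord] = []
    for chain_id, residue, atom in pool:
        ok = True
        for key, value in clauses:
            if key == "chain":
                ok = chain_id == value
            elif key == "resi":
                ok = residue is not None and residue.resseq == int(value)
            elif key == "resn":
                ok = (
                    residue.resname.upper() == value.upper()
                    if residue is not None
                    else atom.resname.upper() == value.upper()
                )
            elif key == "name":
                ok = atom.name.upper() in {v.upper() for v in value.split("+")}
            if not ok:
                break
        if ok:
            out.append(atom)
    return out


# ---------------------------------------------------------------------------
# operations

def transplant_ligand(
    target: StructureModel,
    reference: StructureModel,
    ligand_resname: str,
    superposition: SuperpositionResult,
    selector: tuple[str, int] | None = None,
) -> TransplantedLigand:
    """Carry a HETATM group of the reference into the target frame.

    ``superposition`` must map reference-frame coordinates into the target
    frame (i.e. it superposed the reference onto the target).  With several
    copies of the ligand present, ``selector`` picks one as
    (chain_id, resseq).
    """
    candidates = [
        g for g in reference.het_groups if g.resname.upper() == ligand_resname.upper()
    ]
    if not candidates:
        raise ValueError(
            f"reference {reference.id!r} has no HETATM group {ligand_resname!r}"
        )
    if selector is not None:
        candidates = [
            g
            for g in candidates
            if (g.atoms[0].chain_id, g.resseq) == (selector[0], selector[1])
        ]
        if not candidates:
            raise ValueError(f"no {ligand_resname!r} copy matching selector {selector}")
    if len(candidates) > 1:
        where = [(g.atoms[0].chain_id, g.resseq) for g in candidates]
        raise ValueError(
            f"multiple {ligand_resname!r} copies in {reference.id!r}: {where}; "
            "pass a (chain, resseq) selector"
        )
    group: Residue = candidates[0]
    rotation = superposition.rotation
    translation = superposition.translation
    atoms = []
    for a in group.atoms:
        new_xyz = rotation @ np.array(a.coords) + translation
        atoms.append(
            replace(a, x=float(new_xyz[0]), y=float(new_xyz[1]), z=float(new_xyz[2]))
        )
    return TransplantedLigand(
        atoms=atoms,
        source_entry=reference.id,
        resname=group.resname,
        transform=(rotation.copy(), translation.copy()),
        edits=[],
    )


def truncate_gsh_to_gec(ligand: TransplantedLigand) -> TransplantedLigand:
    """Delete the glycyl moiety of a transplanted GSH, yielding gamma-Glu-Cys.

    The five glycyl heavy atoms are removed; nothing is rebuilt or renamed.
    Raises if any expected glycyl atom is absent (e.g. on a second call).
    """
    present = {a.name for a in ligand.atoms}
    missing = GLYCYL_ATOMS - present
    if missing:
        raise ValueError(
            f"glycyl atoms {sorted(missing)} absent; ligand is not an intact GSH"
        )
    kept = [a for a in ligand.atoms if a.name not in GLYCYL_ATOMS]
    return TransplantedLigand(
        atoms=kept,
        source_entry=ligand.source_entry,
        resname="GEC",
        transform=ligand.transform,
        edits=ligand.edits + sorted(GLYCYL_ATOMS),
    )


def measure_distance(
    structure: StructureModel | None,
    group_a: str,
    group_b: str,
    mode: str = "min",
    ligand: TransplantedLigand | None = None,
) -> DistanceMeasurement:
    """Distance between two atom selections (minimum pairwise or centroid)."""
    atoms_a = select(structure, group_a, ligand)
    atoms_b = select(structure, group_b, ligand)
    if not atoms_a:
        raise ValueError(f"empty selection: {group_a!r}")
    if not atoms_b:
        raise ValueError(f"empty selection: {group_b!r}")
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([a.coords for a in atoms_b])
    if mode == "min":
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        value = float(d.min())
    elif mode == "centroid":
        value = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    else:
        raise ValueError(f"mode must be 'min' or 'centroid', got {mode!r}")
    return DistanceMeasurement(group_a, group_b, mode, value)


def detect_clashes(
    ligand: TransplantedLigand,
    structure: StructureModel,
    tolerance: float = 0.4,
) -> list[ClashRecord]:
    """Ligand-protein pairs closer than the vdW sum minus the tolerance.

    Strict inequality: a pair exactly at r_a + r_b - tolerance is not a
    clash.  Records are sorted by overlap, largest first.
    """
    records: list[ClashRecord] = []
    for la in ligand.atoms:
        ra = atom_radius(la.name, la.element)
        lx = np.array(la.coords)
        for chain in structure.chains:
            for residue in chain.modeled_residues:
                for pa in residue.atoms:
                    rb = atom_radius(pa.name, pa.element)
                    d = float(np.linalg.norm(lx - np.array(pa.coords)))
                    overlap = ra + rb - d - tolerance
                    if overlap > 0:
                        records.append(
                            ClashRecord(
                                ligand_atom=la.name,
                                protein_chain=chain.chain_id,
                                protein_resseq=residue.resseq,
                                protein_icode=residue.icode,
                                protein_resname=residue.resname,
                                protein_atom=pa.name,
                                distance=d,
                                vdw_overlap=overlap,
                            )
                        )
    records.sort(key=lambda r: -r.vdw_overlap)
    return records
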
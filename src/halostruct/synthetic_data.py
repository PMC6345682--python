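"""Deterministic synthetic fixtures for every analysis stage.

Toy C-alpha structures with planted rigid transforms, homodimers, a
GSH-topology ligand, composition-skewed sequences, and alignments evolved
on a known tree.  Everything is byte-reproducible from (parameters, seed)
and is emitted in the same standard formats the analysis modules consume.
"""

from __future__ import annotations

import numpy as np

from .composition import AMINO_ACIDS
from .phylo import SupportedTree, TreeNode, parse_newick
from .structure_io import AtomRecord, ChainModel, Residue, StructureModel

__all__ = [
    "make_helix_structure",
    "make_transformed_copy",
    "make_dimer_structure",
    "make_gsh_like_ligand",
    "make_skewed_sequence",
    "make_sequence_family",
    "rotation_about_axis",
]

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom

#: bonded pairs of the GSH heavy-atom graph with target bond lengths
GSH_BONDS = [
    ("N1", "CA1", 1.47), ("CA1", "C1", 1.52), ("C1", "O11", 1.23),
    ("C1", "O12", 1.25), ("CA1", "CB1", 1.53), ("CB1", "CG1", 1.52),
    ("CG1", "CD1", 1.52), ("CD1", "OE1", 1.23), ("CD1", "N2", 1.33),
    ("N2", "CA2", 1.46), ("CA2", "C2", 1.52), ("C2", "O2", 1.23),
    ("CA2", "CB2", 1.53), ("CB2", "SG2", 1.81), ("C2", "N3", 1.33),
    ("N3", "CA3", 1.45), ("CA3", "C3", 1.52), ("C3", "O31", 1.25),
    ("C3", "O32", 1.25),
]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    k = axis / norm
    theta = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _ca_atom(serial: int, chain_id: str, resseq: int, xyz: np.ndarray) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name="CA",
        altloc="",
        resname="ALA",
        chain_id=chain_id,
        resseq=resseq,
        icode="",
        x=float(xyz[0]),
        y=float(xyz[1]),
        z=float(xyz[2]),
        occupancy=1.0,
        bfactor=0.0,
        element="C",
    )


def make_helix_structure(
    n_res: int, seed: int = 0, chain_id: str = "A", structure_id: str = "HELX"
) -> StructureModel:
    """Ideal alpha-helical C-alpha trace (rise 1.5 A, 100 deg/res, r 2.3 A)."""
    if n_res < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    chain = ChainModel(chain_id=chain_id)
    for i in range(n_res):
        theta = np.deg2rad(HELIX_TWIST * i)
        xyz = np.array(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
        chain.modeled_residues.append(
            Residue(i + 1, "", "ALA", [_ca_atom(i + 1, chain_id, i + 1, xyz)])
        )
    chain.seqres = ["ALA"] * n_res
    return StructureModel(id=structure_id, chains=[chain])


def make_transformed_copy(
    struct: StructureModel,
    rotation_deg: float = 0.0,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Rigidly transformed (and optionally noised) copy with planted truth."""
    if not struct.chains:
        raise ValueError("structure has no chains")
    R = rotation_about_axis(np.array(axis), rotation_deg)
    t = np.asarray(translation, dtype=float)
    rng = np.random.default_rng(seed)
    chains = []
    for chain in struct.chains:
        new_chain = ChainModel(chain_id=chain.chain_id, seqres=list(chain.seqres))
        for residue in chain.modeled_residues:
            atoms = []
            for a in residue.atoms:
                xyz = R @ np.array(a.coords) + t
                if noise_sigma > 0:
                    xyz = xyz + rng.normal(0.0, noise_sigma, size=3)
                atoms.append(
                    AtomRecord(
                        a.serial, a.name, a.altloc, a.resname, a.chain_id,
                        a.resseq, a.icode,
                        float(xyz[0]), float(xyz[1]), float(xyz[2]),
                        a.occupancy, a.bfactor, a.element, a.is_hetatm,
                    )
                )
            new_chain.modeled_residues.append(
                Residue(residue.resseq, residue.icode, residue.resname, atoms)
            )
        chains.append(new_chain)
    meta = {
        "rotation_deg": rotation_deg,
        "axis": list(axis),
        "translation": list(translation),
        "noise_sigma": noise_sigma,
        "seed": seed,
        "rotation_matrix": R.tolist(),
    }
    copy = StructureModel(id=struct.id + "C", chains=chains, cell=struct.cell)
    return copy, meta


def make_dimer_structure(
    n_res: int,
    seed: int = 0,
    distinguishable: bool = False,
    structure_id: str = "DIMR",
) -> StructureModel:
    """Two-chain fixture: chain A helix plus a rotated/translated chain B.

    With ``distinguishable`` the B chain is shorter so the two chains carry
    different sequences of residue counts and chain pairing is detectable.
    """
    a = make_helix_structure(n_res, seed=seed, chain_id="A", structure_id=structure_id)
    n_b = max(4, n_res - 10) if distinguishable else n_res
    b = make_helix_structure(n_b, seed=seed, chain_id="B")
    moved, _ = make_transformed_copy(
        b, rotation_deg=180.0, axis=(1.0, 0.0, 0.0), translation=(12.0, 0.0, 0.0)
    )
    moved.chains[0].chain_id = "B"
    for residue in moved.chains[0].modeled_residues:
        for atom in residue.atoms:
            atom.chain_id = "B"
    return StructureModel(id=structure_id, chains=[a.chains[0], moved.chains[0]])


def make_gsh_like_ligand(seed: int = 0, resseq: int = 401) -> Residue:
    """20-heavy-atom ligand named per the GSH component, plausible bonds.

    Atoms are placed by a seeded chain walk keeping every bonded pair at
    its target length (1.2-1.8 A); geometry is toy, topology is exact.
    """
    rng = np.random.default_rng(seed)
    pos: dict[str, np.ndarray] = {"N1": np.zeros(3)}
    for parent, child, length in GSH_BONDS:
        while True:
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm < 1e-8:
                continue
            candidate = pos[parent] + direction / norm * length
            # keep non-bonded atoms from collapsing onto each other
            if all(
                np.linalg.norm(candidate - p) > 1.1
                for name, p in pos.items()
                if name != parent
            ):
                pos[child] = candidate
                break
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            altloc="",
            resname="GSH",
            chain_id="L",
            resseq=resseq,
            icode="",
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            occupancy=1.0,
            bfactor=0.0,
            element="S" if name.startswith("S") else name[0],
            is_hetatm=True,
        )
        for i, (name, p) in enumerate(pos.items())
    ]
    return Residue(resseq, "", "GSH", atoms)


def make_skewed_sequence(
    length: int,
    enriched: dict[str, float] | None = None,
    motif: str | None = None,
    motif_position: int | None = None,
    seed: int = 0,
) -> str:
    """Random protein sequence with planted composition skew and motif.

    ``enriched`` maps amino acids to target fractions; remaining mass is
    spread uniformly over the other residues.  ``motif_position`` is
    1-based.
    """
    rng = np.random.default_rng(seed)
    enriched = enriched or {}
    probs = np.full(len(AMINO_ACIDS), np.nan)
    remaining = 1.0 - sum(enriched.values())
    if remaining < 0:
        raise ValueError("enriched fractions exceed 1")
    others = [aa for aa in AMINO_ACIDS if aa not in enriched]
    for i, aa in enumerate(AMINO_ACIDS):
        probs[i] = enriched.get(aa, remaining / len(others))
    seq = list(rng.choice(list(AMINO_ACIDS), size=length, p=probs / probs.sum()))
    if motif is not None:
        if motif_position is None:
            motif_position = int(rng.integers(1, length - len(motif) + 2))
        if not 1 <= motif_position <= length - len(motif) + 1:
            raise ValueError("motif does not fit at the requested position")
        seq[motif_position - 1 : motif_position - 1 + len(motif)] = list(motif)
    return "".join(seq)


def make_sequence_family(
    tree_spec: str | SupportedTree,
    n_columns: int,
    subst_rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], SupportedTree]:
    """Evolve sequences on a known tree by per-column substitutions.

    Along each branch every column substitutes independently with
    probability min(0.95, subst_rate * branch_length) to a uniformly chosen
    different residue.  Returns the alignment and the generating tree.
    """
    if not 0 < subst_rate < 0.75:
        raise ValueError("subst_rate must be in (0, 0.75)")
    tree = parse_newick(tree_spec) if isinstance(tree_spec, str) else tree_spec
    leaves = tree.root.leaves()
    if len(leaves) < 4:
        raise ValueError("tree must have at least 4 taxa")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, len(alphabet), size=n_columns)

    msa: dict[str, str] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        p = min(0.95, subst_rate * node.length)
        if p > 0:
            hit = rng.random(n_columns) < p
            if hit.any():
                seq = seq.copy()
                shift = rng.integers(1, len(alphabet), size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % len(alphabet)
        if node.is_leaf:
            msa[node.name] = "".join(alphabet[seq])
        else:
            for child in node.children:
                evolve(child, seq)

    for child in tree.root.children:
        evolve(child, root_seq)
    return msa, tree
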
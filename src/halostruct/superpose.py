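"""Sequence-alignment-driven rigid-body superposition.

Monomer and dimer C-alpha superpositions with iterative outlier rejection,
reporting RMSD, the number of aligned pairs retained, and pairwise sequence
identity over aligned non-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import ChainModel, StructureModel, chain_sequence

__all__ = [
    "ResiduePairing",
    "SuperpositionResult",
    "align_sequences",
    "kabsch",
    "superpose_monomer",
    "superpose_dimer",
]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_CYCLES = 5
DEFAULT_REJECT_FACTOR = 2.0


@dataclass
class ResiduePairing:
    """One-to-one, order-preserving aligned residue index pairs (0-based)."""

    pairs: list[tuple[int, int]]
    identity_percent: float


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    n_aligned: int
    n_rejected: int
    identity_percent: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from the mobile frame into the target frame."""
        return coords @ self.rotation.T + self.translation


def align_sequences(
    seq_a: str,
    seq_b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ResiduePairing:
    """Global alignment with affine gaps; identity over aligned columns.

    identity_percent = 100 * identical pairs / aligned (non-gap) columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            i, j = a_start + offset, b_start + offset
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                identical += 1
    if not pairs:
        return ResiduePairing(pairs=[], identity_percent=0.0)
    return ResiduePairing(pairs=pairs, identity_percent=100.0 * identical / len(pairs))


def kabsch(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Least-squares optimal proper rotation/translation mapping b onto a.

    Returns (rotation, translation, rmsd, degenerate).  The reflection
    branch is corrected so det(rotation) = +1.  ``degenerate`` flags
    near-collinear input for which the rotation is not unique.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    H = bb.T @ aa
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rotation = Vt.T @ D @ U.T
    translation = cen_a - rotation @ cen_b
    diff = (bb @ rotation.T) - aa
    rmsd = float(np.sqrt((diff**2).sum() / n))
    # collinear (or coplanar-degenerate) input: second singular value ~ 0
    degenerate = bool(S[1] <= max(1e-8, 1e-10 * S[0]))
    return rotation, translation, rmsd, degenerate


def _refine(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cycles: int,
    reject_factor: float,
) -> tuple[np.ndarray, np.ndarray, float, int, int, bool]:
    """Kabsch fit with iterative rejection of pairs > reject_factor * rmsd."""
    keep = np.ones(len(coords_a), dtype=bool)
    rotation, translation, rmsd, degenerate = kabsch(coords_a, coords_b)
    for _ in range(cycles):
        mapped = coords_b @ rotation.T + translation
        dev = np.linalg.norm(mapped - coords_a, axis=1)
        cutoff = reject_factor * rmsd
        new_keep = keep & (dev <= cutoff)
        if new_keep.sum() < 3:
            break
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
        rotation, translation, rmsd, degenerate = kabsch(
            coords_a[keep], coords_b[keep]
        )
    n_aligned = int(keep.sum())
    return rotation, translation, rmsd, n_aligned, len(coords_a) - n_aligned, degenerate


def _ca_pairs(
    chain_a: ChainModel, chain_b: ChainModel, pairing: ResiduePairing
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of aligned residue pairs where both have a CA atom."""
    xs, ys = [], []
    for i, j in pairing.pairs:
        ra = chain_a.modeled_residues[i] if i < len(chain_a.modeled_residues) else None
        rb = chain_b.modeled_residues[j] if j < len(chain_b.modeled_residues) else None
        if ra is None or rb is None:
            continue
        ca_a, ca_b = ra.atom("CA"), rb.atom("CA")
        if ca_a is None or ca_b is None:
            continue
        xs.append(ca_a.coords)
        ys.append(ca_b.coords)
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


def superpose_monomer(
    struct_a: StructureModel,
    chain_a: str,
    struct_b: StructureModel,
    chain_b: str,
    cycles: int = DEFAULT_CYCLES,
    reject_factor: float = DEFAULT_REJECT_FACTOR,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SuperpositionResult:
    """Superpose chain_b of struct_b onto chain_a of struct_a (C-alpha only)."""
    ca = struct_a.chain(chain_a)
    cb = struct_b.chain(chain_b)
    pairing = align_sequences(
        chain_sequence(ca, "modeled"),
        chain_sequence(cb, "modeled"),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )
    xa, xb = _ca_pairs(ca, cb, pairing)
    if len(xa) < 3:
        raise ValueError("fewer than 3 alignable C-alpha pairs")
    rot, trans, rmsd, n_aligned, n_rejected, degen = _refine(
        xa, xb, cycles, reject_factor
    )
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        n_aligned=n_aligned,
        n_rejected=n_rejected,
        identity_percent=pairing.identity_percent,
        degenerate=degen,
    )


def superpose_dimer(
    struct_a: StructureModel,
    chains_a: tuple[str, str],
    struct_b: StructureModel,
    chains_b: tuple[str, str],
    cycles: int = DEFAULT_CYCLES,
    reject_factor: float = DEFAULT_REJECT_FACTOR,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SuperpositionResult:
    """Superpose two dimers as concatenated C-alpha sets.

    Both chain-to-chain pairings (AB<->A'B' and AB<->B'A') are evaluated and
    the lower-RMSD one reported.  Residue pairing stays within each
    chain-to-chain alignment; no inter-chain pairing.
    """
    best: SuperpositionResult | None = None
    for cb_pair in (chains_b, (chains_b[1], chains_b[0])):
        xs, ys = [], []
        identities, weights = [], []
        ok = True
        for ca_id, cb_id in zip(chains_a, cb_pair):
            ca = struct_a.chain(ca_id)
            cb = struct_b.chain(cb_id)
            pairing = align_sequences(
                chain_sequence(ca, "modeled"),
                chain_sequence(cb, "modeled"),
                matrix=matrix,
                gap_open=gap_open,
                gap_extend=gap_extend,
            )
            xa, xb = _ca_pairs(ca, cb, pairing)
            if len(xa) == 0:
                ok = False
                break
            xs.append(xa)
            ys.append(xb)
            identities.append(pairing.identity_percent)
            weights.append(len(pairing.pairs))
        if not ok:
            continue
        xa = np.vstack(xs)
        xb = np.vstack(ys)
        if len(xa) < 3:
            continue
        rot, trans, rmsd, n_aligned, n_rejected, degen = _refine(
            xa, xb, cycles, reject_factor
        )
        identity = float(np.average(identities, weights=weights))
        result = SuperpositionResult(
            rotation=rot,
            translation=trans,
            rmsd=rmsd,
            n_aligned=n_aligned,
            n_rejected=n_rejected,
            identity_percent=identity,
            degenerate=degen,
        )
        if best is None or result.rmsd < best.rmsd:
            best = result
    if best is None:
        raise ValueError("no chain pairing yields at least 3 alignable pairs")
    return best
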
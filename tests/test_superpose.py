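import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from halostruct.superpose import (
    align_sequences,
    kabsch,
    superpose_dimer,
    superpose_monomer,
)
from halostruct.synthetic_data import (
    make_dimer_structure,
    make_helix_structure,
    make_transformed_copy,
    rotation_about_axis,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(seq_a, seq_b, gap_open=10.0, gap_extend=0.5):
    """Enumerate every global alignment of two short sequences and score it.

    Affine convention matching the implementation's aligner: a gap of
    length L costs open + (L - 1) * extend, end gaps included.
    """
    best = -np.inf
    n, m = len(seq_a), len(seq_b)

    def score(columns):
        total, prev = 0.0, None
        for ca, cb in columns:
            if ca == "-" or cb == "-":
                state = "a" if ca == "-" else "b"
                total -= gap_open if state != prev else gap_extend
                prev = state
            else:
                total += BLOSUM62[ca, cb]
                prev = None
        return total

    def walk(i, j, columns):
        nonlocal best
        if i == n and j == m:
            best = max(best, score(columns))
            return
        if i < n and j < m:
            walk(i + 1, j + 1, columns + [(seq_a[i], seq_b[j])])
        if i < n:
            walk(i + 1, j, columns + [(seq_a[i], "-")])
        if j < m:
            walk(i, j + 1, columns + [("-", seq_b[j])])

    walk(0, 0, [])
    return best


def aligner_score(seq_a, seq_b):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner.score(seq_a, seq_b)


class TestAlignSequences:
    def test_identical_sequences(self):
        pairing = align_sequences("MKVLAW", "MKVLAW")
        assert pairing.identity_percent == pytest.approx(100.0)
        assert [tuple(p) for p in pairing.pairs] == [(i, i) for i in range(6)]

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_sequences("", "MKV")

    def test_identity_symmetric(self):
        a, b = "MKVAWDEQ", "MKAWPDQ"
        assert align_sequences(a, b).identity_percent == pytest.approx(
            align_sequences(b, a).identity_percent
        )

    @pytest.mark.parametrize(
        "seq_a,seq_b",
        [
            ("MKV", "MV"),
            ("ACDEF", "ADF"),
            ("WWWW", "WAW"),
            ("MKVLAW", "KVAW"),
            ("HHHH", "HH"),
        ],
    )
    def test_matches_brute_force_enumeration(self, seq_a, seq_b):
        assert aligner_score(seq_a, seq_b) == pytest.approx(
            brute_force_best_score(seq_a, seq_b)
        )

    def test_pairing_one_to_one_and_monotone(self):
        pairing = align_sequences("MKVLAWDEQRI", "MKAWDQRI")
        a_idx = [p[0] for p in pairing.pairs]
        b_idx = [p[1] for p in pairing.pairs]
        assert a_idx == sorted(a_idx) and len(set(a_idx)) == len(a_idx)
        assert b_idx == sorted(b_idx) and len(set(b_idx)) == len(b_idx)


class TestKabsch:
    def test_identical_point_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd, degen = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert rot == pytest.approx(np.eye(3), abs=1e-10)
        assert not degen

    def test_planted_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0)
        # construct b such that R @ b + t = a
        t = np.array([1.0, 2.0, 3.0])
        b = np.linalg.solve(R, (a - t).T).T
        rot, trans, rmsd, _ = kabsch(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert rot == pytest.approx(R, abs=1e-8)
        assert trans == pytest.approx(t, abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        z = np.linspace(0, 10, 5)
        pts = np.column_stack([np.zeros(5), np.zeros(5), z])
        *_, degen = kabsch(pts, pts)
        assert degen

    def test_reflection_not_returned(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored set
        rot, *_ = kabsch(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_noise_recovery(self):
        # mean fitted RMSD over replicates approaches sqrt(3) * sigma
        rng = np.random.default_rng(3)
        sigma = 0.5
        rmsds = []
        for _ in range(200):
            a = rng.normal(size=(100, 3)) * 10
            axis = rng.normal(size=3)
            R = rotation_about_axis(axis, rng.uniform(0, 360))
            t = rng.normal(size=3) * 5
            b = np.linalg.solve(R, (a - t).T).T
            a_noisy = a + rng.normal(0, sigma, size=a.shape)
            *_, rmsd, _ = kabsch(a_noisy, b)
            rmsds.append(rmsd)
        assert np.mean(rmsds) == pytest.approx(np.sqrt(3) * sigma, rel=0.05)

    def test_matches_rotation_grid_search(self):
        # coarse-to-1-degree Euler grid search as an independent optimum check
        rng = np.random.default_rng(4)
        for _ in range(3):
            a = rng.normal(size=(4, 3))
            b = rng.normal(size=(4, 3))
            *_, rmsd_kabsch, _ = kabsch(a, b)
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)

            def grid_rmsd(alphas, betas, gammas):
                best = np.inf
                for al, be, ga in itertools.product(alphas, betas, gammas):
                    Rz1 = rotation_about_axis(np.array([0, 0, 1.0]), al)
                    Ry = rotation_about_axis(np.array([0, 1.0, 0]), be)
                    Rz2 = rotation_about_axis(np.array([0, 0, 1.0]), ga)
                    R = Rz1 @ Ry @ Rz2
                    d = bc @ R.T - ac
                    val = np.sqrt((d**2).sum() / len(ac))
                    if val < best:
                        best, best_angles = val, (al, be, ga)
                return best, best_angles

            coarse = np.arange(0, 360, 10.0)
            coarse_b = np.arange(0, 180.0001, 10.0)
            _, (al, be, ga) = grid_rmsd(coarse, coarse_b, coarse)
            fine, _ = grid_rmsd(
                np.arange(al - 10, al + 10.5, 1.0),
                np.arange(be - 10, be + 10.5, 1.0),
                np.arange(ga - 10, ga + 10.5, 1.0),
            )
            assert rmsd_kabsch <= fine + 1e-9
            assert fine - rmsd_kabsch < 0.05


def _angle_between_rotations(r1, r2):
    cos = (np.trace(r1.T @ r2) - 1) / 2
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


class TestSuperposeMonomer:
    def test_self_superposition(self):
        model = make_helix_structure(40)
        result = superpose_monomer(model, "A", model, "A")
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)
        assert result.n_rejected == 0
        assert result.identity_percent == pytest.approx(100.0)

    def test_planted_rotation_recovered_under_noise(self):
        model = make_helix_structure(60)
        moved, meta = make_transformed_copy(
            model, rotation_deg=40.0, axis=(1, 2, 3),
            translation=(4, 5, 6), noise_sigma=0.1, seed=5,
        )
        result = superpose_monomer(model, "A", moved, "A")
        planted = np.array(meta["rotation_matrix"])
        # recovered transform maps moved -> model: inverse of the planted one
        assert _angle_between_rotations(result.rotation, planted.T) < 1.0

    def test_rigid_invariance_of_rmsd(self):
        model = make_helix_structure(50)
        noisy, _ = make_transformed_copy(model, noise_sigma=0.3, seed=6)
        base = superpose_monomer(model, "A", noisy, "A").rmsd
        shifted, _ = make_transformed_copy(
            noisy, rotation_deg=120.0, axis=(0, 1, 0), translation=(9, -4, 2)
        )
        assert superpose_monomer(model, "A", shifted, "A").rmsd == pytest.approx(
            base, abs=1e-6
        )

    def test_invariant_pair_accounting(self):
        model = make_helix_structure(50)
        noisy, _ = make_transformed_copy(model, noise_sigma=0.8, seed=8)
        result = superpose_monomer(model, "A", noisy, "A")
        assert result.n_aligned + result.n_rejected == 50
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_outlier_rejection_reduces_rmsd(self):
        model = make_helix_structure(50)
        noisy, _ = make_transformed_copy(model, noise_sigma=0.2, seed=9)
        # corrupt a few residues hard
        for residue in noisy.chains[0].modeled_residues[::10]:
            for atom in residue.atoms:
                atom.x += 8.0
        no_reject = superpose_monomer(model, "A", noisy, "A", cycles=0)
        with_reject = superpose_monomer(model, "A", noisy, "A", cycles=5)
        assert with_reject.rmsd < no_reject.rmsd
        assert with_reject.n_rejected > 0


class TestSuperposeDimer:
    def test_self_with_swapped_chains(self):
        model = make_dimer_structure(30)
        result = superpose_dimer(model, ("A", "B"), model, ("B", "A"))
        assert result.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_planted_pairing_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = make_dimer_structure(40, distinguishable=True)
            moved, _ = make_transformed_copy(
                model,
                rotation_deg=float(rng.uniform(0, 360)),
                axis=tuple(rng.normal(size=3)),
                translation=tuple(rng.normal(size=3) * 10),
                noise_sigma=0.2,
                seed=seed,
            )
            direct = superpose_dimer(model, ("A", "B"), moved, ("A", "B"))
            swapped = superpose_dimer(model, ("A", "B"), moved, ("B", "A"))
            # the pairing search must find the same (correct) answer both ways
            if abs(direct.rmsd - swapped.rmsd) < 1e-6 and direct.rmsd < 1.0:
                hits += 1
        assert hits == 50

    def test_lower_rmsd_pairing_reported(self):
        model = make_dimer_structure(40, distinguishable=True)
        moved, _ = make_transformed_copy(model, rotation_deg=75.0, axis=(1, 1, 0))
        result = superpose_dimer(model, ("A", "B"), moved, ("A", "B"))
        assert result.rmsd == pytest.approx(0.0, abs=1e-8)
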
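import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from halostruct.phylo import (
    DistanceMatrix,
    SupportedTree,
    TreeNode,
    bipartitions,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    parse_newick,
    robinson_foulds,
    write_newick,
)
from halostruct.synthetic_data import make_sequence_family


def random_additive_tree(n_taxa, rng):
    """Random binary tree as nested tuples with branch lengths.

    Independent oracle: leaf-to-leaf path lengths define an additive matrix.
    """
    nodes = [(f"T{i}", 0.0) for i in range(n_taxa)]  # (subtree, stem length)
    items = [((name, None), float(rng.uniform(0.1, 1.0))) for name, _ in nodes]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(((a, b), float(rng.uniform(0.1, 1.0))))
    return items[0]


def additive_matrix(tree):
    """Distances via explicit path enumeration from the root."""
    paths: dict[str, list] = {}

    def walk2(subtree, edges):
        node, _ = subtree
        if isinstance(node[0], str) and node[1] is None:
            paths[node[0]] = edges
            return
        for child in node:
            walk2(child, edges + [(id(child), child[1])])

    walk2(tree, [])
    taxa = sorted(paths)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei = dict(paths[taxa[i]])
            ej = dict(paths[taxa[j]])
            shared = set(ei) & set(ej)
            dist = sum(v for k, v in ei.items() if k not in shared) + sum(
                v for k, v in ej.items() if k not in shared
            )
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


def tree_leaf_distances(tree: SupportedTree):
    """Path-length matrix of an inferred tree (test-side traversal)."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
            return
        for child in node.children:
            walk(child, acc + [(id(child), child.length)])

    walk(tree.root, [])
    taxa = sorted(dists)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = dict(dists[taxa[i]]), dict(dists[taxa[j]])
            shared = set(ei) & set(ej)
            val = sum(v for k, v in ei.items() if k not in shared) + sum(
                v for k, v in ej.items() if k not in shared
            )
            d[i, j] = d[j, i] = val
    return taxa, d


class TestPDistance:
    def test_identical_sequences_zero(self):
        msa = {"a": "ACDE", "b": "ACDE", "c": "ACDE"}
        assert (p_distance_matrix(msa).d == 0).all()

    def test_one_mismatch_in_four(self):
        msa = {"a": "ACDE", "b": "ACDF", "c": "ACDE"}
        dm = p_distance_matrix(msa)
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_denominator(self):
        msa = {"a": "AC-E", "b": "ACDE", "c": "ACDE"}
        dm = p_distance_matrix(msa)
        assert dm.d[0, 1] == pytest.approx(0.0)  # 0 mismatches / 3 columns
        msa2 = {"a": "AC-E", "b": "ACDF", "c": "ACDE"}
        assert p_distance_matrix(msa2).d[0, 1] == pytest.approx(1 / 3)

    def test_all_gap_pair_errors(self):
        msa = {"a": "--", "b": "AC", "c": "AC"}
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(msa)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AC", "b": "AC"})


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_five_taxon_recovery(self, seed):
        rng = np.random.default_rng(seed)
        gen = random_additive_tree(5, rng)
        dm = additive_matrix(gen)
        tree = nj_tree(dm)
        taxa, d = tree_leaf_distances(tree)
        assert taxa == dm.taxa
        assert d == pytest.approx(dm.d, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_eight_taxon_recovery(self, seed):
        rng = np.random.default_rng(100 + seed)
        gen = random_additive_tree(8, rng)
        dm = additive_matrix(gen)
        tree = nj_tree(dm)
        _, d = tree_leaf_distances(tree)
        assert d == pytest.approx(dm.d, abs=1e-9)

    def test_four_taxon_least_squares_oracle(self):
        # NJ must pick the least-squares-best of the 3 unrooted topologies
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(100):
            gen = random_additive_tree(4, rng)
            dm = additive_matrix(gen)
            noise = rng.normal(0, 0.01, size=dm.d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            d = np.clip(dm.d + noise, 0.001, None)
            np.fill_diagonal(d, 0.0)
            dm_noisy = DistanceMatrix(dm.taxa, d)
            nj = nj_tree(dm_noisy)
            nj_split = next(iter(bipartitions(nj)), None)

            # brute-force: least-squares branch fit for each topology
            # topology encoded by which taxon pairs are cherries
            best_topo, best_res = None, np.inf
            pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            for (a, b), (c, e) in pairs:
                # design matrix: distances as sums of 5 branch lengths
                rows, targets = [], []
                idx = {a: 0, b: 1, c: 2, e: 3}
                for i, j in itertools.combinations(range(4), 2):
                    row = np.zeros(5)
                    row[idx[i]] = 1
                    row[idx[j]] = 1
                    same_cherry = {i, j} in ({a, b}, {c, e})
                    if not same_cherry:
                        row[4] = 1
                    rows.append(row)
                    targets.append(d[i, j])
                sol, res = nnls(np.array(rows), np.array(targets))
                if res < best_res:
                    best_res = res
                    best_topo = frozenset({dm.taxa[a], dm.taxa[b]})
            anchor = min(dm.taxa)
            if nj_split is not None:
                canonical = (
                    best_topo
                    if anchor not in best_topo
                    else frozenset(dm.taxa) - best_topo
                )
                if nj_split == canonical:
                    agree += 1
        assert agree == 100

    def test_negative_branch_clamped(self):
        # matrix engineered to give a negative NJ branch length
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.45],
                [0.1, 0.0, 0.45, 0.4],
                [0.4, 0.45, 0.0, 0.1],
                [0.45, 0.4, 0.1, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        for node in tree.root.leaves():
            assert node.length >= 0

        def all_lengths(node):
            yield node.length
            for c in node.children:
                yield from all_lengths(c)

        assert all(v >= 0 for v in all_lengths(tree.root))


class TestBootstrap:
    def test_planted_signal_high_support(self):
        newick = "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5,(E:0.05,F:0.05):0.5);"
        msa, _ = make_sequence_family(newick, 500, 0.7, seed=3)
        tree = bootstrap_support(msa, n_reps=100, seed=4)
        supports = [
            node.support
            for node in bipartitions(tree).values()
            if node.support is not None
        ]
        assert supports and min(supports) >= 99.0

    def test_deterministic_under_seed(self):
        msa, _ = make_sequence_family(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);", 200, 0.5, seed=5
        )
        t1 = bootstrap_support(msa, n_reps=50, seed=9)
        t2 = bootstrap_support(msa, n_reps=50, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_taxon_order_invariance(self):
        msa, _ = make_sequence_family(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);", 300, 0.5, seed=6
        )
        reordered = dict(reversed(list(msa.items())))
        t1 = nj_tree(p_distance_matrix(msa))
        t2 = nj_tree(p_distance_matrix(reordered))
        assert robinson_foulds(t1, t2) == 0

    def test_threshold_masks_display_only(self):
        root = TreeNode(
            children=[
                TreeNode(
                    support=39.0,
                    length=0.1,
                    children=[
                        TreeNode(name="A", length=0.1),
                        TreeNode(name="B", length=0.1),
                    ],
                ),
                TreeNode(
                    support=41.0,
                    length=0.1,
                    children=[
                        TreeNode(name="C", length=0.1),
                        TreeNode(name="D", length=0.1),
                    ],
                ),
                TreeNode(name="E", length=0.2),
            ]
        )
        tree = SupportedTree(root=root, display_threshold=40.0)
        full = write_newick(tree)
        display = write_newick(tree, apply_threshold=True)
        assert "39" in full and "41" in full
        assert "39" not in display and "41" in display

    def test_n_reps_validation(self):
        msa = {"a": "ACDE", "b": "ACDF", "c": "ACDD"}
        with pytest.raises(ValueError):
            bootstrap_support(msa, n_reps=0)


class TestNewick:
    def test_three_taxon_star(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        assert write_newick(nj_tree(dm)) == "(A:0.5,B:1.5,C:2.5);"

    def test_round_trip(self):
        msa, _ = make_sequence_family(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);", 200, 0.4, seed=8
        )
        tree = bootstrap_support(msa, n_reps=20, seed=1)
        text = write_newick(tree)
        again = parse_newick(text)
        assert write_newick(again) == text
        assert robinson_foulds(tree, again) == 0

    def test_labels_with_spaces_quoted(self):
        root = TreeNode(
            children=[
                TreeNode(name="Taxon with spaces", length=0.1),
                TreeNode(name="B", length=0.2),
                TreeNode(name="C", length=0.3),
            ]
        )
        text = write_newick(SupportedTree(root=root))
        assert "'Taxon with spaces'" in text
        again = parse_newick(text)
        assert "Taxon with spaces" in again.leaf_labels()
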
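"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

Neighbor joining follows the standard Saitou-Nei agglomeration with
deterministic tie-breaking (lowest index pair) and clamping of negative
branch lengths to zero, transferring the deficit to the sister branch.
Bootstrap supports are bipartition frequencies mapped onto the
original-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SupportedTree",
    "read_alignment",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "parse_newick",
    "bipartitions",
    "robinson_foulds",
]

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SupportedTree:
    root: TreeNode
    display_threshold: float | None = None

    def leaf_labels(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]


# ---------------------------------------------------------------------------
# input

def read_alignment(path: str | Path) -> dict[str, str]:
    """Read a Clustal or aligned-FASTA alignment into {id: aligned seq}."""
    path = Path(path)
    text = path.read_text()
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in aln}


# ---------------------------------------------------------------------------
# distances

def p_distance_matrix(
    msa: dict[str, str], gap_handling: str = "pairwise-deletion"
) -> DistanceMatrix:
    """Proportion of mismatching columns, gapped columns excluded per pair."""
    if gap_handling != "pairwise-deletion":
        raise ValueError("only pairwise-deletion gap handling is supported")
    taxa = list(msa)
    if len(taxa) < 3:
        raise ValueError("at least 3 sequences are required")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    seqs = [np.frombuffer(msa[t].encode(), dtype="S1") for t in taxa]
    gap = [np.isin(s, [b"-", b"."]) for s in seqs]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gap[i] | gap[j])
            m = int(usable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            mism = int((seqs[i][usable] != seqs[j][usable]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(matrix: DistanceMatrix) -> SupportedTree:
    """Saitou-Nei neighbor joining; unrooted tree (trifurcating root).

    Ties in the Q matrix break to the lowest (i, j) index pair.  Negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new_node = TreeNode(children=[child_i, child_j])
        new_d = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_d[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_d)] = new_d
        d[: len(new_d), -1] = new_d
        nodes.append(new_node)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = max(li, 0.0), max(lj, 0.0), max(lk, 0.0)
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return SupportedTree(root=root)


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def bipartitions(tree: SupportedTree) -> dict[frozenset, TreeNode]:
    """Internal-branch bipartitions as canonical leaf-label sets.

    Each internal (non-root) branch splits the leaves; the side not
    containing the lexicographically smallest label is the canonical key.
    Trivial (single-leaf) splits are excluded.
    """
    all_labels = frozenset(tree.leaf_labels())
    anchor = min(all_labels)
    out: dict[frozenset, TreeNode] = {}

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_labels) - 1:
            key = below if anchor not in below else all_labels - below
            out[key] = node
        return below

    walk(tree.root)
    return out


def robinson_foulds(tree_a: SupportedTree, tree_b: SupportedTree) -> int:
    """Symmetric-difference distance between the internal bipartition sets."""
    ba = set(bipartitions(tree_a))
    bb = set(bipartitions(tree_b))
    return len(ba ^ bb)


def bootstrap_support(
    msa: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    threshold: float = 40.0,
) -> SupportedTree:
    """NJ tree with bootstrap supports from column resampling.

    Supports (percent of replicates containing each bipartition) are mapped
    onto the original-data NJ tree.  Values below ``threshold`` stay in the
    data and are only masked when writing with the display threshold
    applied.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(p_distance_matrix(msa))
    tree.display_threshold = threshold
    parts = bipartitions(tree)
    counts = {key: 0 for key in parts}
    taxa = list(msa)
    n_cols = len(next(iter(msa.values())))
    arr = np.array([list(msa[t]) for t in taxa])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {t: "".join(arr[i, cols]) for i, t in enumerate(taxa)}
        try:
            rep_tree = nj_tree(p_distance_matrix(resampled))
        except ValueError:
            continue  # e.g. all-gap pair in a pathological resample
        for key in bipartitions(rep_tree):
            if key in counts:
                counts[key] += 1
    for key, node in parts.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


# ---------------------------------------------------------------------------
# newick

def _format_length(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text or "0"


def _format_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: SupportedTree, apply_threshold: bool = False
) -> str:
    """Serialize to newick; supports become internal node labels.

    With ``apply_threshold`` set, supports below the tree's display
    threshold are omitted from the output (the data is untouched).
    """
    threshold = tree.display_threshold if apply_threshold else None

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if node.support is not None and not is_root:
                if threshold is None or node.support > threshold:
                    label = _format_length(node.support)
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{_format_length(node.length)}"

    return fmt(tree.root, True) + ";"


def parse_newick(text: str) -> SupportedTree:
    """Parse a newick string (supports as internal labels, quoted names)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"unbalanced parentheses at offset {pos}")
            pos += 1
            label = parse_label()
            if label:
                node.support = float(label)
        else:
            node.name = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters at offset {pos}")
    return SupportedTree(root=root)
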
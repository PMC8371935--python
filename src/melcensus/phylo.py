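"""Distance-based gene-family phylogenetics.

Trees are built from trimmed protein alignments with Kimura-corrected
distances and neighbor-joining, rooted on a designated outgroup, with
nonparametric bootstrap supports from column resampling.  This is the
package's deliberate surrogate for full maximum-likelihood inference: the
census questions asked of the trees (are the WGD-derived a- and b-paralog
clades monophyletic, where does a copy attach) are recoverable from
distances at the divergences the pipeline operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pseudogene import align_proteins
from .scoring import BLOSUM62, GLOBAL_GAP_EXT, GLOBAL_GAP_OPEN, AA_ALPHABET
from . import _kernels

KIMURA_P_MAX = 0.8537  # domain edge of the correction formula
KIMURA_CAP = 10.0


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes may carry a support."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> list[set[str]]:
        """Leaf sets of every node in the (rooted) tree."""
        out = [set(self.leaves())]
        for c in self.children:
            out.extend(c.clades())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class GeneTree:
    root: Node
    outgroup: str | None = None

    def newick(self) -> str:
        return self.root.newick()

    def leaves(self) -> list[str]:
        return self.root.leaves()


def parse_newick(text: str) -> Node:
    """Parse a newick string (names, branch lengths, internal labels)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    return parse_node()


def kimura_distance(p: float) -> float:
    """Kimura's correction for protein distance: d = -ln(1 - p - 0.2 p^2)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= KIMURA_P_MAX:
        return KIMURA_CAP
    return -math.log(1.0 - p - 0.2 * p * p)


def protein_distance(a: str, b: str, aligned: bool = True) -> float:
    """Kimura-corrected distance between two proteins.

    With ``aligned=True`` the inputs are rows of an alignment (equal
    length); columns with a gap in either row are excluded.  Otherwise the
    pair is globally aligned first.
    """
    if not aligned:
        _, a, b = align_proteins(a, b)
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    valid = diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        valid += 1
        if x != y:
            diff += 1
    if valid == 0:
        return KIMURA_CAP
    return kimura_distance(diff / valid)


def distance_matrix(rows: list[str]) -> np.ndarray:
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = protein_distance(rows[i], rows[j])
    return D


# ---------------------------------------------------------------------------
# Neighbor-joining

def nj_tree(D: np.ndarray, labels: list[str], outgroup: str | None = None) -> GeneTree:
    """Standard neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    label pair.  The unrooted result is rooted on the outgroup leaf edge
    when one is designated, else left with a trifurcating root.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name=l) for l in labels]
    names = list(labels)  # sort key per active node: smallest leaf label
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (na - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((names[i], names[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (na - 2))
        lj = D[i, j] - li
        nodes[i].length = li
        nodes[j].length = lj
        new = Node(children=[nodes[i], nodes[j]])
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            D[u, m] = D[m, u] = 0.5 * (D[i, m] + D[j, m] - D[i, j])
        nodes.append(new)
        names.append(min(names[i], names[j]))
        active = [m for m in active if m not in (i, j)] + [u]
    # join the final three
    i, j, k = sorted(active, key=lambda m: names[m])
    di = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    dj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for m, dm in ((i, di), (j, dj), (k, dk)):
        nodes[m].length = dm
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    tree = GeneTree(root, outgroup)
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def root_on_outgroup(tree: GeneTree, outgroup: str) -> GeneTree:
    """Re-root on the edge leading to the outgroup leaf (split at midpoint)."""
    if outgroup not in tree.leaves():
        raise ValueError(f"outgroup {outgroup!r} not among leaves")
    # build parent map
    parent: dict[int, Node] = {}

    def walk(node: Node) -> None:
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(tree.root)
    leaf = _find_leaf(tree.root, outgroup)
    path = [leaf]
    while id(path[-1]) in parent:
        path.append(parent[id(path[-1])])
    # reverse edges along the path from the old root down to the leaf parent
    for a in range(len(path) - 1, 1, -1):
        upper, lower = path[a], path[a - 1]
        upper.children.remove(lower)
        upper.length = lower.length
        upper.support = lower.support
        lower.children.append(upper)
    p = path[1] if len(path) > 1 else tree.root
    if leaf in p.children:
        p.children.remove(leaf)
    half = leaf.length / 2.0
    leaf.length = half
    p.length = half
    new_root = Node(children=[leaf, p])
    return GeneTree(new_root, outgroup)


def _find_leaf(node: Node, name: str) -> Node:
    if node.is_leaf:
        if node.name == name:
            return node
        raise KeyError(name)
    for c in node.children:
        try:
            return _find_leaf(c, name)
        except KeyError:
            continue
    raise KeyError(name)


def check_monophyly(tree: GeneTree, leaf_set: set[str]) -> bool:
    """True iff ``leaf_set`` is exactly the leaf set of some clade."""
    leaves = set(tree.leaves())
    unknown = set(leaf_set) - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    return set(leaf_set) in [set(c) for c in tree.root.clades()]


# ---------------------------------------------------------------------------
# Bootstrap

def _clade_sets(tree: GeneTree) -> set[frozenset[str]]:
    all_leaves = frozenset(tree.leaves())
    out = set()
    for c in tree.root.clades():
        fs = frozenset(c)
        if 1 < len(fs) < len(all_leaves):
            out.add(fs)
    return out


def _msa_distance_matrix(enc: np.ndarray, gap_code: int) -> np.ndarray:
    """Pairwise Kimura distances from an integer-encoded MSA (n, L)."""
    n = enc.shape[0]
    D = np.zeros((n, n))
    nongap = enc != gap_code
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            valid = int(both.sum())
            if valid == 0:
                D[i, j] = D[j, i] = KIMURA_CAP
                continue
            p = float((enc[i, both] != enc[j, both]).mean())
            D[i, j] = D[j, i] = kimura_distance(p)
    return D


_GAP_CODE = len(AA_ALPHABET)


def _encode_msa(rows: list[str]) -> np.ndarray:
    from .scoring import AA_INDEX

    return np.array(
        [[AA_INDEX.get(c, AA_INDEX["X"]) if c != "-" else _GAP_CODE for c in r] for r in rows],
        dtype=np.int16,
    )


def bootstrap_support(
    rows: list[str],
    labels: list[str],
    n_reps: int,
    seed: int,
    outgroup: str | None = None,
) -> GeneTree:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Replicate ``r`` uses an RNG seeded ``seed + r``; supports are the
    percentage of replicates containing each internal bipartition of the
    point-estimate tree.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 rows")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = _encode_msa(rows)
    L = enc.shape[1]
    point = nj_tree(_msa_distance_matrix(enc, _GAP_CODE), labels, outgroup)
    counts: dict[frozenset[str], int] = {c: 0 for c in _clade_sets(point)}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(_msa_distance_matrix(enc[:, cols], _GAP_CODE), labels, outgroup)
        rep_clades = _clade_sets(rep)
        for c in counts:
            if c in rep_clades:
                counts[c] += 1

    def annotate(node: Node) -> None:
        if not node.is_leaf:
            fs = frozenset(node.leaves())
            if fs in counts:
                node.support = 100.0 * counts[fs] / n_reps
            for c in node.children:
                annotate(c)

    annotate(point.root)
    return point


def write_phylip(rows: list[str], labels: list[str], path) -> None:
    """Adapter: export a trimmed alignment in relaxed PHYLIP for external
    ML tools (not exercised by the pipeline itself)."""
    with open(path, "w") as fh:
        fh.write(f" {len(rows)} {len(rows[0])}\n")
        width = max(len(l) for l in labels) + 2
        for lab, row in zip(labels, rows):
            fh.write(f"{lab:<{width}}{row}\n")


# ---------------------------------------------------------------------------
# Progressive multiple alignment

def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 24-letter alphabet (gaps excluded)."""
    L = len(rows[0])
    prof = np.zeros((L, len(AA_ALPHABET)))
    from .scoring import AA_INDEX

    for r in rows:
        for c, ch in enumerate(r):
            if ch != "-":
                prof[c, AA_INDEX.get(ch, AA_INDEX["X"])] += 1
    occ = prof.sum(axis=1, keepdims=True)
    occ[occ == 0] = 1
    return prof / occ


def _merge(rows_a: list[str], rows_b: list[str]) -> list[str]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    smat = pa @ BLOSUM62.astype(float) @ pb.T
    _, npath, pi, pj = _kernels.nw_affine_matrix(
        smat, float(GLOBAL_GAP_OPEN + GLOBAL_GAP_EXT), float(GLOBAL_GAP_EXT)
    )
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for k in range(npath):
        i, j = pi[k], pj[k]
        for r, row in enumerate(rows_a):
            out_a[r] += row[i] if i >= 0 else "-"
        for r, row in enumerate(rows_b):
            out_b[r] += row[j] if j >= 0 else "-"
    return out_a + out_b


def progressive_msa(seqs: dict[str, str]) -> tuple[list[str], list[str]]:
    """Progressive multiple alignment over a UPGMA guide tree.

    Pairwise Kimura distances from global alignments feed average-linkage
    clustering; profiles are merged by profile-profile global alignment
    with sum-of-pairs BLOSUM62 scoring.  Returns (labels, aligned rows).
    """
    labels = sorted(seqs)
    if len(labels) == 1:
        return labels, [seqs[labels[0]]]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = protein_distance(seqs[labels[i]], seqs[labels[j]], aligned=False)
    if n == 2:
        _, a, b = align_proteins(seqs[labels[0]], seqs[labels[1]])
        return labels, [a, b]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [seqs[labels[i]]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        la, ra = groups.pop(int(a))
        lb, rb = groups.pop(int(b))
        merged = _merge(ra, rb)
        groups[n + step] = (la + lb, merged)
    (names, rows), = groups.values()
    order = [names.index(l) for l in labels]
    return labels, [rows[i] for i in order]
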
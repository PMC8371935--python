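"""Independent reference implementations used to verify the pipeline.

These deliberately avoid the package's own DP kernels: pairwise alignment
oracles run through Biopython's C aligner, the spliced-alignment oracle is
a plain-Python dynamic program, and tree oracles work from first
principles (path metrics on explicitly constructed trees, four-point
condition enumeration).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from melcensus.core_io import reverse_complement, translate
from melcensus.genemodel import FRAMESHIFT_PENALTY, INTRON_OPEN, MIN_INTRON
from melcensus.scoring import AA_INDEX, BLOSUM62

_B62 = substitution_matrices.load("BLOSUM62")


def local_aligner(open_cost: int = 11, ext: int = 1) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = _B62
    a.open_gap_score = -(open_cost + ext)
    a.extend_gap_score = -ext
    a.mode = "local"
    return a


def global_aligner(open_cost: int = 10, ext: int = 1) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = _B62
    a.open_gap_score = -(open_cost + ext)
    a.extend_gap_score = -ext
    a.mode = "global"
    return a


def sw6_best_score(query: str, contig: str) -> float:
    """Best six-frame Smith-Waterman score of a protein vs a DNA contig."""
    aligner = local_aligner()
    best = 0.0
    for src in (contig, reverse_complement(contig)):
        for off in range(3):
            tr = translate(src, off)
            if len(tr) >= 4:
                best = max(best, aligner.score(query, tr))
    return best


_NEG = -(10**8)


def spliced_best_score(
    query: str,
    dna: str,
    go: int = 12,
    ge: int = 1,
    intron_open: int = INTRON_OPEN,
    fs: int = FRAMESHIFT_PENALTY,
    min_intron: int = MIN_INTRON,
) -> int:
    """Reference spliced-alignment DP (score only, plain Python).

    Same model as the production kernel — codon matches, affine residue
    gaps, GT..AG introns with a fixed opening cost, 1-2 bp codon-boundary
    slips — re-derived independently from the model definition.
    """
    n, m = len(query), len(dna)
    x = AA_INDEX["X"]
    q = [AA_INDEX.get(c, x) for c in query]
    aa = [-1] * (m + 1)
    for j in range(3, m + 1):
        aa[j] = AA_INDEX.get(translate(dna[j - 3 : j]) or "X", x)
    donor = [dna[j : j + 2] == "GT" for j in range(m + 1)]
    acc = [j >= 2 and dna[j - 2 : j] == "AG" for j in range(m + 1)]
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Dm = [_NEG] * (n + 1)
    best = 0
    for j in range(m + 1):
        jd = j - min_intron
        if jd >= 0 and donor[jd]:
            for i in range(n + 1):
                if M[i][jd] > Dm[i]:
                    Dm[i] = M[i][jd]
        if acc[j]:
            for i in range(n + 1):
                if Dm[i] > _NEG:
                    I[i][j] = Dm[i] - intron_open
        for i in range(1, n + 1):
            if j >= 3:
                Y[i][j] = max(M[i][j - 3] - go, Y[i][j - 3] - ge)
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            if aa[j] >= 0:
                s = int(BLOSUM62[q[i - 1], aa[j]])
                bv = 0
                for d, pen in ((3, 0), (2, fs), (4, fs), (1, fs), (5, fs)):
                    jp = j - d
                    if jp < 0:
                        continue
                    v = max(M[i - 1][jp], X[i - 1][jp], Y[i - 1][jp], I[i - 1][jp]) - pen
                    if v > bv:
                        bv = v
                M[i][j] = s + bv
                if M[i][j] > best:
                    best = M[i][j]
    return best


# ---------------------------------------------------------------------------
# tree oracles

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random topology with positive branch lengths; returns (labels, D, splits).

    Built by attaching leaves to random edges of a growing unrooted tree;
    distances are explicit path sums, splits the non-trivial bipartitions.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with edge lengths; nodes 0..n_taxa-1 are leaves
    edges: dict[tuple[int, int], float] = {}
    nxt = n_taxa

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    add_edge(0, nxt, blen())
    add_edge(1, nxt, blen())
    add_edge(2, nxt, blen())
    nxt += 1
    for leaf in range(3, n_taxa):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        mid = nxt
        nxt += 1
        f = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * f)
        add_edge(v, mid, w * (1 - f))
        add_edge(leaf, mid, blen())
    # all-pairs path lengths by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            D[i, j] = di[j]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    splits = set()
    for (a, b) in edges:
        # leaves on the 'a' side of edge (a,b)
        seen = {b}
        stack = [a]
        side = set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            if u < n_taxa:
                side.add(labels[u])
            for v, _ in adj[u]:
                if v not in seen:
                    stack.append(v)
        if 1 < len(side) < n_taxa - 1:
            splits.add(frozenset(side))
    return labels, D, _canonical_splits(splits, labels)


def _canonical_splits(splits, labels):
    ref = labels[0]
    full = set(labels)
    out = set()
    for s in splits:
        side = set(s)
        if ref in side:
            side = full - side
        if 1 < len(side) < len(labels) - 1:
            out.add(frozenset(side))
    return out


def tree_splits(node, labels):
    """Non-trivial bipartitions of one of the package's tree nodes."""
    splits = set()

    def walk(n):
        if n.is_leaf:
            return
        s = frozenset(n.leaves())
        if 1 < len(s) < len(labels) - 1:
            splits.add(s)
        for c in n.children:
            walk(c)

    walk(node)
    return _canonical_splits(splits, labels)


def four_taxon_split_oracle(D: np.ndarray, labels):
    """Enumerate the three unrooted 4-taxon topologies; pick the additive one.

    Under the four-point condition the correct split {x,y}|{z,w} minimises
    d(x,y)+d(z,w).
    """
    best = None
    for (i, j) in itertools.combinations(range(4), 2):
        k, l = [m for m in range(4) if m not in (i, j)]
        s = D[i, j] + D[k, l]
        if best is None or s < best[0]:
            best = (s, frozenset({labels[i], labels[j]}))
    side = set(best[1])
    if labels[0] in side:
        side = set(labels) - side
    return frozenset(side)
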
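"""Distance-based phylogeny of the deduced proteins.

Pairwise global (Needleman–Wunsch) alignment with linear gap costs
feeds a p-distance matrix (gap columns excluded), from which a
neighbor-joining tree is built with the classical Q-criterion
agglomeration.  On an additive distance matrix NJ recovers the unique
generating tree with exact branch lengths.  A purity check then asks,
for each locus, whether some edge bipartition of the unrooted tree
separates exactly that locus's leaves.

The tree and distance-matrix containers are scikit-bio objects
(``TreeNode``, ``DistanceMatrix``); the alignment and NJ algorithms are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode


def global_align(
    seq1: str,
    seq2: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment under linear gap scoring.

    Returns the two aligned strings (equal length, ``-`` for gaps) and
    the optimal score.  Traceback preference is diagonal, then up
    (gap in ``seq2``), then left — deterministic among co-optimal paths.
    """
    if not seq1 or not seq2:
        raise ValueError("sequences must be non-empty")
    a = np.frombuffer(seq1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq2.encode("ascii"), dtype=np.uint8)
    m, n = len(a), len(b)
    F = np.empty((m + 1, n + 1), dtype=np.float64)
    F[0, :] = gap * np.arange(n + 1)
    F[:, 0] = gap * np.arange(m + 1)
    j_idx = np.arange(1, n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        subst = np.where(b == a[i - 1], match, mismatch)
        cand = np.maximum(F[i - 1, :-1] + subst, F[i - 1, 1:] + gap)
        # left moves under a linear gap: F[i,j] = max_{k<=j} cand[k] + gap*(j-k)
        A = np.maximum.accumulate(cand - gap * j_idx)
        F[i, 1:] = A + gap * j_idx
    # deterministic traceback
    out1, out2 = [], []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out1.append(seq1[i - 1])
            out2.append(seq2[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out1.append(seq1[i - 1])
            out2.append("-")
            i -= 1
        else:
            out1.append("-")
            out2.append(seq2[j - 1])
            j -= 1
    return "".join(reversed(out1)), "".join(reversed(out2)), float(F[m, n])


def p_distance(aligned1: str, aligned2: str) -> float:
    """Fraction of mismatching compared columns; columns with a gap in
    either sequence are excluded.  Zero compared columns is an error."""
    if len(aligned1) != len(aligned2):
        raise ValueError("aligned sequences must have equal length")
    compared = mismatches = 0
    for x, y in zip(aligned1, aligned2):
        if x == "-" or y == "-":
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        raise ValueError("no gap-free columns to compare")
    return mismatches / compared


def protein_distance_matrix(
    proteins: dict[str, str],
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> DistanceMatrix:
    """Pairwise p-distances from global alignments of every protein pair."""
    ids = list(proteins)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a1, a2, _ = global_align(
                proteins[ids[i]], proteins[ids[j]], match, mismatch, gap
            )
            d[i, j] = d[j, i] = p_distance(a1, a2)
    return DistanceMatrix(d, ids)


@dataclass
class NJResult:
    tree: TreeNode
    #: number of computed branch lengths clamped from negative to zero
    n_clamped: int


def neighbor_joining(dm: DistanceMatrix) -> NJResult:
    """Classical neighbor joining.

    Iteratively joins the pair minimizing the Q criterion
    ``Q_ij = (n-2) d_ij - r_i - r_j`` with the standard branch-length
    formulas; ties broken by the lowest index pair.  Negative computed
    branch lengths are clamped to zero and counted.  The result is an
    unrooted tree represented with a trifurcating root.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=np.float64)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest index pair (i<j) among minima
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = clamp(li)
        cj.length = clamp(lj)
        parent.extend([ci, cj])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    # closed-form three-point join
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode()
    root.extend([a, b, c])
    return NJResult(tree=root, n_clamped=n_clamped)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


@dataclass(frozen=True)
class LocusPurity:
    locus: str
    pure: bool
    #: leaves in the symmetric difference of the best bipartition side
    #: and the locus's leaf set
    exceptions: tuple[str, ...]


def cluster_purity(
    tree: TreeNode,
    assignments: dict[str, str],
    allowed_exceptions: int = 0,
) -> list[LocusPurity]:
    """For each locus, test whether some edge bipartition of the tree
    separates exactly that locus's leaves, allowing up to
    ``allowed_exceptions`` misplaced leaves (reported by name)."""
    leaves = {leaf.name for leaf in tree.tips()}
    missing = leaves - set(assignments)
    if missing:
        raise ValueError(f"leaves without locus assignment: {sorted(missing)}")
    # every edge's bipartition, plus the trivial whole-set split so a
    # single-locus tree is pure
    sides: list[frozenset[str]] = [frozenset(leaves)]
    for node in tree.traverse(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips()) or frozenset({node.name})
        sides.append(clade)
    report = []
    for locus in sorted(set(assignments.values())):
        target = frozenset(l for l in leaves if assignments[l] == locus)
        best: frozenset[str] = frozenset(leaves)  # worst case
        best_sd = len(leaves)
        for side in sides:
            for candidate in (side, frozenset(leaves) - side):
                sd = candidate ^ target
                if len(sd) < best_sd:
                    best_sd = len(sd)
                    best = sd
        report.append(
            LocusPurity(
                locus=locus,
                pure=best_sd <= allowed_exceptions,
                exceptions=tuple(sorted(best)),
            )
        )
    return report
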
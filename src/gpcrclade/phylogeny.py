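"""Progressive alignment, neighbor-joining trees, bootstrap, tree comparison.

Alignment is progressive in the classical style: a k-mer guide distance
(fraction of 3-mers not shared), a UPGMA guide tree, and profile-profile
Needleman-Wunsch with affine gaps (BLOSUM62, open 10, extend 0.5).
Distances between aligned sequences are p-distances with pairwise deletion
(sites where either sequence holds a gap or X are skipped for that pair);
a Poisson correction is available behind a flag.  Trees are built with the
Saitou-Nei neighbor-joining agglomeration, which is exact on additive
distance matrices; bootstrap support is the percentage of
column-resampled replicates whose NJ tree contains each internal split of
the point-estimate tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloTree",
    "Node",
    "align",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap",
    "compare_trees",
]

GAP = "-"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5
GUIDE_K = 3

_BLOSUM = substitution_matrices.load("BLOSUM62")
_PROFILE_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX" + GAP
_SCORE = np.zeros((len(_PROFILE_ALPHABET), len(_PROFILE_ALPHABET)))
for _i, _a in enumerate(_PROFILE_ALPHABET[:-1]):
    for _j, _b in enumerate(_PROFILE_ALPHABET[:-1]):
        _SCORE[_i, _j] = _BLOSUM[_a, _b]
# gap column entries score 0 against everything (gap costs are affine,
# charged by the DP, not the substitution matrix)
_CHAR_INDEX = {c: i for i, c in enumerate(_PROFILE_ALPHABET)}


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A multiple sequence alignment: parallel id and row lists."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def as_array(self) -> np.ndarray:
        return np.array([[_CHAR_INDEX[c] for c in row] for row in self.rows],
                        dtype=np.int8)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(row[c] for c in cols) for row in self.rows]
        return Alignment(list(self.ids), rows)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        ids, rows, cur = [], [], []
        for line in open(path):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            else:
                cur.append(line.upper())
        if cur:
            rows.append("".join(cur))
        return cls(ids, rows)


def _kmer_set(seq: str, k: int = GUIDE_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _guide_distances(seqs: list[str]) -> np.ndarray:
    """Fractional-common-kmer distance: 1 - shared / min(count, count)."""
    sets = [_kmer_set(s) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return d


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """Column frequency vectors over the profile alphabet, (n_cols, 22)."""
    arr = np.array([[_CHAR_INDEX[c] for c in row] for row in rows])
    n_cols = arr.shape[1]
    prof = np.zeros((n_cols, len(_PROFILE_ALPHABET)))
    for k in range(len(_PROFILE_ALPHABET)):
        prof[:, k] = (arr == k).mean(axis=0)
    return prof


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman-Wunsch between two profiles (Gotoh)."""
    pa = _profile_matrix(rows_a)
    pb = _profile_matrix(rows_b)
    S = pa @ _SCORE @ pb.T  # (la, lb) expected column-pair score
    la, lb = S.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -GAP_OPEN - (i - 1) * GAP_EXTEND
    for j in range(1, lb + 1):
        Y[0, j] = -GAP_OPEN - (j - 1) * GAP_EXTEND
    for i in range(1, la + 1):
        Si = S[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        for j in range(1, lb + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Xi[j] = max(Mi1[j] - GAP_OPEN, Xi1[j] - GAP_EXTEND,
                        Y[i - 1][j] - GAP_OPEN)
            Yi[j] = max(Mi[j - 1] - GAP_OPEN, Yi[j - 1] - GAP_EXTEND,
                        Xi[j - 1] - GAP_OPEN)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            ops.append("M")
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            cand = [M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND,
                    Y[i - 1, j] - GAP_OPEN]
            ops.append("X")
            i -= 1
            state = int(np.argmax(cand))
        else:
            cand = [M[i, j - 1] - GAP_OPEN, X[i, j - 1] - GAP_OPEN,
                    Y[i, j - 1] - GAP_EXTEND]
            ops.append("Y")
            j -= 1
            state = int(np.argmax(cand))
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
    return out_a, out_b


def align(sequences: dict[str, str] | list[tuple[str, str]]) -> Alignment:
    """Progressive multiple alignment.

    Guide distances are fractional-common-3-mer distances, the guide tree
    is UPGMA, and profiles are merged by affine-gap profile-profile
    Needleman-Wunsch.  Degapping any output row returns its input.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise AlignmentError("need at least 2 sequences to align")
    for rid, seq in items:
        if not seq:
            raise AlignmentError(f"empty sequence for {rid!r}")
    ids = [rid for rid, _ in items]
    seqs = [seq.upper() for _, seq in items]
    if len(items) == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]])
        return Alignment(ids, [a[0], b[0]])
    d = _guide_distances(seqs)
    Z = linkage(squareform(d, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    nxt = len(seqs)
    for a_idx, b_idx, _, _ in Z:
        ia, rows_a = clusters.pop(int(a_idx))
        ib, rows_b = clusters.pop(int(b_idx))
        out_a, out_b = _align_profiles(rows_a, rows_b)
        clusters[nxt] = (ia + ib, out_a + out_b)
        nxt += 1
    order, rows = clusters.popitem()[1]
    # restore input order
    by_index = dict(zip(order, rows))
    return Alignment(ids, [by_index[i] for i in range(len(seqs))])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValueError("distances must be >= 0 with a zero diagonal")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa are not unique")
        self.matrix = m

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.matrix):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


class IncomparablePairError(ValueError):
    pass


def distance_matrix(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """p-distance (optionally Poisson-corrected) with pairwise deletion.

    Sites where either sequence holds a gap or X are skipped for that pair;
    a pair with zero comparable sites raises IncomparablePairError.
    """
    arr = alignment.as_array()
    gap_idx = _CHAR_INDEX[GAP]
    x_idx = _CHAR_INDEX["X"]
    valid = (arr != gap_idx) & (arr != x_idx)
    n = len(alignment.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise IncomparablePairError(
                    f"no comparable sites between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / n_sites
            if model == "poisson":
                p = min(p, 0.999999)
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(alignment.ids), d)


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes may carry support."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        parts = [f"{child.newick()}:{bl:.6f}" for child, bl in self.children]
        inner = f"({','.join(parts)})"
        if self.support is not None:
            inner += f"{self.support:g}"
        return inner


@dataclass
class PhyloTree:
    """Unrooted tree represented with a basal trifurcation (or root node).

    Branch lengths are >= 0 (negative NJ estimates are clamped, the deficit
    moved to the sister branch); bootstrap supports, when attached, live on
    internal nodes and apply to the edge above each node.
    """

    root: Node
    taxa: list[str]

    def splits(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Canonical unrooted splits: each edge's leaf side not containing
        the reference (lexicographically smallest) taxon."""
        ref = min(self.taxa)
        full = set(self.taxa)
        out: set[frozenset[str]] = set()

        def visit(node: Node) -> set[str]:
            if not node.children:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                cset = visit(child)
                side = cset if ref not in cset else full - cset
                if not nontrivial or 2 <= len(side) <= len(full) - 2:
                    out.add(frozenset(side))
                below |= cset
            return below

        visit(self.root)
        return out

    def newick(self) -> str:
        return self.root.newick() + ";"

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def internal_nodes(self) -> list[Node]:
        out = []

        def visit(node: Node) -> None:
            for child, _ in node.children:
                if child.children:
                    out.append(child)
                    visit(child)

        visit(self.root)
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (r-2) d(i,j) - R_i - R_j``; exact Q-ties are broken by the
    lexicographically smallest pair of subtree labels (each subtree is
    labelled by its smallest leaf name).  Negative branch-length estimates
    are clamped to zero with the deficit added to the sister branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes = [Node(name=t) for t in dm.taxa]
    labels = list(dm.taxa)
    d = dm.matrix.copy()
    while len(nodes) > 3:
        r = len(nodes)
        R = d.sum(axis=1)
        Q = (r - 2) * d - R[:, None] - R[None, :]
        # restrict to the upper triangle: Q is symmetric in exact arithmetic
        # but the float evaluation order breaks ulp-level symmetry
        Q[np.tril_indices(r)] = np.inf
        qmin = Q.min()
        candidates = [
            (tuple(sorted((labels[i], labels[j]))), int(i), int(j))
            for i, j in zip(*np.where(Q == qmin))
        ]
        _, i, j = min(candidates)
        vi = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = Node(children=[(nodes[i], vi), (nodes[j], vj)])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
    # final three-point join
    (a, b, c) = range(3)
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node(children=[(nodes[a], max(va, 0.0)),
                          (nodes[b], max(vb, 0.0)),
                          (nodes[c], max(vc, 0.0))])
    leaves = sorted(root.leaves())
    return PhyloTree(root, leaves)


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def bootstrap(alignment: Alignment, replicates: int = 1000, seed: int = 0,
              model: str = "p") -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of
    each internal edge of the point-estimate tree is the percentage of
    replicate trees containing that split.
    """
    tree = neighbor_joining(distance_matrix(alignment, model=model))
    if replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree.splits()}
    for _ in range(replicates):
        rep = alignment.resample_columns(rng)
        rep_tree = neighbor_joining(distance_matrix(rep, model=model))
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1
    ref = min(tree.taxa)
    full = set(tree.taxa)

    def attach(node: Node, below: set[str]) -> None:
        side = below if ref not in below else full - below
        key = frozenset(side)
        if key in counts:
            node.support = 100.0 * counts[key] / replicates

    def visit(node: Node) -> set[str]:
        if not node.children:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            cset = visit(child)
            if child.children:
                attach(child, cset)
            below |= cset
        return below

    visit(tree.root)
    return tree


def compare_trees(t1: PhyloTree, t2: PhyloTree) -> dict:
    """Robinson-Foulds distance and shared non-trivial splits."""
    if set(t1.taxa) != set(t2.taxa):
        raise ValueError("trees have different leaf sets")
    s1, s2 = t1.splits(), t2.splits()
    shared = s1 & s2
    return {
        "shared_splits": sorted(tuple(sorted(s)) for s in shared),
        "n_shared": len(shared),
        "rf_distance": len(s1 ^ s2),
    }
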
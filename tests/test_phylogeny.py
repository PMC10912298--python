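"""Alignment, distances, neighbor joining, bootstrap, tree comparison."""

import numpy as np
import pytest

from gpcrclade.phylogeny import (
    Alignment, AlignmentError, DistanceMatrix, IncomparablePairError, align,
    bootstrap, compare_trees, distance_matrix, neighbor_joining,
)


def random_additive(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree -> (taxa, additive distance matrix,
    set of nontrivial splits canonicalized away from the smallest taxon)."""
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    # build by sequential random attachment; store as adjacency with lengths
    adj: dict[int, list[tuple[int, float]]] = {0: [], 1: []}
    next_id = n_taxa  # internal node ids
    edges: list[tuple[int, int]] = [(0, 1)]
    lengths = {(0, 1): float(rng.uniform(0.1, 1.0))}

    def add_edge(a, b):
        w = float(rng.uniform(0.1, 1.0))
        lengths[(min(a, b), max(a, b))] = w

    for leaf in range(2, n_taxa):
        ei = int(rng.integers(0, len(edges)))
        a, b = edges.pop(ei)
        lengths.pop((min(a, b), max(a, b)))
        mid = next_id
        next_id += 1
        edges.extend([(a, mid), (mid, b), (mid, leaf)])
        add_edge(a, mid)
        add_edge(mid, b)
        add_edge(mid, leaf)
    graph: dict[int, list[tuple[int, float]]] = {}
    for a, b in edges:
        w = lengths[(min(a, b), max(a, b))]
        graph.setdefault(a, []).append((b, w))
        graph.setdefault(b, []).append((a, w))
    # path distances between leaves
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in graph[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    d = (d + d.T) / 2  # per-source path sums differ at the ulp level
    # nontrivial splits: remove each internal edge, collect leaf side
    ref = taxa[0]
    full = set(taxa)
    splits = set()
    for a, b in edges:
        reach = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, _ in graph[u]:
                if v != b and v not in reach and (u, v) != (a, b):
                    if u == a and v == b:
                        continue
                    reach.add(v)
                    stack.append(v)
        side = {taxa[x] for x in reach if x < n_taxa}
        side = side if ref not in side else full - side
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(frozenset(side))
    return taxa, d, splits


class TestAlign:
    def test_identical_sequences_no_gaps(self):
        aln = align([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
        assert aln.rows == ["MKTAYIAK", "MKTAYIAK"]

    def test_single_gap_and_degap_identity(self):
        aln = align([("a", "ACDE"), ("b", "ACE")])
        assert aln.n_cols == 4
        assert aln.degapped(0) == "ACDE"
        assert aln.degapped(1) == "ACE"
        assert sum(c == "-" for c in aln.rows[1]) == 1

    def test_column_count_at_least_longest_input(self):
        seqs = [("a", "MKTAYIAKQR"), ("b", "MKTAYI"), ("c", "KTAYIAKQ")]
        aln = align(seqs)
        assert aln.n_cols >= 10

    def test_degap_identity_many_sequences(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        seqs = []
        for i in range(6):
            cut = int(rng.integers(0, 10))
            seqs.append((f"s{i}", base[cut:] if i % 2 else base[: 60 - cut]))
        aln = align(seqs)
        for i, (_, seq) in enumerate(seqs):
            assert aln.degapped(i) == seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align([("a", "MK"), ("b", "")])


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["MKTA", "MKTA"])
        dm = distance_matrix(aln)
        assert dm.matrix[0, 1] == 0.0

    def test_counting_with_pairwise_deletion(self):
        # 10 comparable sites, 2 differences; gap and X columns skipped
        aln = Alignment(["a", "b"], ["MKTAYIAKQRG-X", "MKTAYIAKVH-GX"])
        dm = distance_matrix(aln)
        assert dm.matrix[0, 1] == pytest.approx(0.2)

    def test_symmetry(self):
        aln = Alignment(["a", "b", "c"], ["MKTA", "MKTT", "MATA"])
        dm = distance_matrix(aln)
        assert np.allclose(dm.matrix, dm.matrix.T)

    def test_zero_comparable_sites_raises(self):
        aln = Alignment(["a", "b"], ["MK--", "--TA"])
        with pytest.raises(IncomparablePairError, match="a"):
            distance_matrix(aln)

    def test_poisson_correction_behind_flag(self):
        aln = Alignment(["a", "b"], ["MKTAYIAKQR", "MKTAYIAKVH"])
        p = distance_matrix(aln).matrix[0, 1]
        c = distance_matrix(aln, model="poisson").matrix[0, 1]
        assert c == pytest.approx(-np.log(1 - p))


def tree_path_distances(tree):
    """Leaf-to-leaf path lengths of a PhyloTree."""
    dists = {}

    def visit(node, acc):
        if not node.children:
            dists[node.name] = acc
            return
        for child, bl in node.children:
            visit(child, acc + bl)

    # root the walk at each leaf via the unrooted structure: easier to get
    # pairwise distances by dynamic programming over the tree
    leaves = tree.taxa
    out = {}

    def collect(node):
        """Return {leaf: distance to this node}."""
        if not node.children:
            return {node.name: 0.0}
        maps = []
        for child, bl in node.children:
            sub = collect(child)
            maps.append({k: v + bl for k, v in sub.items()})
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for la, da in maps[i].items():
                    for lb, db in maps[j].items():
                        out[frozenset((la, lb))] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    collect(tree.root)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        taxa = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        assert frozenset({"C", "D"}) in tree.splits() or \
            frozenset({"A", "B"}) in tree.splits()
        paths = tree_path_distances(tree)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                assert paths[frozenset((a, b))] == pytest.approx(
                    d[taxa.index(a), taxa.index(b)]
                )

    def test_three_taxa_three_point_formulas(self):
        taxa = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        paths = tree_path_distances(tree)
        assert paths[frozenset(("A", "B"))] == pytest.approx(3)
        assert paths[frozenset(("A", "C"))] == pytest.approx(4)
        assert paths[frozenset(("B", "C"))] == pytest.approx(5)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0.0, 1], [1, 0]])))

    def test_taxon_order_does_not_change_topology(self):
        rng = np.random.default_rng(7)
        taxa, d, true_splits = random_additive(12, rng)
        t1 = neighbor_joining(DistanceMatrix(taxa, d))
        perm = list(rng.permutation(len(taxa)))
        t2 = neighbor_joining(
            DistanceMatrix([taxa[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert t1.splits() == t2.splits()

    def test_recovers_random_additive_topologies(self):
        """NJ is exact on additive matrices: 50/50 random 12-taxon trees."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            taxa, d, true_splits = random_additive(12, rng)
            tree = neighbor_joining(DistanceMatrix(taxa, d))
            hits += tree.splits() == true_splits
        assert hits == 50

    def test_agrees_with_skbio_on_noisy_matrix(self):
        """Independent oracle: scikit-bio's NJ yields the same unrooted
        topology on a perturbed additive matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(13)
        taxa, d, _ = random_additive(10, rng)
        noise = rng.uniform(0, 0.01, size=d.shape)
        d = d + (noise + noise.T)  # pre-summed so symmetry is float-exact
        np.fill_diagonal(d, 0.0)
        ours = neighbor_joining(DistanceMatrix(taxa, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        ref = min(taxa)
        full = set(taxa)
        their_splits = set()
        for node in theirs.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            side = side if ref not in side else full - side
            if 2 <= len(side) <= len(taxa) - 2:
                their_splits.add(frozenset(side))
        assert ours.splits() == their_splits


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(17)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        left = "".join(rng.choice(aa, size=120))
        right = "".join(rng.choice(aa, size=120))

        def mutate(seq, n):
            s = list(seq)
            for pos in rng.choice(len(s), size=n, replace=False):
                s[pos] = rng.choice(aa)
            return "".join(s)

        rows = [mutate(left, 3), mutate(left, 3), mutate(right, 3),
                mutate(right, 3)]
        return Alignment(["a1", "a2", "b1", "b2"], rows)

    def test_well_separated_clades_get_high_central_support(self):
        aln = self._clade_alignment()
        tree = bootstrap(aln, replicates=200, seed=3)
        internal = tree.internal_nodes()
        assert internal, "4-taxon tree must have one internal edge"
        assert internal[0].support >= 95

    def test_supports_deterministic_given_seed(self):
        aln = self._clade_alignment()
        t1 = bootstrap(aln, replicates=25, seed=8)
        t2 = bootstrap(aln, replicates=25, seed=8)
        s1 = [n.support for n in t1.internal_nodes()]
        s2 = [n.support for n in t2.internal_nodes()]
        assert s1 == s2

    def test_supports_bounded(self, study_result):
        tree = study_result.tree_7tm
        for node in tree.internal_nodes():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0


class TestCompareTrees:
    def _tree(self, split_pair):
        (a, b), (c, d) = split_pair
        taxa = sorted([a, b, c, d])
        # build distances implying the requested split
        idx = {t: i for i, t in enumerate(taxa)}
        m = np.full((4, 4), 3.0)
        np.fill_diagonal(m, 0.0)
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = 1.0
        m[idx[c], idx[d]] = m[idx[d], idx[c]] = 1.0
        return neighbor_joining(DistanceMatrix(taxa, m))

    def test_identical_trees_rf_zero(self):
        t1 = self._tree((("A", "B"), ("C", "D")))
        t2 = self._tree((("A", "B"), ("C", "D")))
        result = compare_trees(t1, t2)
        assert result["rf_distance"] == 0
        assert result["n_shared"] == len(t1.splits())

    def test_conflicting_quartets_rf_two(self):
        t1 = self._tree((("A", "B"), ("C", "D")))
        t2 = self._tree((("A", "C"), ("B", "D")))
        result = compare_trees(t1, t2)
        assert result["rf_distance"] == 2
        assert result["n_shared"] == 0

    def test_symmetry(self):
        t1 = self._tree((("A", "B"), ("C", "D")))
        t2 = self._tree((("A", "C"), ("B", "D")))
        assert (compare_trees(t1, t2)["rf_distance"]
                == compare_trees(t2, t1)["rf_distance"])

    def test_leaf_set_mismatch_rejected(self):
        t1 = self._tree((("A", "B"), ("C", "D")))
        t2 = self._tree((("A", "B"), ("C", "E")))
        with pytest.raises(ValueError):
            compare_trees(t1, t2)

    def test_rf_agrees_with_dendropy(self):
        """Independent oracle: dendropy's unweighted RF on newick exports."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(19)
        taxa, d1, _ = random_additive(8, rng)
        _, d2, _ = random_additive(8, rng)
        ours1 = neighbor_joining(DistanceMatrix(taxa, d1))
        ours2 = neighbor_joining(DistanceMatrix(taxa, d2))
        rf = compare_trees(ours1, ours2)["rf_distance"]
        tns = dendropy.TaxonNamespace()
        dt1 = dendropy.Tree.get(data=ours1.newick(), schema="newick",
                                taxon_namespace=tns)
        dt2 = dendropy.Tree.get(data=ours2.newick(), schema="newick",
                                taxon_namespace=tns)
        dt1.encode_bipartitions()
        dt2.encode_bipartitions()
        assert rf == dendropy.calculate.treecompare.symmetric_difference(dt1, dt2)


def test_7tm_and_orf_trees_share_planted_clade_splits(study_result,
                                                      truth_by_id):
    """Conserved-TM families give congruent 7TM-span and full-ORF trees:
    every planted clade appears as a split in both."""
    t7, to = study_result.tree_7tm, study_result.tree_orf
    planted: dict[str, set[str]] = {}
    for rid in t7.taxa:
        planted.setdefault(truth_by_id[rid].clade, set()).add(rid)
    ref = min(t7.taxa)
    full = set(t7.taxa)
    s7, so = t7.splits(), to.splits()
    for clade, members in planted.items():
        side = members if ref not in members else full - members
        key = frozenset(side)
        assert key in s7, f"{clade} missing from 7TM tree"
        assert key in so, f"{clade} missing from ORF tree"
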
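"""NJ/UPGMA correctness against hand-derived and independent oracles."""

import numpy as np
import pytest

from zeinhap.phylo_trees import (
    DistanceMatrix,
    Tree,
    bootstrap,
    distance_matrix,
    nj,
    upgma,
)
from zeinhap.synthetic_data import evolve_sequence, random_sequence


def leaf_branches(tree):
    out = {}

    def walk(n):
        if n.is_leaf:
            out[n.name] = n.length
        for c in n.children:
            walk(c)

    walk(tree.root)
    return out


class TestDistanceMatrix:
    def test_identical_sequences(self):
        m = distance_matrix([("a", "ACGT" * 10), ("b", "ACGT" * 10), ("c", "ACGT" * 10)])
        assert np.allclose(m.d, 0)

    def test_matches_per_pair_k2p(self):
        from zeinhap.divergence_dating import k2p, pairwise_site_counts

        rng = np.random.default_rng(4)
        anc = random_sequence(2000, rng)
        seqs = [(f"t{i}", evolve_sequence(anc, 0.02 * (i + 1), 2.0, i)) for i in range(4)]
        m = distance_matrix(seqs)
        for i in range(4):
            for j in range(i + 1, 4):
                expect = k2p(
                    pairwise_site_counts(seqs[i][1], seqs[j][1], prealigned=True)
                ).K
                assert m.d[i, j] == pytest.approx(expect)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            distance_matrix([("a", "ACGT"), ("b", "ACG")])

    def test_saturated_pair_named(self):
        from zeinhap.divergence_dating import SaturationError

        # a/b maximally diverged by transversions at every site
        with pytest.raises(SaturationError, match=r"\(a, b\)"):
            distance_matrix([("a", "AAAA" * 5), ("b", "CCCC" * 5), ("c", "AAAA" * 5)])


class TestNJ:
    def test_three_point_solution(self):
        # d(AB)=2, d(AC)=3, d(BC)=3 -> A:1, B:1, C:2
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = nj(m)
        assert leaf_branches(tree) == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_additive_four_taxon_round_trip(self):
        # tree ((A:1,B:2):1.5,(C:0.5,D:3)); additive matrix built by hand
        d = np.array(
            [
                [0, 3, 3.0, 5.5],
                [3, 0, 4.0, 6.5],
                [3.0, 4.0, 0, 3.5],
                [5.5, 6.5, 3.5, 0],
            ]
        )
        m = DistanceMatrix(["A", "B", "C", "D"], d)
        tree = nj(m)
        assert frozenset(["A", "B"]) in tree.bipartitions()
        # branch lengths exact: leaf branches recovered
        assert leaf_branches(tree) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0}
        )

    def test_identical_taxa_zero_branches(self):
        m = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        tree = nj(m)
        assert all(v == 0 for v in leaf_branches(tree).values())

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_recovers_random_additive_matrices(self):
        """NJ finds the generating topology of random additive matrices (5 taxa)."""
        rng = np.random.default_rng(2024)
        for rep in range(20):
            tree_true, d, labels = _random_additive(5, rng)
            out = nj(DistanceMatrix(labels, d))
            assert out.bipartitions() == tree_true


class TestUPGMA:
    def test_hand_execution(self):
        # d(AB)=2, d(AC)=4, d(BC)=4 -> ((A:1,B:1):1, C:2)
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = upgma(m)
        assert tree.rooted
        depths = tree.depths()
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}
        assert leaf_branches(tree) == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_two_taxa(self):
        m = DistanceMatrix(["A", "B"], np.array([[0, 3], [3, 0]], float))
        tree = upgma(m)
        assert leaf_branches(tree) == {"A": 1.5, "B": 1.5}

    def test_ultrametric_depths_equal(self):
        rng = np.random.default_rng(5)
        d = _random_ultrametric(6, rng)
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(6)], d))
        depths = list(tree.depths().values())
        assert max(depths) - min(depths) < 1e-9

    def test_matches_scipy_average_linkage_heights(self):
        """Independent cross-check: merge heights equal scipy linkage heights/2."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        n = 6
        pts = rng.random((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))
        heights = sorted(
            h for h in _node_heights(tree) if h > 0
        )
        scipy_heights = sorted(linkage(squareform(d), method="average")[:, 2] / 2)
        assert heights == pytest.approx(scipy_heights)


def _node_heights(tree):
    """Heights of internal nodes of an ultrametric tree (root depth - distance)."""
    out = []

    def walk(n, depth):
        depth += n.length
        if not n.is_leaf:
            # height above leaves = total depth of any leaf minus this depth
            out.append(depth)
        for c in n.children:
            walk(c, depth)

    walk(tree.root, -tree.root.length)
    leaf_depth = max(tree.depths().values())
    return [leaf_depth - d for d in out]


def _random_additive(n, rng):
    """Random binary tree on n taxa -> (bipartition set, additive matrix, labels)."""
    labels = [f"t{i}" for i in range(n)]
    # start from 3-taxon star, insert remaining leaves on random edges
    # edges as dict node->(parent, length); simpler: build via dendropy-free paths
    # Represent tree as list of edges between node ids; leaf ids 0..n-1
    next_id = n
    edges = {}  # child -> (parent, length)
    root = next_id
    next_id += 1
    for leaf in (0, 1, 2):
        edges[leaf] = (root, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n):
        target = int(rng.integers(0, len(edges)))
        child = list(edges)[target]
        parent, length = edges[child]
        mid = next_id
        next_id += 1
        split = float(rng.uniform(0.2, 0.8))
        edges[child] = (mid, length * split)
        edges[mid] = (parent, length * (1 - split))
        edges[leaf] = (mid, float(rng.uniform(0.1, 1.0)))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # lowest common ancestor via cumulative distances to the root
            anc_i = {}
            dist = 0.0
            x = i
            while x in edges:
                anc_i[x] = dist
                parent, length = edges[x]
                dist += length
                x = parent
            anc_i[x] = dist
            x = j
            dist = 0.0
            while x not in anc_i:
                parent, length = edges[x]
                dist += length
                x = parent
            d[i, j] = d[j, i] = dist + anc_i[x]
    # true bipartitions: for each internal edge, leaves below
    children = {}
    for child, (parent, _) in edges.items():
        children.setdefault(parent, []).append(child)

    def leaves_below(x):
        if x < n:
            return {x}
        out = set()
        for c in children.get(x, []):
            out |= leaves_below(c)
        return out

    bips = set()
    all_leaves = frozenset(labels)
    for child, (parent, _) in edges.items():
        below = frozenset(labels[i] for i in leaves_below(child))
        if 1 < len(below) < n - 1:
            other = all_leaves - below
            bips.add(min((below, other), key=lambda s: (len(s), tuple(sorted(s)))))
    return bips, d, labels


def _random_ultrametric(n, rng):
    """Random ultrametric matrix via random merge heights."""
    heights = np.sort(rng.uniform(0.5, 5.0, size=n - 1))
    # sequential random merges
    clusters = [{i} for i in range(n)]
    d = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * h
        clusters[i] |= clusters[j]
        del clusters[j]
    return d


class TestBootstrap:
    @pytest.fixture
    def clean_alignment(self):
        rng = np.random.default_rng(3)
        anc = random_sequence(1500, rng)
        a = evolve_sequence(anc, 0.01, 2.0, 1)
        b = evolve_sequence(anc, 0.01, 2.0, 2)
        far = evolve_sequence(anc, 0.15, 2.0, 3)
        c = evolve_sequence(far, 0.01, 2.0, 4)
        dd = evolve_sequence(far, 0.01, 2.0, 5)
        return [("A", a), ("B", b), ("C", c), ("D", dd)]

    def test_full_support_on_congruent_split(self, clean_alignment):
        tree = bootstrap(clean_alignment, method="nj", n_reps=200, seed=1)
        supports = _supports(tree)
        assert supports and min(supports) >= 95

    def test_seed_determinism(self, clean_alignment):
        t1 = bootstrap(clean_alignment, n_reps=50, seed=9)
        t2 = bootstrap(clean_alignment, n_reps=50, seed=9)
        assert t1.newick() == t2.newick()


def _supports(tree):
    out = []

    def walk(n):
        if n.support is not None:
            out.append(n.support)
        for c in n.children:
            walk(c)

    walk(tree.root)
    return out


class TestNewick:
    def test_round_trip(self, tmp_path):
        m = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 3.0, 5.5], [3, 0, 4.0, 6.5], [3.0, 4.0, 0, 3.5],
                 [5.5, 6.5, 3.5, 0]]
            ),
        )
        tree = nj(m)
        tree.root.children[0].support = 87  # decorate an internal node
        back = Tree.from_newick(tree.newick())
        assert back.bipartitions() == tree.bipartitions()
        assert leaf_branches(back) == pytest.approx(leaf_branches(tree), abs=1e-9)
        assert 87 in _supports(back)
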
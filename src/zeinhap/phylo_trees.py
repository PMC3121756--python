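"""Distance-matrix phylogenetics for paralog chronology.

Neighbor-joining (Saitou & Nei Q-criterion) and UPGMA on K2P or p-distance
matrices, with nonparametric bootstrap support and Newick round-tripping.
NJ recovers any additive matrix exactly; UPGMA any ultrametric one.  All
tie-breaks take the lowest (row, column) index pair so results are
deterministic across platforms.  Negative NJ branch lengths are clamped to
zero with the deficit shifted to the sibling branch.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from zeinhap.divergence_dating import SaturationError, k2p, pairwise_site_counts


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Node:
    """A tree node; ``length`` is the branch above it, ``support`` a bootstrap percent."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the smaller side
        (ties broken lexicographically)."""
        all_labels = frozenset(self.leaf_labels())
        out: set[frozenset[str]] = set()

        def walk(n: Node) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.name or ""])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and 1 < len(below) < len(all_labels) - 1:
                other = all_labels - below
                pick = min(
                    (below, other), key=lambda s: (len(s), tuple(sorted(s)))
                )
                out.add(pick)
            return below

        walk(self.root)
        return out

    def depths(self) -> dict[str, float]:
        """Leaf label -> root-to-leaf path length."""
        out: dict[str, float] = {}

        def walk(n: Node, h: float) -> None:
            h += n.length
            if n.is_leaf:
                out[n.name or ""] = h
            for c in n.children:
                walk(c, h)

        walk(self.root, -self.root.length)
        return out

    def newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = "" if n.support is None else str(n.support)
            return f"({inner}){label}:{n.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else str(self.root.support)
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def convert(dn) -> Node:
            n = Node(
                name=dn.taxon.label if dn.taxon else None,
                length=dn.edge.length or 0.0,
            )
            if dn.label is not None and not dn.is_leaf():
                try:
                    n.support = int(float(dn.label))
                except ValueError:
                    pass
            n.children = [convert(c) for c in dn.child_nodes()]
            return n

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root=root, rooted=rooted)


# ---------------------------------------------------------------------------


def distance_matrix(
    seqs: list[tuple[str, str]], model: str = "k2p"
) -> DistanceMatrix:
    """Pairwise distances between labelled aligned sequences.

    ``model`` is "k2p" or "p_distance"; columns with gaps or N in a pair are
    dropped pairwise.  A saturated pair raises, naming the pair.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = [s[0] for s in seqs]
    L = len(seqs[0][1])
    if any(len(s[1]) != L for s in seqs):
        raise ValueError("sequences must be aligned to equal length")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = pairwise_site_counts(seqs[i][1], seqs[j][1], prealigned=True)
            if model == "p_distance":
                dij = counts.P + counts.Q
            elif model == "k2p":
                try:
                    dij = k2p(counts).K
                except SaturationError as err:
                    raise SaturationError(
                        f"pair ({labels[i]}, {labels[j]}) saturated: {err}"
                    ) from err
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=labels, d=d)


def nj(m: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k).  The final three
    lineages are joined on an unrooted trifurcating root.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError(f"NJ needs at least 3 taxa, got {n}")
    nodes: list[Node] = [Node(name=lbl) for lbl in m.labels]
    d = m.d.copy()
    active = list(range(n))

    while len(active) > 3:
        na = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best: tuple[float, int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (na - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (na - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li + 0.0  # +0.0 normalises -0.0
        nodes[j].length = lj + 0.0
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0) + 0.0
        root.children.append(nodes[idx])
    return Tree(root=root, rooted=False)


def upgma(m: DistanceMatrix) -> Tree:
    """Average-linkage clustering; node height is half the merge distance."""
    n = len(m.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes: dict[int, Node] = {i: Node(name=lbl) for i, lbl in enumerate(m.labels)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    d = m.d.copy()
    active = list(range(n))
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                if best is None or d[i, j] < best[0] - 1e-12:
                    best = (d[i, j], i, j)
        dij, i, j = best  # type: ignore[misc]
        h = dij / 2
        parent = Node()
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = h - heights[child_idx]
            parent.children.append(child)
        # average linkage update
        for k in active:
            if k in (i, j):
                continue
            dk = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
            d[i, k] = d[k, i] = dk
        sizes[i] += sizes[j]
        heights[i] = h
        nodes[i] = parent
        active.remove(j)
    root = nodes[active[0]]
    return Tree(root=root, rooted=True)


def bootstrap(
    seqs: list[tuple[str, str]],
    method: str = "nj",
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "k2p",
) -> Tree:
    """Full-data tree with bootstrap support percentages on internal branches.

    Alignment columns are resampled with replacement per replicate; support
    is the percentage of successful replicates whose tree contains each
    internal bipartition of the full-data tree.  Replicates with a saturated
    pair are skipped and counted with a warning.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    build = {"nj": nj, "upgma": upgma}[method]
    full = build(distance_matrix(seqs, model=model))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = len(seqs[0][1])
    labels = [s[0] for s in seqs]
    arr = np.array([list(s[1]) for s in seqs])
    skipped = 0
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = [(lbl, "".join(row)) for lbl, row in zip(labels, arr[:, cols])]
        try:
            tree = build(distance_matrix(rep, model=model))
        except SaturationError:
            skipped += 1
            continue
        done += 1
        found = tree.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    if skipped:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped (saturated pair)",
            stacklevel=2,
        )
    if done == 0:
        raise SaturationError("every bootstrap replicate was saturated")

    def annotate(n: Node, all_labels: frozenset[str]) -> frozenset[str]:
        if n.is_leaf:
            return frozenset([n.name or ""])
        below = frozenset().union(*(annotate(c, all_labels) for c in n.children))
        if n is not full.root and 1 < len(below) < len(all_labels) - 1:
            pick = min(
                (below, all_labels - below), key=lambda s: (len(s), tuple(sorted(s)))
            )
            n.support = round(100 * counts[pick] / done)
        return below

    annotate(full.root, frozenset(labels))
    return full


def write_newick(tree: Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str) -> Tree:
    with io.open(path) as fh:
        return Tree.from_newick(fh.read())
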
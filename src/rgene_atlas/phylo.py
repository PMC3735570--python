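"""Distance-based phylogenetics for NBS-domain alignments.

Distances (p-distance, Poisson correction, Kimura 2-parameter for
nucleotides) are computed with pairwise deletion of gapped columns,
trees are built with neighbor joining, internal-edge stability is assessed
by seeded column-resampling bootstrap, and clade questions (e.g. "do the
TIR genes form an independent clade excluding any non-TIR gene?") are
answered as bipartition queries on the unrooted tree.

The literature this pipeline mirrors ran "Kimura 2-parameter" distances on
amino-acid alignments, which is a nucleotide model; here the protein
default is the Poisson correction, with K2P retained for nucleotide
alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# Alignment and distances
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A fixed set of aligned rows (residues plus ``-`` gaps)."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def resample_columns(self, column_idx: np.ndarray) -> "Alignment":
        return Alignment(
            {k: "".join(s[i] for i in column_idx) for k, s in self.rows.items()}
        )


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")


class SaturatedDistanceError(ValueError):
    pass


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CTU")
_GAPLIKE = frozenset("-.?")


def _pairwise_columns(a: str, b: str):
    for x, y in zip(a.upper(), b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        yield x, y


def compute_distances(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances under ``p``, ``poisson`` or ``k2p_nt``.

    Columns with a gap in either row of a pair are skipped (pairwise
    deletion). ``p`` is the raw mismatch proportion; ``poisson`` the
    corrected -ln(1 - p); ``k2p_nt`` the Kimura 2-parameter distance
    -1/2 ln((1-2P-Q) sqrt(1-2Q)) from transition/transversion proportions
    (nucleotide alignments only).
    """
    if model not in {"p", "poisson", "k2p_nt"}:
        raise ValueError(f"unknown distance model {model!r}")
    labels = aln.labels
    n = len(labels)
    mat = np.frombuffer(
        "".join(aln.rows[l].upper() for l in labels).encode(), dtype=np.uint8
    ).reshape(n, aln.ncol)
    gap = np.isin(mat, np.frombuffer("".join(_GAPLIKE).encode(), np.uint8))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "k2p_nt":
                dist = _k2p(
                    aln.rows[labels[i]], aln.rows[labels[j]], labels[i], labels[j]
                )
            else:
                valid = ~gap[i] & ~gap[j]
                compared = int(valid.sum())
                if compared == 0:
                    raise SaturatedDistanceError(
                        f"no comparable columns for ({labels[i]}, {labels[j]})"
                    )
                p = int(((mat[i] != mat[j]) & valid).sum()) / compared
                if model == "p":
                    dist = p
                else:
                    if p >= 1:
                        raise SaturatedDistanceError(
                            f"saturated Poisson distance for "
                            f"({labels[i]}, {labels[j]}): p = {p}"
                        )
                    dist = -math.log(1 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def _k2p(a: str, b: str, la: str, lb: str) -> float:
    compared = transitions = transversions = 0
    for x, y in _pairwise_columns(a, b):
        compared += 1
        if x == y:
            continue
        same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise SaturatedDistanceError(f"no comparable columns for ({la}, {lb})")
    P, Q = transitions / compared, transversions / compared
    arg = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q) if Q < 0.5 else 0.0
    if arg <= 0:
        raise SaturatedDistanceError(f"saturated K2P distance for ({la}, {lb})")
    return -0.5 * math.log(arg)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    Wraps a :class:`dendropy.Tree`; bootstrap supports (percent of
    replicates, 0-100) live on internal-node labels.
    """

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        tree.is_rooted = False
        return cls(tree)

    def path_length(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as the side omitting the first
        (alphabetically) leaf label, so splits compare across trees."""
        leaves = self.leaf_labels
        ref = min(leaves)
        splits: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(
                l.taxon.label for l in node.leaf_iter()
            )
            side = frozenset(leaves - below) if ref in below else below
            if 2 <= len(side) <= len(leaves) - 2:
                splits.add(side)
        return splits


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Neighbor joining with the standard Q-criterion and branch lengths.

    On an additive matrix the produced tree reproduces the matrix path
    lengths exactly. Tie-breaks in the Q-matrix minimum go to the lowest
    index pair. Negative branch lengths are kept unless ``clamp_negative``.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def set_len(node: dendropy.Node, length: float) -> None:
        node.edge.length = max(0.0, length) if clamp_negative else length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # grow the distance store for the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = tree.seed_node
    set_len(nodes[i], (d[i, j] + d[i, k] - d[j, k]) / 2)
    set_len(nodes[j], (d[i, j] + d[j, k] - d[i, k]) / 2)
    set_len(nodes[k], (d[i, k] + d[j, k] - d[i, j]) / 2)
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap and monophyly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapParams:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def bootstrap_support(
    aln: Alignment,
    model: str = "poisson",
    params: BootstrapParams | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; each internal
    bipartition's support is the percentage of replicate trees containing
    it. Runs are bit-reproducible given the seed.
    """
    params = params or BootstrapParams()
    base = nj_tree(compute_distances(aln, model))
    counts: dict[frozenset[str], int] = {s: 0 for s in base.bipartitions()}
    rng = np.random.default_rng(params.seed)
    for _ in range(params.replicates):
        idx = rng.integers(0, aln.ncol, size=aln.ncol)
        rep = nj_tree(compute_distances(aln.resample_columns(idx), model))
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1

    leaves = base.leaf_labels
    ref = min(leaves)
    for node in base.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(leaves - below) if ref in below else below
        if side in counts:
            node.label = str(round(100.0 * counts[side] / params.replicates, 1))
    return base


def test_monophyly(tree: PhyloTree, tip_set: set[str] | frozenset[str]) -> bool:
    """True iff some edge of the unrooted tree induces tip_set | complement."""
    tips = frozenset(tip_set)
    leaves = tree.leaf_labels
    unknown = tips - leaves
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(tips) <= 1 or len(tips) >= len(leaves) - 1:
        return True  # leaf edges (and their complements) always exist
    ref = min(leaves)
    side = frozenset(leaves - tips) if ref in tips else tips
    return side in tree.bipartitions()
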
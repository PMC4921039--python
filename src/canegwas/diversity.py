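"""Genetic diversity: Dice dissimilarity and neighbor-joining trees.

For dominant presence/absence profiles the Dice dissimilarity between two
clones is 1 - 2a / (2a + b + c), with a the number of shared band
presences and b, c the presences unique to each clone, counted over the
markers observed in both (pairwise-complete missing handling).  Shared
absences carry no information for dominant markers and do not enter the
index.  Trees are built by the Saitou-Nei neighbor-joining agglomeration
with deterministic lexicographic tie-breaking and exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = ["DistanceMatrix", "Tree", "dice_matrix", "neighbor_joining"]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over genotypes, entries in [0, 1]."""

    ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "genotype"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), frame.to_numpy(dtype=float))


@dataclass
class Tree:
    """Unrooted tree with branch lengths, stored as Newick text.

    ``clamped`` counts negative branch-length estimates that were clamped
    to zero (the deficit is moved to the sister branch so the joined pair
    distance is preserved).
    """

    newick: str
    leaf_names: list
    clamped: int = 0

    def dendropy_tree(self):
        import dendropy
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances along the tree."""
        tree = self.dendropy_tree()
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        n = len(self.leaf_names)
        out = np.zeros((n, n))
        for i, a in enumerate(self.leaf_names):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[self.leaf_names[j]])
                out[i, j] = out[j, i] = d
        return pd.DataFrame(out, index=self.leaf_names,
                            columns=self.leaf_names)


def dice_matrix(m: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Dice dissimilarities between all genotypes."""
    if m.n_genotypes < 2:
        raise ValueError("need >= 2 genotypes for a distance matrix")
    x = m.values()
    present = np.nan_to_num(x, nan=0.0)
    absent = np.nan_to_num(1.0 - x, nan=0.0)
    a = present @ present.T
    b = present @ absent.T          # presences unique to the row genotype
    c = absent @ present.T
    denom = 2.0 * a + b + c
    if np.any((denom == 0) & ~np.eye(m.n_genotypes, dtype=bool)):
        i, j = np.argwhere((denom == 0) &
                           ~np.eye(m.n_genotypes, dtype=bool))[0]
        raise ValueError(
            f"Dice dissimilarity undefined for pair "
            f"({m.genotype_ids[i]!r}, {m.genotype_ids[j]!r}): no marker "
            "with a band observed in either genotype")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * a / denom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.genotype_ids), d)


class _Node:
    __slots__ = ("label", "children", "lengths")

    def __init__(self, label, children=None, lengths=None):
        self.label = label
        self.children = children or []
        self.lengths = lengths or []

    def newick(self) -> str:
        if not self.children:
            return str(self.label)
        inner = ",".join(f"{c.newick()}:{l:.10g}"
                         for c, l in zip(self.children, self.lengths))
        return f"({inner})"


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on a dissimilarity matrix.

    Pair selection minimises the Q criterion; ties are broken by the
    lexicographically smallest sorted pair of node labels (internal nodes
    inherit the smaller label of their children), so the output is
    deterministic under input permutation.  Negative branch-length
    estimates are clamped to zero with the deficit transferred to the
    sister branch.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dist = d.matrix.astype(float).copy()
    nodes = [_Node(str(i)) for i in d.ids]
    labels = [str(i) for i in d.ids]
    clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in ties if i < j
        )
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i, j] - li
        if li < 0:
            clamped += 1
            lj += li
            li = 0.0
        if lj < 0:
            clamped += 1
            li += lj
            lj = 0.0
        parent = _Node(min(labels[i], labels[j]), [nodes[i], nodes[j]],
                       [li, lj])
        new_row = 0.5 * (dist[i] + dist[j] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[np.ix_(keep, keep)],
                          new_row[keep][None, :]])
        dist = np.hstack([dist, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [parent.label]

    # resolve the final three nodes around an unrooted central vertex
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    lengths = []
    for l in (l0, l1, l2):
        if l < 0:
            clamped += 1
            l = 0.0
        lengths.append(l)
    root = _Node("", nodes, lengths)
    newick = root.newick() + ";"
    return Tree(newick=newick, leaf_names=[str(i) for i in d.ids],
                clamped=clamped)
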
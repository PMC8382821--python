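"""Uncorrected-distance neighbor-joining gene trees and taxonomy comparison.

The horizontal-gene-transfer question is quantitative here: build an NJ tree
from raw p-distances ("without correction" — no Poisson/Kimura multiple-hit
adjustment) over an aminotransferase alignment, and compare its unrooted
topology against a reference taxonomy tree with the Robinson–Foulds
bipartition distance.  Discordance is quantified, never explained.

Trees are dendropy objects wrapped with bookkeeping for clamped negative NJ
branch lengths (clamped to zero, flagged — common practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .motif import MultipleAlignment


@dataclass
class DistanceMatrix:
    """Labelled symmetric distances with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.matrix < 0):
            raise ValueError("distance matrix has negative entries")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        """Square TSV with header row/column; PHYLIP-style lower-triangle
        rows are also accepted (missing upper cells mirrored)."""
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        header = lines[0].split("\t")[1:]
        n = len(header)
        mat = np.zeros((n, n))
        for i, line in enumerate(lines[1:]):
            cells = line.split("\t")[1:]
            for j, cell in enumerate(cells):
                if cell:
                    mat[i, j] = float(cell)
        # mirror lower triangle if the upper half was left blank
        mat = np.where(mat == 0, mat.T, mat)
        np.fill_diagonal(mat, 0.0)
        return cls(labels=header, matrix=mat)


@dataclass
class PhyloTree:
    """An unrooted leaf-labeled tree; negative NJ lengths are clamped."""

    tree: dendropy.Tree
    clamped_branches: int = 0
    clamped: bool = field(init=False)

    def __post_init__(self) -> None:
        self.clamped = self.clamped_branches > 0

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "PhyloTree":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True,
                                 **kwargs)
        return cls(tree=tree)


def p_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances: mismatches over columns where neither row gaps.

    A pair with zero comparable columns is an error naming the pair (no
    silent NaN).  Values lie in [0, 1].
    """
    if len(msa.rows) < 3:
        raise ValueError("p_distance needs an MSA with at least 3 rows")
    n = len(msa.rows)
    arrays = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in msa.rows]
    gap = ord("-")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrays[i] != gap) & (arrays[j] != gap)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no "
                    "gap-free columns"
                )
            mism = int((arrays[i][ok] != arrays[j][ok]).sum())
            mat[i, j] = mat[j, i] = mism / n_ok
    return DistanceMatrix(labels=list(msa.ids), matrix=mat)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Among minimal-Q pairs, the lexicographically lowest (label_i, label_j)
    pair is joined first.  Additive inputs are recovered exactly (up to
    floating point).  Negative branch lengths are clamped to zero and
    counted in ``clamped_branches``.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for label in D.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node

    active = list(D.labels)
    dist = {
        (a, b): float(D.matrix[i, j])
        for i, a in enumerate(D.labels)
        for j, b in enumerate(D.labels)
    }
    clamped = 0

    def d(a: str, b: str) -> float:
        return dist[(a, b)]

    join_counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * d(a, b) - row_sum[a] - row_sum[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = 0.5 * d(a, b) + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        if la < 0:
            clamped += 1
            la = 0.0
        if lb < 0:
            clamped += 1
            lb = 0.0
        join_counter += 1
        new_label = f"__join{join_counter}"
        parent = dendropy.Node()
        parent.add_child(nodes[a]); nodes[a].edge.length = la
        parent.add_child(nodes[b]); nodes[b].edge.length = lb
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(new_label, c)] = dist[(c, new_label)] = duc
        dist[(new_label, new_label)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    center = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += 1
            length = 0.0
        center.add_child(nodes[label])
        nodes[label].edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    return PhyloTree(tree=tree, clamped_branches=clamped)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Unrooted Robinson–Foulds distance and its 2(n-3) normalization.

    Counts bipartitions present in exactly one tree.  Leaf sets must match;
    a mismatch raises with the differing labels listed.  For n = 3 (no
    internal bipartitions possible) the normalized value is 0.
    """
    leaves1, leaves2 = t1.leaf_labels(), t2.leaf_labels()
    if leaves1 != leaves2:
        only1 = sorted(leaves1 - leaves2)
        only2 = sorted(leaves2 - leaves1)
        raise ValueError(
            f"leaf sets differ: only in first = {only1}, "
            f"only in second = {only2}"
        )
    taxa = dendropy.TaxonNamespace(sorted(leaves1))
    a = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                          taxon_namespace=taxa, preserve_underscores=True)
    b = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                          taxon_namespace=taxa, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    rf = int(dendropy.calculate.treecompare.symmetric_difference(a, b))
    n = len(leaves1)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)
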
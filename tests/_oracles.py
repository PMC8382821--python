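"""Independent reference implementations used only to check the package.

Everything here is deliberately written with plain Python loops and naive
data structures, sharing no code with the implementations under test.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = -math.inf


def blosum62(a: str, b: str) -> float:
    return float(_B62[a, b])


def sw_affine_score(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> int:
    """Plain-loop Smith-Waterman/Gotoh best local score.

    A gap of length k costs gap_open + k*gap_extend.  Textbook three-state
    recurrence, no vectorization tricks.
    """
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


class DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry


def component_count(nodes, edges) -> tuple[int, int]:
    """(number of components of size >= 2, number of singletons)."""
    dsu = DisjointSet(nodes)
    for u, v in edges:
        dsu.union(u, v)
    sizes: dict[str, int] = {}
    for node in nodes:
        root = dsu.find(node)
        sizes[root] = sizes.get(root, 0) + 1
    multi = sum(1 for s in sizes.values() if s >= 2)
    single = sum(1 for s in sizes.values() if s == 1)
    return multi, single


def circular_rank_distance(i: int, j: int, n: int, circular: bool) -> int:
    if circular:
        return min((i - j) % n, (j - i) % n)
    return abs(i - j)


def neighborhood_indices(n: int, idx: int, window: int,
                         circular: bool) -> set[int]:
    """All feature indices within the +-window ORF neighborhood of idx."""
    return {
        j for j in range(n)
        if j != idx and circular_rank_distance(idx, j, n, circular) <= window
    }


def exhaustive_3gc_focals(genome, schema, focal_activity: str,
                          window: int) -> set[str]:
    """Focal feature ids with >= 1 in-window gene of each other activity,
    by exhaustive enumeration of all in-window triples."""
    out: set[str] = set()
    others = [a for a in schema.names() if a != focal_activity]
    for contig in genome.contigs:
        feats = contig.features
        n = len(feats)
        for i, focal in enumerate(feats):
            if not (schema[focal_activity] & focal.families):
                continue
            neighbor_idx = neighborhood_indices(n, i, window, contig.circular)
            found = []
            for activity in others:
                found.append(any(
                    schema[activity] & feats[j].families
                    for j in neighbor_idx
                ))
            if all(found):
                out.add(focal.feature_id)
    return out


def scan_positions(sequence: str, pattern: str, budget: int) -> list[tuple[int, int]]:
    """Position-by-position motif scan, 1-based offsets."""
    pattern = pattern.upper()
    sequence = sequence.upper()
    out = []
    for start in range(len(sequence) - len(pattern) + 1):
        mism = 0
        for k, c in enumerate(pattern):
            if c != "X" and sequence[start + k] != c:
                mism += 1
        if mism <= budget:
            out.append((start + 1, mism))
    return out


def leaf_bipartitions(newick: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    side not containing the alphabetically smallest leaf.  Own recursive
    parser-free approach via dendropy node traversal only."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    bips: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = below if anchor not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(frozenset(side))
    return bips


def rf_exhaustive(newick1: str, newick2: str) -> int:
    b1, b2 = leaf_bipartitions(newick1), leaf_bipartitions(newick2)
    return len(b1 ^ b2)


def pdist_recount(rows: list[str]) -> list[list[float]]:
    n = len(rows)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = mism = 0
            for x, y in zip(rows[i], rows[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        mism += 1
            out[i][j] = mism / comparable
    return out


def random_additive_tree(rng, n: int):
    """A random unrooted binary tree topology with positive branch lengths
    and its exact leaf-to-leaf path-length matrix.

    Built by sequential leaf attachment onto random edges; distances are
    accumulated on an explicit adjacency graph, independent of any NJ code.
    Returns (newick, labels, matrix).
    """
    labels = [f"t{k:02d}" for k in range(n)]
    # adjacency: node -> list of (node, length); internal nodes get negative ids
    adj: dict[object, list] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def remove_edge(u, v):
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]

    def blen():
        return float(rng.uniform(0.05, 1.0))

    add_edge(labels[0], labels[1], blen())
    next_internal = 0
    for label in labels[2:]:
        edges = sorted(
        {tuple(sorted((str(u), str(v))) ) for u in adj for v, _ in adj[u]}
        )
        pick = edges[rng.integers(len(edges))]
        # find actual nodes (internal ids are "i<k>" strings, leaves labels)
        u, v = pick
        w = [wt for x, wt in adj[u] if x == v][0]
        remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, label, blen())

    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in out:
                    out[nb] = out[cur] + w
                    stack.append(nb)
        return out

    import numpy as np

    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        d = dist_from(a)
        for j, b in enumerate(labels):
            mat[i, j] = d[b]

    def to_newick(node, parent):
        children = [(nb, w) for nb, w in adj[node] if nb != parent]
        if not children:
            return node
        inner = ",".join(f"{to_newick(nb, node)}:{w:.6f}" for nb, w in children)
        return f"({inner})"

    start = f"i0" if n > 2 else labels[0]
    newick = to_newick(start, None) + ";"
    return newick, labels, mat
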
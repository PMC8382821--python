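"""Sequence similarity networks: build, threshold, cluster, sweep, label.

Nodes are proteins, edges are above-threshold pairwise hits.  Clusters are
the connected components of the thresholded graph (EFI-EST semantics);
components of size >= 2 are numbered 1..C by strictly non-increasing size
with ties broken by the lexicographically smallest member id, and singletons
are flagged separately.  Two singleton counts are tracked: nodes isolated
because no pairwise hit existed at all, and nodes isolated only after
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .align import PairwiseHit
from .io_formats import ProteinRecord, genus_of

THRESHOLD_METRICS = ("percent_identity", "alignment_score")


@dataclass
class SimilarityNetwork:
    """A thresholded similarity graph with size-ranked cluster labels."""

    graph: nx.Graph
    threshold_spec: tuple[str, float] | None
    #: singletons that had no hit at any threshold (no edge in the hit list)
    n_isolated_no_hit: int = 0

    def nodes(self) -> Iterable[str]:
        return self.graph.nodes()

    def node(self, node_id: str) -> dict:
        return self.graph.nodes[node_id]

    def clusters(self) -> dict[int, list[str]]:
        """cluster_id -> sorted member ids (size >= 2 clusters only)."""
        out: dict[int, list[str]] = {}
        for node, data in self.graph.nodes(data=True):
            cid = data.get("cluster_id")
            if cid is not None:
                out.setdefault(cid, []).append(node)
        return {cid: sorted(members) for cid, members in sorted(out.items())}

    def singletons(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("singleton")
        )


def build_network(hits: Sequence[PairwiseHit],
                  threshold_spec: tuple[str, float],
                  records: Sequence[ProteinRecord] | None = None,
                  ) -> SimilarityNetwork:
    """Build a network keeping edges whose metric is >= the threshold.

    ``threshold_spec`` is (metric, value) with metric one of
    ``percent_identity`` or ``alignment_score`` (the EFI -log10 E-value
    scale).  When ``records`` is given, every record becomes a node even if
    isolated, carrying organism/genus attributes; otherwise nodes are the
    endpoints of the full hit list (so post-threshold isolates are retained).
    """
    metric, value = threshold_spec
    if metric not in THRESHOLD_METRICS:
        raise ValueError(
            f"unknown threshold metric {metric!r}; expected one of "
            f"{THRESHOLD_METRICS}"
        )
    graph = nx.Graph()
    with_hits: set[str] = set()
    for hit in hits:
        with_hits.update((hit.query_id, hit.subject_id))
    if records is not None:
        for rec in records:
            graph.add_node(rec.protein_id, organism=rec.organism,
                           genus=rec.genus)
    for node in sorted(with_hits):
        if node not in graph:
            graph.add_node(node)
    for hit in hits:
        if getattr(hit, metric) >= value:
            graph.add_edge(
                hit.query_id, hit.subject_id,
                percent_identity=hit.percent_identity,
                bit_score=hit.bit_score,
                evalue=hit.evalue,
                alignment_score=hit.alignment_score,
            )
    n_no_hit = sum(1 for n in graph.nodes if n not in with_hits)
    return SimilarityNetwork(graph=graph, threshold_spec=threshold_spec,
                             n_isolated_no_hit=n_no_hit)


def cluster_network(net: SimilarityNetwork) -> SimilarityNetwork:
    """Assign connected-component cluster ids in place (and return the net).

    Components of size >= 2 get ids 1..C by descending size, ties by the
    lexicographically smallest member; single nodes get ``singleton=True``
    and ``cluster_id=None``.
    """
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    multi = sorted(
        (c for c in components if len(c) >= 2),
        key=lambda c: (-len(c), c[0]),
    )
    for node in net.graph.nodes:
        net.graph.nodes[node]["cluster_id"] = None
        net.graph.nodes[node]["singleton"] = False
    for cid, members in enumerate(multi, start=1):
        for node in members:
            net.graph.nodes[node]["cluster_id"] = cid
    for comp in components:
        if len(comp) == 1:
            net.graph.nodes[comp[0]]["singleton"] = True
    return net


def threshold_sweep(hits: Sequence[PairwiseHit],
                    thresholds: Sequence[float],
                    metric: str = "percent_identity",
                    records: Sequence[ProteinRecord] | None = None,
                    tracked: Sequence[str] = (),
                    ) -> pd.DataFrame:
    """Cluster counts (and tracked-node co-membership) across thresholds.

    Returns one row per threshold with ``n_clusters`` (size >= 2),
    ``n_singletons`` (post-threshold isolates), ``n_singletons_no_hit``
    (nodes with no hit at any threshold), and ``tracked_partition`` — the
    partition the tracked nodes fall into, as a ``|``-joined string of
    comma-joined groups.
    """
    if not thresholds:
        raise ValueError("need at least one threshold")
    rows = []
    for value in thresholds:
        net = cluster_network(build_network(hits, (metric, value), records))
        clusters = net.clusters()
        partition: dict[object, list[str]] = {}
        for node in tracked:
            key = net.node(node).get("cluster_id")
            partition.setdefault(key if key is not None else f"s:{node}",
                                 []).append(node)
        groups = sorted(",".join(sorted(g)) for g in partition.values())
        rows.append({
            "threshold": value,
            "n_clusters": len(clusters),
            "n_singletons": len(net.singletons()),
            "n_singletons_no_hit": net.n_isolated_no_hit,
            "tracked_partition": "|".join(groups),
        })
    return pd.DataFrame(rows)


def label_clusters_by_genus(net: SimilarityNetwork,
                            majority_fraction: float = 0.75) -> dict[int, str]:
    """Label each cluster by genus, or "GenusA/GenusB" when mixed.

    A cluster whose most common genus reaches ``majority_fraction`` of its
    nodes is labeled with that genus; otherwise the two most populous genera
    are joined by "/" (count ties broken alphabetically).
    """
    labels: dict[int, str] = {}
    for cid, members in net.clusters().items():
        counts: dict[str, int] = {}
        for node in members:
            genus = net.node(node).get("genus") or genus_of(
                net.node(node).get("organism", "")
            )
            counts[genus] = counts.get(genus, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_genus, top_count = ranked[0]
        if top_count / len(members) >= majority_fraction:
            labels[cid] = top_genus
        else:
            labels[cid] = "/".join(g for g, _ in ranked[:2])
    return labels
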
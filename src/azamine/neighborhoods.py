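"""Genome neighborhoods and the "colored SSN".

A neighborhood is the +-N ORFs around a focal gene in start-coordinate rank
order (base-pair distance is irrelevant); it never crosses contig boundaries
but wraps around circular contigs without double-counting.  Coloring
attaches, to each network node, the set of pathway activities found among
its neighbors and the phosphatase class implied by the neighbor families.
Per-cluster family co-occurrence summarizes how often each family appears in
the neighborhoods of a cluster's nodes; families at or above the reporting
threshold (default 20%) make the summary, everything is retained in the
full table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GeneFeature, GenomeRecord
from .ssn import SimilarityNetwork

DEFAULT_WINDOW = 3
DEFAULT_COOCCURRENCE = 0.20

#: activity -> PFAM family accessions (pairwise-disjoint sets)
DEFAULT_SCHEMA: dict[str, frozenset[str]] = {
    "aminotransferase": frozenset({"PF00202"}),
    "dehydrogenase": frozenset({"PF00107", "PF08240", "PF16912"}),
    "phosphatase": frozenset({"PF13419", "PF00459", "PF12710", "PF07081"}),
}

INOSITOL_FAMILIES = frozenset({"PF00459"})
HAD_FAMILIES = frozenset({"PF13419", "PF12710", "PF07081"})


@dataclass(frozen=True)
class ActivitySchema:
    """Mapping from enzyme activity to the PFAM families that signal it."""

    activities: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValueError("schema has no activities")
        seen: set[str] = set()
        for name, fams in self.activities.items():
            if not fams:
                raise ValueError(f"activity {name!r} has an empty family set")
            overlap = seen & set(fams)
            if overlap:
                raise ValueError(
                    f"family sets are not disjoint: {sorted(overlap)}"
                )
            seen.update(fams)

    def __getitem__(self, activity: str) -> frozenset[str]:
        return self.activities[activity]

    def __contains__(self, activity: str) -> bool:
        return activity in self.activities

    def names(self) -> list[str]:
        return list(self.activities)

    def activities_of(self, families: frozenset[str]) -> set[str]:
        """Activities signalled by a feature's family annotations (a feature
        carrying families from two activities counts toward both)."""
        return {
            name for name, fams in self.activities.items() if fams & families
        }

    @classmethod
    def default(cls) -> "ActivitySchema":
        return cls(activities=DEFAULT_SCHEMA)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "ActivitySchema":
        return cls(activities={k: frozenset(v) for k, v in mapping.items()})


@dataclass
class NeighborhoodProfile:
    """The window ORFs on each side of a focal gene, focal excluded."""

    focal_feature_id: str
    window: int
    neighbors: list[tuple[int, GeneFeature]]  # (offset in -w..+w, != 0)

    def families(self) -> set[str]:
        out: set[str] = set()
        for _, feat in self.neighbors:
            out.update(feat.families)
        return out


def extract_neighborhood(genome: GenomeRecord, focal_feature_id: str,
                         window: int = DEFAULT_WINDOW) -> NeighborhoodProfile:
    """The +-window ORFs around a focal feature, in rank order.

    Truncates at linear-contig ends; wraps on circular contigs, assigning
    each distinct neighbor its smallest-|offset| slot (ties to the
    downstream/+ side) so nothing is double-counted even when 2*window
    exceeds the gene count.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    for contig in genome.contigs:
        ids = [f.feature_id for f in contig.features]
        if focal_feature_id not in ids:
            continue
        idx = ids.index(focal_feature_id)
        n = len(contig.features)
        chosen: dict[int, int] = {}  # feature index -> offset
        for offset in sorted(range(-window, window + 1),
                             key=lambda o: (abs(o), -o)):
            if offset == 0:
                continue
            if contig.circular:
                j = (idx + offset) % n
                if j == idx or j in chosen:
                    continue
                chosen[j] = offset
            else:
                j = idx + offset
                if 0 <= j < n:
                    chosen[j] = offset
        neighbors = sorted(
            ((off, contig.features[j]) for j, off in chosen.items()),
            key=lambda pair: pair[0],
        )
        return NeighborhoodProfile(
            focal_feature_id=focal_feature_id, window=window,
            neighbors=neighbors,
        )
    raise KeyError(
        f"feature {focal_feature_id!r} not found in genome {genome.genome_id!r}"
    )


def classify_phosphatase(families: set[str]) -> str:
    """Phosphatase class from a set of neighbor families.

    Returns ``inositol_phosphatase``, ``HAD_hydrolase``, ``both`` (conflict:
    reported, never resolved) or ``none``.
    """
    has_inositol = bool(families & INOSITOL_FAMILIES)
    has_had = bool(families & HAD_FAMILIES)
    if has_inositol and has_had:
        return "both"
    if has_inositol:
        return "inositol_phosphatase"
    if has_had:
        return "HAD_hydrolase"
    return "none"


def _protein_to_feature(genomes: Sequence[GenomeRecord]):
    mapping: dict[str, tuple[GenomeRecord, GeneFeature]] = {}
    for genome in genomes:
        for feat in genome.features():
            if feat.protein_id:
                mapping[feat.protein_id] = (genome, feat)
    return mapping


def color_nodes(net: SimilarityNetwork, genomes: Sequence[GenomeRecord],
                schema: ActivitySchema | None = None,
                window: int = DEFAULT_WINDOW,
                ) -> dict[str, NeighborhoodProfile]:
    """Attach neighborhood content to every network node ("colored SSN").

    Each node gains ``colors`` (the set of activities among its neighbors)
    and ``phosphatase_class``.  Nodes without a genomic mapping are flagged
    ``unmapped`` with a warning, never silently dropped.  Returns the
    per-node neighborhood profiles for reuse (co-occurrence, detection).
    """
    schema = schema or ActivitySchema.default()
    mapping = _protein_to_feature(genomes)
    profiles: dict[str, NeighborhoodProfile] = {}
    for node in net.nodes():
        data = net.node(node)
        if node not in mapping:
            warnings.warn(f"node {node!r} has no genomic mapping", stacklevel=2)
            data["unmapped"] = True
            data["colors"] = frozenset()
            data["phosphatase_class"] = "none"
            continue
        genome, feat = mapping[node]
        profile = extract_neighborhood(genome, feat.feature_id, window)
        profiles[node] = profile
        families = profile.families()
        data["unmapped"] = False
        data["colors"] = frozenset(schema.activities_of(frozenset(families)))
        ph_class = classify_phosphatase(families)
        if ph_class == "both":
            warnings.warn(
                f"node {node!r}: neighborhood carries both inositol and HAD "
                "phosphatase families",
                stacklevel=2,
            )
        data["phosphatase_class"] = ph_class
    return profiles


@dataclass
class ClusterCooccurrence:
    """Per-cluster fraction of nodes whose neighborhood holds each family."""

    cluster_id: int
    fractions: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_COOCCURRENCE

    def reported(self) -> dict[str, float]:
        return {fam: frac for fam, frac in sorted(self.fractions.items())
                if frac >= self.threshold}


def cluster_cooccurrence(net: SimilarityNetwork,
                         profiles: Mapping[str, NeighborhoodProfile],
                         threshold: float = DEFAULT_COOCCURRENCE,
                         ) -> list[ClusterCooccurrence]:
    """Family co-occurrence per cluster (the GNN summary table).

    For each cluster and family: the fraction of the cluster's nodes whose
    neighborhood contains at least one feature of that family.  Families
    below the reporting threshold stay in the full table
    (:meth:`ClusterCooccurrence.fractions`) but are excluded from
    :meth:`ClusterCooccurrence.reported`.
    """
    out = []
    for cid, members in net.clusters().items():
        counts: dict[str, int] = {}
        n_members = len(members)
        for node in members:
            profile = profiles.get(node)
            if profile is None:
                continue
            for fam in profile.families():
                counts[fam] = counts.get(fam, 0) + 1
        out.append(
            ClusterCooccurrence(
                cluster_id=cid,
                fractions={f: c / n_members for f, c in counts.items()},
                threshold=threshold,
            )
        )
    return out


def cooccurrence_table(cooc: Sequence[ClusterCooccurrence]) -> pd.DataFrame:
    rows = [
        {"cluster_id": c.cluster_id, "family": fam, "fraction": frac,
         "reported": frac >= c.threshold}
        for c in cooc
        for fam, frac in sorted(c.fractions.items())
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "family", "fraction",
                                       "reported"])
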
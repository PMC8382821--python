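"""Detection of the azasugar three-gene-cluster (3GC) signature.

A putative producer carries, within a +-window ORF neighborhood, at least
one gene from each of the three required activities: aminotransferase,
aminopolyol dehydrogenase, and phosphatase ("at least one family from each
activity's set" — phosphatase families are alternatives, not all required).
Detection operates on genome annotations directly, so it is testable
without a network; the colored-SSN route is reproduced by intersecting the
detected genomes with SSN membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneFeature, GenomeRecord
from .neighborhoods import (
    ActivitySchema,
    DEFAULT_WINDOW,
    classify_phosphatase,
    extract_neighborhood,
)

_ACTIVITY_LETTER = {
    "aminotransferase": "A",
    "dehydrogenase": "D",
    "phosphatase": "P",
}


@dataclass(frozen=True)
class ThreeGeneCluster:
    """A detected aminotransferase + dehydrogenase + phosphatase triple."""

    genome_id: str
    organism: str
    at_feature: GeneFeature
    dh_feature: GeneFeature
    ph_feature: GeneFeature
    order_signature: str  # permutation of "ADP" in ascending start order
    phosphatase_class: str
    span_orfs: int  # max |offset| from the focal gene that was used
    focal_activity: str

    def member_ids(self) -> frozenset[str]:
        return frozenset({self.at_feature.feature_id,
                          self.dh_feature.feature_id,
                          self.ph_feature.feature_id})


def classify_order(at: GeneFeature, dh: GeneFeature, ph: GeneFeature) -> str:
    """Gene-order signature: letters sorted by start coordinate (ties by
    end).  Reverse-strand blocks are NOT flipped — coordinates only."""
    triples = [("A", at), ("D", dh), ("P", ph)]
    triples.sort(key=lambda t: (t[1].start, t[1].end, t[0]))
    return "".join(letter for letter, _ in triples)


def find_3gc(genomes: Sequence[GenomeRecord] | GenomeRecord,
             schema: ActivitySchema | None = None,
             focal_activity: str = "aminotransferase",
             window: int = DEFAULT_WINDOW) -> list[ThreeGeneCluster]:
    """One cluster record per focal gene whose +-window neighborhood
    contains at least one gene of each other activity.

    When several neighbors could fill an activity, the nearest by |offset|
    wins, ties going to the lower start coordinate — deterministic, and one
    record per focal gene so combinatorial duplicates never appear.  Output
    order follows (genome_id, focal feature start), independent of the input
    genome ordering.
    """
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    schema = schema or ActivitySchema.default()
    if focal_activity not in schema:
        raise ValueError(f"unknown focal activity {focal_activity!r}")
    others = [a for a in schema.names() if a != focal_activity]
    clusters: list[ThreeGeneCluster] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for feat in genome.features():
            if not (schema[focal_activity] & feat.families):
                continue
            profile = extract_neighborhood(genome, feat.feature_id, window)
            picks: dict[str, tuple[int, GeneFeature]] = {}
            for activity in others:
                candidates = [
                    (off, f) for off, f in profile.neighbors
                    if schema[activity] & f.families
                ]
                if not candidates:
                    break
                candidates.sort(key=lambda c: (abs(c[0]), c[1].start))
                picks[activity] = candidates[0]
            else:
                by_activity = {focal_activity: (0, feat)}
                by_activity.update(picks)
                at = by_activity["aminotransferase"][1]
                dh = by_activity["dehydrogenase"][1]
                ph = by_activity["phosphatase"][1]
                clusters.append(
                    ThreeGeneCluster(
                        genome_id=genome.genome_id,
                        organism=genome.organism,
                        at_feature=at,
                        dh_feature=dh,
                        ph_feature=ph,
                        order_signature=classify_order(at, dh, ph),
                        phosphatase_class=classify_phosphatase(
                            set(ph.families)
                        ),
                        span_orfs=max(
                            abs(off) for off, _ in by_activity.values()
                        ),
                        focal_activity=focal_activity,
                    )
                )
    return clusters


def tabulate_producers(clusters: Sequence[ThreeGeneCluster],
                       min_genus_count: int = 5) -> pd.DataFrame:
    """Genus tally of genomes with >= 1 cluster (each genome counted once).

    Returns the full listing sorted by descending count (ties alphabetical)
    with an ``in_main_table`` flag marking genera at or above
    ``min_genus_count``; the main table is the flagged subset.
    """
    genomes_by_genus: dict[str, set[str]] = {}
    for c in clusters:
        genus = c.organism.split()[0] if c.organism.split() else ""
        genomes_by_genus.setdefault(genus, set()).add(c.genome_id)
    rows = [
        {"genus": genus, "n_genomes": len(gids),
         "in_main_table": len(gids) >= min_genus_count}
        for genus, gids in genomes_by_genus.items()
    ]
    rows.sort(key=lambda r: (-r["n_genomes"], r["genus"]))
    return pd.DataFrame(rows, columns=["genus", "n_genomes", "in_main_table"])


def merge_hit_sets(**sets: Iterable[str]) -> dict[str, set[str]]:
    """Union hit sets keyed by genome id, with per-source provenance.

    ``merge_hit_sets(at_ssn={...}, dh_ssn={...})`` returns
    ``{genome_id: {"at_ssn", ...}}`` mapping each genome to the set of
    sources that found it.
    """
    merged: dict[str, set[str]] = {}
    for source, genome_ids in sets.items():
        for gid in genome_ids:
            merged.setdefault(gid, set()).add(source)
    return merged


def clusters_table(clusters: Sequence[ThreeGeneCluster],
                   ssn_cluster_of: Mapping[str, object] | None = None,
                   ) -> pd.DataFrame:
    """Flat per-cluster table (one row per focal gene) for TSV export."""
    rows = []
    for c in clusters:
        row = {
            "genome_id": c.genome_id,
            "organism": c.organism,
            "focal_activity": c.focal_activity,
            "at_feature": c.at_feature.feature_id,
            "at_start": c.at_feature.start,
            "dh_feature": c.dh_feature.feature_id,
            "dh_start": c.dh_feature.start,
            "ph_feature": c.ph_feature.feature_id,
            "ph_start": c.ph_feature.start,
            "order_signature": c.order_signature,
            "phosphatase_class": c.phosphatase_class,
            "span_orfs": c.span_orfs,
        }
        if ssn_cluster_of is not None:
            at_pid = c.at_feature.protein_id
            row["ssn_cluster"] = ssn_cluster_of.get(at_pid)
        rows.append(row)
    return pd.DataFrame(rows)
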
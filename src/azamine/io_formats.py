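"""Readers and writers for the external formats the pipeline touches.

Protein sets travel as FASTA, annotated genomes as GFF3 (+ contig FASTA),
similarity networks as GraphML or a TSV edge list.  Coordinates are 1-based
inclusive everywhere, following the GFF3/GenBank convention; no half-open
conversion is ever exposed.

Family annotations (PFAM accessions) are consumed from the input files —
either ``Dbxref=Pfam:PFxxxxx`` or a custom ``pfam=`` attribute.  The pipeline
never bundles PFAM models; users who need to annotate raw proteomes can plug
an external profile search via :data:`PROFILE_SEARCH_COMMAND_HOOK`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: amino-acid alphabet accepted in ProteinRecord sequences (X = unknown/any)
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: contract name for an optional external HMM/profile scanner; the pipeline
#: itself never runs one, it only documents the hook.
PROFILE_SEARCH_COMMAND_HOOK = "profile_search_command"


class FormatError(ValueError):
    """Malformed input file (bad coordinates, duplicate ids, bad strand...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with organism and family tags; the SSN node payload.

    ``organism`` is a free-text binomial-style string; its genus is defined as
    the first whitespace-delimited token (see :func:`genus_of`).
    """

    protein_id: str
    sequence: str
    organism: str = ""
    source_gene: str | None = None
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )

    @property
    def genus(self) -> str:
        return genus_of(self.organism)


def genus_of(organism: str) -> str:
    """Genus = first whitespace-delimited token of the organism string."""
    return organism.split()[0] if organism.split() else ""


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded ORF on a contig (1-based inclusive coordinates)."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    product: str = ""
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.feature_id!r}: unknown strand {self.strand!r}"
            )


@dataclass
class Contig:
    contig_id: str
    length: int
    circular: bool = False
    features: list[GeneFeature] = field(default_factory=list)

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.feature_id))


@dataclass
class GenomeRecord:
    """An annotated genome: ordered contigs, each with start-sorted features."""

    genome_id: str
    organism: str = ""
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genus(self) -> str:
        return genus_of(self.organism)

    def features(self) -> Iterable[GeneFeature]:
        for contig in self.contigs:
            yield from contig.features

    def validate(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs:
            contig.sort_features()
            for f in contig.features:
                if f.feature_id in seen:
                    raise FormatError(
                        f"genome {self.genome_id!r}: duplicate feature id "
                        f"{f.feature_id!r}"
                    )
                seen.add(f.feature_id)
                if f.end > contig.length:
                    raise FormatError(
                        f"feature {f.feature_id!r} ends at {f.end}, beyond "
                        f"contig {contig.contig_id!r} length {contig.length}"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes ``protein_id``.  The
    description is scanned for ``organism=...`` (value runs to the next
    ``key=`` token or end of line), ``gene=`` (source feature id) and
    ``pfam=`` (comma-separated family accessions) keys.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"protein {rec.id!r} in {path} has an empty sequence")
        kv = _parse_description(rec.description)
        families = frozenset(
            x for x in kv.get("pfam", "").split(",") if x
        )
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=seq,
                organism=kv.get("organism", ""),
                source_gene=kv.get("gene") or None,
                families=families,
            )
        )
    return records


def _parse_description(description: str) -> dict[str, str]:
    # "p1 organism=Bacillus velezensis gene=f3 pfam=PF00202" — values may
    # contain spaces, so a value runs until the next token containing "=".
    tokens = description.split()[1:]
    out: dict[str, str] = {}
    key: str | None = None
    buf: list[str] = []
    for tok in tokens:
        if "=" in tok:
            if key is not None:
                out[key] = " ".join(buf)
            key, _, first = tok.partition("=")
            buf = [first] if first else []
        elif key is not None:
            buf.append(tok)
    if key is not None:
        out[key] = " ".join(buf)
    return out


def write_fasta(records: Sequence[ProteinRecord], path: str | os.PathLike) -> None:
    """Write proteins as FASTA, 60 columns per line, metadata as key=value."""
    seqrecords = []
    for r in records:
        desc_parts = []
        if r.organism:
            desc_parts.append(f"organism={r.organism}")
        if r.source_gene:
            desc_parts.append(f"gene={r.source_gene}")
        if r.families:
            desc_parts.append("pfam=" + ",".join(sorted(r.families)))
        seqrecords.append(
            SeqRecord(Seq(r.sequence), id=r.protein_id, description=" ".join(desc_parts))
        )
    with open(path, "w") as fh:
        # Biopython's fasta writer wraps at 60 columns
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_annotations(
    gff_path: str | os.PathLike,
    fasta_path: str | os.PathLike | None = None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Parse a GFF3 annotation (CDS rows) into a :class:`GenomeRecord`.

    Contig lengths come from ``##sequence-region`` pragmas, or from the
    companion contig FASTA when given.  Circularity is read from a ``region``
    feature carrying the INSDC ``Is_circular=true`` attribute.  Both
    ``Dbxref=Pfam:PFxxxxx`` and a custom ``pfam=`` attribute populate
    ``families``.  Features exceeding their contig length are an error, never
    clamped.
    """
    gff_path = os.fspath(gff_path)
    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    lengths: dict[str, int] = {}
    organism = ""
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                lengths[parts[1]] = int(parts[3])
        elif directive.startswith("organism"):
            organism = directive.partition(" ")[2].strip()
    if fasta_path is not None:
        for rec in SeqIO.parse(os.fspath(fasta_path), "fasta"):
            lengths[rec.id] = len(rec.seq)

    circular: dict[str, bool] = {}
    contig_order: list[str] = []
    features_by_contig: dict[str, list[GeneFeature]] = {}
    for f in db.all_features(order_by=("seqid", "start", "end")):
        if f.seqid not in contig_order:
            contig_order.append(f.seqid)
            features_by_contig[f.seqid] = []
        if f.featuretype == "region":
            is_circ = [v.lower() for v in f.attributes.get("Is_circular", [])]
            circular[f.seqid] = "true" in is_circ
            continue
        if f.featuretype != "CDS":
            continue
        if f.strand not in ("+", "-"):
            raise FormatError(
                f"{gff_path}: CDS at {f.seqid}:{f.start} has unknown strand "
                f"{f.strand!r}"
            )
        families: set[str] = set()
        for xref in f.attributes.get("Dbxref", []):
            prefix, _, acc = xref.partition(":")
            if prefix.lower() == "pfam" and acc:
                families.add(acc)
        for val in f.attributes.get("pfam", []):
            families.update(x for x in val.split(",") if x)
        feature_id = (f.attributes.get("ID") or [f.id])[0]
        protein_id = (f.attributes.get("protein_id") or [None])[0]
        product = (f.attributes.get("product") or [""])[0]
        features_by_contig[f.seqid].append(
            GeneFeature(
                feature_id=feature_id,
                contig_id=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand,
                protein_id=protein_id,
                product=product,
                families=frozenset(families),
            )
        )

    contigs = []
    for cid in contig_order or sorted(lengths):
        feats = features_by_contig.get(cid, [])
        if cid not in lengths:
            raise FormatError(
                f"{gff_path}: no length for contig {cid!r} "
                "(missing ##sequence-region and no FASTA given)"
            )
        contigs.append(
            Contig(
                contig_id=cid,
                length=lengths[cid],
                circular=circular.get(cid, False),
                features=feats,
            )
        )
    gid = genome_id or os.path.splitext(os.path.basename(gff_path))[0]
    return GenomeRecord(genome_id=gid, organism=organism, contigs=contigs)


def write_annotations(genome: GenomeRecord, gff_path: str | os.PathLike) -> None:
    """Write a :class:`GenomeRecord` as GFF3 (CDS rows plus region features)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome.organism:
            fh.write(f"##organism {genome.organism}\n")
        for contig in genome.contigs:
            fh.write(f"##sequence-region {contig.contig_id} 1 {contig.length}\n")
        for contig in genome.contigs:
            circ = "true" if contig.circular else "false"
            fh.write(
                f"{contig.contig_id}\tazamine\tregion\t1\t{contig.length}\t.\t+\t.\t"
                f"ID=region-{contig.contig_id};Is_circular={circ}\n"
            )
            for f in contig.features:
                attrs = [f"ID={f.feature_id}"]
                if f.protein_id:
                    attrs.append(f"protein_id={f.protein_id}")
                if f.product:
                    attrs.append(f"product={f.product}")
                for fam in sorted(f.families):
                    attrs.append(f"Dbxref=Pfam:{fam}")
                fh.write(
                    f"{f.contig_id}\tazamine\tCDS\t{f.start}\t{f.end}\t.\t"
                    f"{f.strand}\t0\t{';'.join(attrs)}\n"
                )


# ---------------------------------------------------------------------------
# Networks

_NODE_ATTRS = ("organism", "genus", "cluster_id", "singleton", "colors",
               "phosphatase_class")
_EDGE_ATTRS = ("percent_identity", "bit_score", "evalue", "alignment_score")


def write_network(net, path: str | os.PathLike, fmt: str = "graphml") -> None:
    """Export a similarity network as GraphML or a TSV edge list.

    GraphML carries node attributes (organism, genus, cluster id, neighborhood
    colors) and edge attributes (percent identity, bit score, E-value,
    alignment score).  The edge list is a TSV with a header row.
    """
    graph = net.graph
    for u, v in graph.edges():
        if u not in graph.nodes or v not in graph.nodes:  # pragma: no cover
            raise FormatError(f"edge ({u}, {v}) references an absent node")
    if fmt == "graphml":
        export = nx.Graph()
        for node, data in graph.nodes(data=True):
            clean = {}
            for key in _NODE_ATTRS:
                if key in data and data[key] is not None:
                    value = data[key]
                    if isinstance(value, (set, frozenset, list, tuple)):
                        value = ",".join(sorted(map(str, value)))
                    clean[key] = value
            export.add_node(node, **clean)
        for u, v, data in graph.edges(data=True):
            export.add_edge(
                u, v, **{k: float(data[k]) for k in _EDGE_ATTRS if k in data}
            )
        nx.write_graphml(export, os.fspath(path))
    elif fmt == "edgelist_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\t" + "\t".join(_EDGE_ATTRS) + "\n")
            for u, v, data in sorted(graph.edges(data=True)):
                vals = "\t".join(f"{data.get(k, float('nan')):.6g}" for k in _EDGE_ATTRS)
                fh.write(f"{u}\t{v}\t{vals}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_graphml(path: str | os.PathLike):
    """Read a GraphML export back; returns a SimilarityNetwork.

    Node ``colors`` round-trip as comma-joined sorted strings.
    """
    from .ssn import SimilarityNetwork  # local import to avoid a cycle

    graph = nx.read_graphml(os.fspath(path))
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        if "colors" in data and isinstance(data["colors"], str):
            data = dict(data)
            data["colors"] = frozenset(x for x in data["colors"].split(",") if x)
        out.add_node(node, **data)
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, **data)
    return SimilarityNetwork(graph=out, threshold_spec=None)
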
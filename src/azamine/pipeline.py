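"""End-to-end orchestration: simulate -> align -> SSN -> color -> detect ->
consensus -> screen -> tree, with plain-file handoffs and a manifest.

Every stage writes ordinary files (TSV/GraphML/FASTA/GFF3/Newick/JSON) into
a run directory, so stages are individually testable and replaceable.  All
randomness flows from the single configured seed; rerunning with the same
config reproduces identical non-log outputs, and the manifest (parameters,
seed, package version, input checksums) suffices to reproduce any run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .align import DEFAULT_EVALUE_CUTOFF, all_vs_all, hits_to_frame
from .detect import clusters_table, find_3gc, merge_hit_sets, tabulate_producers
from .io_formats import write_fasta, write_network
from .motif import (
    AZA_AMINOTRANSFERASE_MOTIF,
    derive_consensus,
    progressive_msa,
    screen_and_validate,
)
from .neighborhoods import (
    ActivitySchema,
    DEFAULT_COOCCURRENCE,
    DEFAULT_WINDOW,
    cluster_cooccurrence,
    color_nodes,
    cooccurrence_table,
)
from .phylo import PhyloTree, neighbor_joining, p_distance, robinson_foulds
from .ssn import build_network, cluster_network, threshold_sweep
from .synthetic import SyntheticConfig, generate_dataset, write_dataset

log = logging.getLogger("azamine")

_KNOWN_KEYS = {
    "out_dir", "rng_seed", "identity_thresholds", "evalue_cutoff", "window",
    "cooccurrence", "genus_min", "schema", "motif", "mismatch_budget",
    "simulate", "taxonomy_newick", "log_level",
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    ``simulate`` holds keyword arguments for :class:`SyntheticConfig`
    (the pipeline's packaged demo substrate); point the pipeline at real
    annotations by swapping the simulate stage for your own GFF3+FASTA and
    running the remaining subcommands on those files.
    """

    out_dir: str = "run"
    rng_seed: int = 0
    identity_thresholds: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0)
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    window: int = DEFAULT_WINDOW
    cooccurrence: float = DEFAULT_COOCCURRENCE
    genus_min: int = 5
    schema: dict | None = None
    motif: str = AZA_AMINOTRANSFERASE_MOTIF
    mismatch_budget: int = 0
    simulate: dict = field(default_factory=dict)
    taxonomy_newick: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.identity_thresholds:
            raise ValueError("need at least one identity threshold")
        if any(not (0 <= t <= 100) for t in self.identity_thresholds):
            raise ValueError("identity thresholds must lie in [0, 100]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 <= self.cooccurrence <= 1):
            raise ValueError("cooccurrence must lie in [0, 1]")
        if self.genus_min < 1:
            raise ValueError("genus_min must be >= 1")
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "identity_thresholds" in data:
            data["identity_thresholds"] = tuple(data["identity_thresholds"])
        return cls(**data)

    def activity_schema(self) -> ActivitySchema:
        if self.schema is None:
            return ActivitySchema.default()
        return ActivitySchema.from_mapping(self.schema)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig) -> str:
    """Run every stage into ``config.out_dir``; returns the run directory.

    Any stage failure aborts with the stage name; partial outputs of earlier
    stages are retained on disk.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage = "simulate"
    try:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", config.rng_seed)
        sim = SyntheticConfig(**sim_kwargs)
        genomes, proteome, truth = generate_dataset(sim)
        data_dir = os.path.join(out, "data")
        write_dataset(genomes, proteome, truth, data_dir)
        log.info("simulated %d genomes (%d positive)", len(genomes),
                 len(truth.clusters))

        schema = config.activity_schema()
        by_activity = {
            name: [p for p in proteome if schema[name] & p.families]
            for name in ("aminotransferase", "dehydrogenase")
        }

        stage = "align"
        hits = {}
        for name, records in by_activity.items():
            hits[name] = all_vs_all(records, evalue_cutoff=config.evalue_cutoff)
            hits_to_frame(hits[name]).to_csv(
                os.path.join(out, f"hits_{name}.tsv"), sep="\t", index=False
            )

        stage = "ssn"
        nets = {}
        for name, records in by_activity.items():
            sweep = threshold_sweep(
                hits[name], config.identity_thresholds,
                records=records,
            )
            sweep.to_csv(os.path.join(out, f"sweep_{name}.tsv"), sep="\t",
                         index=False)
            net = cluster_network(
                build_network(
                    hits[name],
                    ("percent_identity", config.identity_thresholds[0]),
                    records=records,
                )
            )
            nets[name] = net

        stage = "color"
        for name, net in nets.items():
            profiles = color_nodes(net, genomes, schema, config.window)
            cooc = cluster_cooccurrence(net, profiles, config.cooccurrence)
            cooccurrence_table(cooc).to_csv(
                os.path.join(out, f"cooccurrence_{name}.tsv"), sep="\t",
                index=False,
            )
            write_network(net, os.path.join(out, f"ssn_{name}.graphml"))

        stage = "detect"
        at_clusters = find_3gc(genomes, schema, "aminotransferase",
                               config.window)
        dh_clusters = find_3gc(genomes, schema, "dehydrogenase", config.window)
        ssn_cluster_of = {
            n: nets["aminotransferase"].node(n).get("cluster_id")
            for n in nets["aminotransferase"].nodes()
        }
        clusters_table(at_clusters, ssn_cluster_of).to_csv(
            os.path.join(out, "3gc_table.tsv"), sep="\t", index=False
        )
        merged = merge_hit_sets(
            at_ssn={c.genome_id for c in at_clusters},
            dh_ssn={c.genome_id for c in dh_clusters},
        )
        with open(os.path.join(out, "merged_hits.json"), "w") as fh:
            json.dump({g: sorted(s) for g, s in sorted(merged.items())}, fh,
                      indent=2)
        tabulate_producers(at_clusters + dh_clusters, config.genus_min).to_csv(
            os.path.join(out, "producers_by_genus.tsv"), sep="\t", index=False
        )
        log.info("detected 3GCs in %d genomes", len(merged))

        stage = "consensus"
        detected_at_ids = {c.at_feature.protein_id for c in at_clusters}
        at_records = [p for p in proteome if p.protein_id in detected_at_ids]
        consensus_path = os.path.join(out, "consensus.txt")
        if len(at_records) >= 2:
            msa = progressive_msa(at_records)
            msa.write_fasta(os.path.join(out, "aminotransferases.afa"))
            consensus = derive_consensus(msa)
            with open(consensus_path, "w") as fh:
                fh.write(consensus.pattern + "\n")
        else:
            msa = None
            with open(consensus_path, "w") as fh:
                fh.write("\n")

        stage = "screen"
        report = screen_and_validate(proteome, config.motif,
                                     at_clusters + dh_clusters,
                                     config.mismatch_budget)
        with open(os.path.join(out, "screen_report.json"), "w") as fh:
            json.dump(
                {
                    "n_in_3gc": report.n_in_3gc,
                    "n_not_in_3gc": report.n_not_in_3gc,
                    "n_unmapped": report.n_unmapped,
                    "precision": report.precision,
                    "n_proteins_hit": report.n_proteins_hit,
                    "n_organisms_hit": report.n_organisms_hit,
                    "hits": report.hits,
                },
                fh, indent=2, sort_keys=True,
            )

        stage = "tree"
        tree_info: dict = {}
        if msa is not None and len(msa.ids) >= 3:
            gene_tree = neighbor_joining(p_distance(msa))
            gene_tree.write_newick(os.path.join(out, "gene_tree.nwk"))
            tree_info["clamped_branches"] = gene_tree.clamped_branches
            if config.taxonomy_newick:
                taxo = PhyloTree.from_newick(config.taxonomy_newick,
                                             is_path=True)
                rf, norm = robinson_foulds(gene_tree, taxo)
                tree_info.update({"rf": rf, "rf_normalized": norm})
        with open(os.path.join(out, "tree_info.json"), "w") as fh:
            json.dump(tree_info, fh, indent=2, sort_keys=True)

        stage = "manifest"
        manifest = {
            "azamine_version": __version__,
            "seed": config.rng_seed,
            "parameters": {
                k: v for k, v in dataclasses.asdict(config).items()
                if k != "out_dir"
            },
            "input_checksums": {
                f: _sha256(os.path.join(data_dir, f))
                for f in sorted(os.listdir(data_dir))
            },
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
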
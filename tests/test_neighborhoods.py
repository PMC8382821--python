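import numpy as np
import pytest

from azamine.align import all_vs_all
from azamine.io_formats import Contig, GeneFeature, GenomeRecord, ProteinRecord
from azamine.neighborhoods import (
    ActivitySchema,
    classify_phosphatase,
    cluster_cooccurrence,
    color_nodes,
    extract_neighborhood,
)
from azamine.ssn import build_network, cluster_network
from _oracles import neighborhood_indices


def toy_genome(n_genes: int, circular: bool = False,
               families: list[frozenset] | None = None,
               strands: str | None = None) -> GenomeRecord:
    feats = []
    for i in range(n_genes):
        start = 100 + i * 1000
        feats.append(
            GeneFeature(
                feature_id=f"f{i}", contig_id="c1", start=start,
                end=start + 800,
                strand=(strands[i] if strands else "+"),
                protein_id=f"p{i}",
                families=families[i] if families else frozenset(),
            )
        )
    return GenomeRecord(
        genome_id="g", organism="Bacillus synthetica",
        contigs=[Contig("c1", 100 + n_genes * 1000 + 1000, circular, feats)],
    )


class TestExtractNeighborhood:
    def test_linear_start_boundary_truncates(self):
        genome = toy_genome(6)
        profile = extract_neighborhood(genome, "f0", window=3)
        assert [off for off, _ in profile.neighbors] == [1, 2, 3]

    def test_circular_five_genes_window_three(self):
        genome = toy_genome(5, circular=True)
        profile = extract_neighborhood(genome, "f0", window=3)
        ids = [f.feature_id for _, f in profile.neighbors]
        assert len(ids) == 4  # all other genes, no double counting
        assert len(set(ids)) == 4

    def test_matches_enumeration_oracle_on_random_contigs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            circular = bool(rng.integers(2))
            window = int(rng.integers(1, 5))
            genome = toy_genome(n, circular=circular)
            idx = int(rng.integers(n))
            profile = extract_neighborhood(genome, f"f{idx}", window)
            got = {f.feature_id for _, f in profile.neighbors}
            expected = {
                f"f{j}"
                for j in neighborhood_indices(n, idx, window, circular)
            }
            assert got == expected
            offsets = [off for off, _ in profile.neighbors]
            assert offsets == sorted(offsets)
            assert all(0 < abs(off) <= window for off in offsets)

    def test_consecutive_cluster_layout_offsets(self):
        # aminotransferase, phosphatase, dehydrogenase consecutive with
        # transporters beyond: the dehydrogenase sits at +2 from the focal
        fams = [frozenset({"PF00202"}), frozenset({"PF00459"}),
                frozenset({"PF00107"}), frozenset({"PF99001"}),
                frozenset({"PF99002"})]
        genome = toy_genome(5, families=fams)
        profile = extract_neighborhood(genome, "f0", window=3)
        by_offset = {off: f for off, f in profile.neighbors}
        assert "PF00107" in by_offset[2].families

    def test_strand_invariance(self, rng):
        fams = [frozenset({f"PF9000{i}"}) for i in range(7)]
        forward = toy_genome(7, families=fams, strands="+++++++")
        mixed = toy_genome(7, families=fams, strands="+-+--+-")
        for fid in ("f0", "f3", "f6"):
            a = extract_neighborhood(forward, fid, 3)
            b = extract_neighborhood(mixed, fid, 3)
            assert [(off, f.feature_id) for off, f in a.neighbors] == \
                   [(off, f.feature_id) for off, f in b.neighbors]

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            extract_neighborhood(toy_genome(3), "nope", 3)


class TestSchema:
    def test_default_families(self):
        schema = ActivitySchema.default()
        assert schema["aminotransferase"] == {"PF00202"}
        assert schema["dehydrogenase"] == {"PF00107", "PF08240", "PF16912"}
        assert schema["phosphatase"] == {"PF13419", "PF00459", "PF12710",
                                         "PF07081"}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ActivitySchema.from_mapping(
                {"a": ["PF1"], "b": ["PF1", "PF2"]}
            )

    def test_phosphatase_classes(self):
        assert classify_phosphatase({"PF00459"}) == "inositol_phosphatase"
        assert classify_phosphatase({"PF13419"}) == "HAD_hydrolase"
        assert classify_phosphatase({"PF12710", "PF07081"}) == "HAD_hydrolase"
        assert classify_phosphatase({"PF00459", "PF13419"}) == "both"
        assert classify_phosphatase({"PF99999"}) == "none"


def colored_net_from(small_dataset):
    genomes, proteome, truth = small_dataset
    schema = ActivitySchema.default()
    at_records = [p for p in proteome if schema["aminotransferase"] & p.families]
    hits = all_vs_all(at_records)
    net = cluster_network(
        build_network(hits, ("percent_identity", 40.0), records=at_records)
    )
    profiles = color_nodes(net, genomes, schema)
    return net, profiles, truth, genomes


class TestColorNodes:
    def test_planted_nodes_carry_both_partner_activities(self, small_dataset):
        net, profiles, truth, _ = colored_net_from(small_dataset)
        planted_at_pids = set()
        genomes = {g.genome_id: g for g in small_dataset[0]}
        for gid, info in truth.clusters.items():
            feats = {f.feature_id: f for f in genomes[gid].features()}
            planted_at_pids.add(feats[info["members"]["A"]].protein_id)
        for node in planted_at_pids:
            colors = net.node(node)["colors"]
            assert {"dehydrogenase", "phosphatase"} <= colors
            assert net.node(node)["phosphatase_class"] in (
                "inositol_phosphatase", "HAD_hydrolase"
            )

    def test_two_gene_decoy_missing_phosphatase_class(self):
        fams = [frozenset({"PF00202"}), frozenset({"PF00107"}),
                frozenset({"PF99001"})]
        genome = toy_genome(3, families=fams)
        records = [ProteinRecord("p0", "MKVLAW" * 20, organism="Erwinia x")]
        net = cluster_network(
            build_network([], ("percent_identity", 40), records=records)
        )
        color_nodes(net, [genome])
        assert net.node("p0")["phosphatase_class"] == "none"
        assert net.node("p0")["colors"] == {"dehydrogenase"}

    def test_conflicting_phosphatase_families_flagged_both(self):
        fams = [frozenset({"PF00202"}), frozenset({"PF00459"}),
                frozenset({"PF13419"})]
        genome = toy_genome(3, families=fams)
        records = [ProteinRecord("p0", "MKVLAW" * 20, organism="Erwinia x")]
        net = cluster_network(
            build_network([], ("percent_identity", 40), records=records)
        )
        with pytest.warns(UserWarning, match="both"):
            color_nodes(net, [genome])
        assert net.node("p0")["phosphatase_class"] == "both"

    def test_unmapped_node_flagged_not_dropped(self):
        records = [ProteinRecord("ghost", "MKVLAW" * 20)]
        net = cluster_network(
            build_network([], ("percent_identity", 40), records=records)
        )
        with pytest.warns(UserWarning, match="no genomic mapping"):
            color_nodes(net, [toy_genome(2)])
        assert net.node("ghost")["unmapped"] is True


class TestCooccurrence:
    def test_planted_cluster_fractions_are_one(self):
        # with decoys that carry no schema genes, the aminotransferase
        # cluster is purely planted copies: every node neighbors one
        # dehydrogenase and one phosphatase family member
        from azamine.synthetic import SyntheticConfig, generate_dataset

        dataset = generate_dataset(
            SyntheticConfig(rng_seed=17, n_genomes=8, n_planted_3gc=5,
                            decoy_spec={"none": 3})
        )
        net, profiles, truth, _ = colored_net_from(dataset)
        cooc = cluster_cooccurrence(net, profiles)
        main = max(cooc, key=lambda c: len(net.clusters()[c.cluster_id]))
        dh_fams = {"PF00107", "PF08240", "PF16912"}
        ph_fams = {"PF13419", "PF00459", "PF12710", "PF07081"}
        assert sum(main.fractions.get(f, 0.0) for f in dh_fams) == \
            pytest.approx(1.0)
        assert sum(main.fractions.get(f, 0.0) for f in ph_fams) == \
            pytest.approx(1.0)

    def test_fractions_match_brute_force_recount(self, small_dataset):
        net, profiles, truth, _ = colored_net_from(small_dataset)
        for cooc in cluster_cooccurrence(net, profiles):
            members = net.clusters()[cooc.cluster_id]
            for fam, frac in cooc.fractions.items():
                count = sum(
                    1 for node in members
                    if node in profiles and any(
                        fam in f.families for _, f in profiles[node].neighbors
                    )
                )
                assert frac == pytest.approx(count / len(members))

    def test_reporting_threshold_excludes_rare_families(self):
        from azamine.neighborhoods import ClusterCooccurrence

        cooc = ClusterCooccurrence(cluster_id=1,
                                   fractions={"PF00459": 0.1, "PF13419": 0.2})
        assert cooc.reported() == {"PF13419": 0.2}
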
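import numpy as np
import pytest

from azamine.detect import find_3gc
from azamine.io_formats import ProteinRecord
from azamine.motif import (
    AZA_AMINOTRANSFERASE_MOTIF,
    ConsensusMotif,
    MultipleAlignment,
    derive_consensus,
    instantiate_motif,
    progressive_msa,
    scan_motif,
    screen_and_validate,
)
from azamine.synthetic import (
    SEED_AMINOTRANSFERASE,
    SyntheticConfig,
    generate_dataset,
    mutate_protein,
)
from _oracles import scan_positions
from conftest import random_protein


class TestProgressiveMsa:
    def test_identical_pair_gap_free(self):
        recs = [ProteinRecord("a", "MKVLAWCD"), ProteinRecord("b", "MKVLAWCD")]
        msa = progressive_msa(recs)
        assert msa.rows == ["MKVLAWCD", "MKVLAWCD"]

    def test_single_substitution_gap_free(self):
        recs = [ProteinRecord("a", "MKVLAWCD"), ProteinRecord("b", "MKVLAYCD")]
        msa = progressive_msa(recs)
        assert "-" not in "".join(msa.rows)
        mismatch_cols = [
            j for j in range(msa.n_columns)
            if msa.rows[0][j] != msa.rows[1][j]
        ]
        assert len(mismatch_cols) == 1

    def test_mutated_copies_align_full_length(self):
        recs = [
            ProteinRecord(f"c{i}", mutate_protein(SEED_AMINOTRANSFERASE,
                                                  0.8, 300 + i))
            for i in range(6)
        ]
        msa = progressive_msa(recs)
        assert msa.n_columns == len(SEED_AMINOTRANSFERASE)
        for i in range(6):
            assert msa.degapped(i) == recs[i].sequence

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([ProteinRecord("a", "MKV")])

    def test_round_trip_formats(self, tmp_path):
        msa = MultipleAlignment(ids=["a", "b"], rows=["MKV-LAW", "MKVQLAW"])
        path = tmp_path / "aln.afa"
        msa.write_fasta(path)
        back = MultipleAlignment.read_fasta(path)
        assert back.ids == msa.ids and back.rows == msa.rows
        msa.write_clustal(tmp_path / "aln.aln")  # writes without error


class TestDeriveConsensus:
    def test_unanimous_column_uppercase(self):
        msa = MultipleAlignment(ids=list("abcdef"), rows=["A"] * 6)
        assert derive_consensus(msa).pattern == "A"

    def test_plurality_tie_gives_x(self):
        msa = MultipleAlignment(ids=list("abcdef"),
                                rows=["A", "A", "A", "G", "G", "G"])
        assert derive_consensus(msa).pattern == "X"

    def test_identical_rows_reproduce_sequence_uppercase(self, rng):
        seq = random_protein(rng, 40)
        msa = MultipleAlignment(ids=list("abcd"), rows=[seq] * 4)
        assert derive_consensus(msa).pattern == seq

    def test_weak_fraction_lowercase(self):
        # 3/6 = 0.5 -> lowercase; 5/6 = 0.83 -> lowercase; 6/6 -> uppercase
        rows = ["AC", "AC", "AC", "GC", "TC", "WC"]
        msa = MultipleAlignment(ids=list("abcdef"), rows=rows)
        assert derive_consensus(msa).pattern == "aC"

    def test_all_gap_column_gives_x(self):
        msa = MultipleAlignment(ids=list("ab"), rows=["A-C", "A-C"])
        assert derive_consensus(msa).pattern == "AXC"

    def test_row_permutation_invariant(self, rng):
        rows = [random_protein(rng, 30) for _ in range(5)]
        ids = [f"r{i}" for i in range(5)]
        base = derive_consensus(MultipleAlignment(ids=ids, rows=rows))
        perm = np.random.default_rng(0).permutation(5)
        shuffled = derive_consensus(MultipleAlignment(
            ids=[ids[i] for i in perm], rows=[rows[i] for i in perm]
        ))
        assert base.pattern == shuffled.pattern


class TestScanMotif:
    def test_packaged_motif_shape(self):
        motif = ConsensusMotif(AZA_AMINOTRANSFERASE_MOTIF)
        assert len(motif) == 30
        assert motif.constrained_count == 16
        assert AZA_AMINOTRANSFERASE_MOTIF.count("X") == 14

    def test_planted_instance_found_once(self, rng):
        inst = instantiate_motif(AZA_AMINOTRANSFERASE_MOTIF, rng)
        seq = random_protein(rng, 90) + inst + random_protein(rng, 60)
        hits = scan_motif(seq, AZA_AMINOTRANSFERASE_MOTIF)
        assert hits == [(91, 0)]

    def test_motif_longer_than_sequence_is_empty(self):
        assert scan_motif("MKV", AZA_AMINOTRANSFERASE_MOTIF) == []

    def test_case_insensitive_and_wildcards(self):
        hits = scan_motif("aagnwcc", ConsensusMotif("GnX"), 0)
        assert hits == [(3, 0)]

    def test_mismatch_budget(self, rng):
        inst = instantiate_motif(AZA_AMINOTRANSFERASE_MOTIF, rng)
        broken = "A" + inst[1:]  # breaks the constrained S at position 1
        assert scan_motif(broken, AZA_AMINOTRANSFERASE_MOTIF, 0) == []
        assert scan_motif(broken, AZA_AMINOTRANSFERASE_MOTIF, 1) == [(1, 1)]

    def test_overlapping_matches_all_reported(self):
        hits = scan_motif("AAAA", ConsensusMotif("AA"))
        assert hits == [(1, 0), (2, 0), (3, 0)]

    def test_matches_positional_oracle_on_random_sequences(self, rng):
        for _ in range(100):
            seq = random_protein(rng, int(rng.integers(30, 80)))
            pattern = "".join(
                "X" if rng.random() < 0.4 else random_protein(rng, 1)
                for _ in range(int(rng.integers(2, 8)))
            )
            budget = int(rng.integers(0, 3))
            got = scan_motif(seq, ConsensusMotif(pattern), budget)
            assert got == scan_positions(seq, pattern, budget)

    def test_random_match_rate_matches_analytic_null(self, rng):
        # 16 constrained positions: P(exact match) = 20^-16 per offset,
        # so >= 1e6 offsets should give 0 matches (3 sigma ~ 0.0002)
        n_offsets = 0
        n_hits = 0
        for _ in range(40):
            seq = random_protein(rng, 25_030)
            hits = scan_motif(seq, AZA_AMINOTRANSFERASE_MOTIF)
            n_offsets += len(seq) - 30 + 1
            n_hits += len(hits)
        assert n_offsets >= 1_000_000
        expected = n_offsets * 20.0 ** -16
        sigma = np.sqrt(expected)
        assert abs(n_hits - expected) <= max(3 * sigma, 1e-6)
        assert n_hits == 0


class TestScreenAndValidate:
    def make(self, n_planted, motif_plants, decoy_motif_plants=0, seed=31):
        config = SyntheticConfig(
            rng_seed=seed, n_genomes=n_planted + 4,
            n_planted_3gc=n_planted, motif_plants=motif_plants,
            decoy_motif_plants=decoy_motif_plants,
            decoy_spec={"two_gene": 2, "none": 2},
        )
        genomes, proteome, truth = generate_dataset(config)
        clusters = find_3gc(genomes)
        return proteome, clusters, truth

    def test_all_planted_hits_in_3gc_precision_one(self):
        proteome, clusters, truth = self.make(20, 20)
        report = screen_and_validate(proteome, AZA_AMINOTRANSFERASE_MOTIF,
                                     clusters)
        assert report.n_in_3gc == 20
        assert report.n_not_in_3gc == 0
        assert report.precision == 1.0
        found = {h["protein_id"] for h in report.hits}
        assert found == set(truth.motif_plants)

    def test_decoy_instantiation_reduces_precision(self):
        proteome, clusters, _ = self.make(19, 19, decoy_motif_plants=1)
        report = screen_and_validate(proteome, AZA_AMINOTRANSFERASE_MOTIF,
                                     clusters)
        assert report.n_in_3gc == 19
        assert report.n_not_in_3gc == 1
        assert report.precision == pytest.approx(0.95)

    def test_no_hits_means_undefined_precision(self):
        proteome, clusters, _ = self.make(3, 0)
        report = screen_and_validate(proteome, AZA_AMINOTRANSFERASE_MOTIF,
                                     clusters)
        assert report.precision is None

    def test_unmapped_hit_warns_and_excluded(self, rng):
        inst = instantiate_motif(AZA_AMINOTRANSFERASE_MOTIF, rng)
        orphan = ProteinRecord("orphan", random_protein(rng, 50) + inst)
        with pytest.warns(UserWarning, match="no gene mapping"):
            report = screen_and_validate([orphan],
                                         AZA_AMINOTRANSFERASE_MOTIF, [])
        assert report.n_unmapped == 1
        assert report.precision is None
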
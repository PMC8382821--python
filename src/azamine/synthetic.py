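"""Synthetic annotated genomes with planted azasugar-like three-gene clusters.

Every downstream stage of the pipeline is exercised against data generated
here, where the ground truth is known exactly: which genomes carry a
three-gene cluster (aminotransferase + phosphatase + aminopolyol
dehydrogenase), in which of the two observed gene orders (A-P-D,
Bacilli-like, with an inositol-phosphate phosphatase; A-D-P,
Chitinophaga/Paenibacillus-like, with a HAD-hydrolase phosphatase), and
where exact consensus-motif instantiations were planted in the proteome.

Cluster member proteins are point-mutated copies of four fixed synthetic
length-400 seed enzymes committed below (real GabT1/GutB1 sequences are not
embedded).  Decoy ORFs carry dummy family accessions from a disjoint
"PF9xxxx" space so schema collisions cannot occur by chance.  Genes alternate
strand at random — the detector must be strand-agnostic — and intergenic gaps
are drawn uniformly from 50–500 bp.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    Contig,
    GeneFeature,
    GenomeRecord,
    ProteinRecord,
    write_annotations,
    write_fasta,
)
from .motif import AZA_AMINOTRANSFERASE_MOTIF, instantiate_motif

# Fixed synthetic seed enzymes (length 400 each): an aminotransferase-like,
# a dehydrogenase-like, and one phosphatase-like seed per phosphatase class.
SEED_AMINOTRANSFERASE = (
    "CNSGCPYYMPTHCYVNEFMGFWCGYCASQNPYAWRSRHCHHKRKVSFRMQQYAPLISMGM"
    "IKQFKKKCPCGWLSWWNDPETENQLSSRCWARMMMICTPTFCDPWGCGTDNYEFISGGAT"
    "ARSEFVPRMYIQAYGQKCFRPQLRCCVVNIHEHWWWERVHGCYHVYKPQYIQWAYFQLWK"
    "NHKVHDYHFIMPWHQTHKCMSKHFDKWYFYILNWVVKYNFYFSLQDWHVHCSWGKIRNYG"
    "YQVYEPRCWKEMMHEGTCHDLCDEYAKMHYEQIIQPIERFMGQANSGTGLTNAVVKERDE"
    "QMMHAREKNNYNEKWNPLIFDLKYRPYLMYTPFRSKFHRNILANWRMAKFYSIGQFKHNV"
    "MWKMLVEKYNCSKGVYYAQEPVYSIQWCRDNCRNNDAGVR"
)
SEED_DEHYDROGENASE = (
    "LLCKRKMCLQQGGIAMCCAQDTLQIWVVAWYPKCGILIAAPAKGCSGIIQIPEGQYNTPD"
    "YMVLYLLSEGHHVQVQEQRKMKHLSWALYGGKLNHGFRSGVSLDIYDNEHNYQFKDLYLF"
    "LARGFRGMEAQNRLNYYQWVHDGYKFFTNLMGCNKFYYVFMGGYPHEKQFPARRLNVIYP"
    "HSKQMPRVNKYLKTKAMDEYHHVKHPMNCERFGFLAVHSGQHRNCQCGSAYEKTPLDGEY"
    "PIIGFNADNEYRFNSEVIIDGTTRFMCVVEFAVGTFRAGDCKASHKGCHGDDQFPIDCNH"
    "HEQNREWDSDFQDQCPQELPVIEHYYDWIDFNGMDCWMHRAQHFQSCRIFILFDAFFKCL"
    "HWAQQCHWKHYQTPDQQSHFKEFWMSQMVDEMFNCFVINP"
)
SEED_PHOSPHATASE_INOSITOL = (
    "GQVHHRSRTQIKSPHEYDRCFWCISCSQDALTKDNMRVYMDHWQIMRCCPSLPHVPYHPN"
    "LQIMGRTRERFFHVAFPENYTPRIDEQTPIVFIRLEQEEKWCGQRPDKRCVTIMWVFFSP"
    "KMACIQKTAGVPMNWVAIVYQFSSDAGLYPNFPPFAACRMCEIFCECRITDTKAWLMWAE"
    "SCNIDQIVCFPWEEKASVHDEGCFAISTEEWCHRDISVAGKKGVIPMLSTDTWSMANSNL"
    "FQIMRCENGVEVPLNWGAIMFISSNHPQLYFEDYRSDMPDGKWDRQRAKPFPMGQGDETM"
    "HNNIVNWVETQAYLHRVTTEKLHEMCTHHYSAVAFTQFFVVYKNCGNGFQSGYNMSSYRH"
    "DRFREGQSPSEESCLKTTQIAGEMHLGRSMRGWHDTWNYL"
)
SEED_PHOSPHATASE_HAD = (
    "KVWHGRGISYNSVHHDFQGKQFSIQCTALNQIAEEVNMHMPWCKEHLASYHENPNIKKYG"
    "FHYDACGLSQAAKKPYTKPCAIPLIKEFPSWDQINHVYMCPYPGLGITVQRFCIMVEHTH"
    "TENKGRDPDPALFWLAALWQQGNGCFNARGQMGSASLNSPRKVDGIRRKGPMVPGYHADT"
    "EGFFLQAAIQHDGEAPRPKQGFLHAFNSEEVICSNGHLQEWDGQNAINAYSWDFEYNPGC"
    "DPFSGTNMIKTETLPMMSRAMFMRFGDDSPDHKCICCSAFFSGWTEIRTSCLHIQQNSWE"
    "SNMHKYNRVWHFMQWGFFKHWQVNHLMPSNTEFWLVLWIEACWPMPKRMLRQEYHCNGPF"
    "RLMWNPKRFTSSHEPFPNKDRYLALHMQWCFLRVVKFEDN"
)

SEEDS = {
    "aminotransferase": SEED_AMINOTRANSFERASE,
    "dehydrogenase": SEED_DEHYDROGENASE,
    "phosphatase_inositol": SEED_PHOSPHATASE_INOSITOL,
    "phosphatase_had": SEED_PHOSPHATASE_HAD,
}

# family accessions assigned to planted members, one per activity/class
FAMILY_AT = "PF00202"
FAMILY_DH = ("PF00107", "PF08240", "PF16912")
FAMILY_PH_INOSITOL = "PF00459"
FAMILY_PH_HAD = ("PF13419", "PF12710", "PF07081")

_POSITIVE_GENERA = ("Bacillus", "Paenibacillus", "Chitinophaga",
                    "Streptomyces", "Xenorhabdus", "Photorhabdus")
_DECOY_GENERA = ("Escherichia", "Pseudomonas", "Vibrio", "Listeria")

#: where in the planted aminotransferase the motif instantiation is written
#: (1-based; mirrors the diagnostic span around positions 145-174)
MOTIF_PLANT_POSITION = 146


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``target_identity_to_seed`` is the ungapped identity of each planted
    member to its seed enzyme; the default 0.7 gives within-set pairwise
    identities near 50%, inside the 40-50% working range of the network
    thresholds.  ``order_signature`` / ``phosphatase_class`` may be "mixed",
    in which case positives cycle jointly through the two observed
    combinations (A-P-D with an inositol phosphatase, A-D-P with a HAD
    hydrolase).  ``decoy_spec`` counts genomes with an incomplete cluster
    (two_gene), all three activities scattered beyond the window (scattered),
    or no schema family at all (none).
    """

    rng_seed: int = 0
    n_genomes: int = 10
    n_planted_3gc: int = 5
    target_identity_to_seed: float = 0.7
    order_signature: str = "mixed"  # "A-P-D" | "A-D-P" | "mixed"
    phosphatase_class: str = "mixed"  # "inositol_phosphatase" | "HAD_hydrolase" | "mixed"
    window_spacing: int = 3
    decoy_spec: dict = field(
        default_factory=lambda: {"two_gene": 2, "scattered": 2, "none": 1}
    )
    motif_plants: int = 0
    decoy_motif_plants: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_identity_to_seed <= 1):
            raise ValueError("target_identity_to_seed must be in (0, 1]")
        if self.window_spacing < 1:
            raise ValueError("window_spacing must be >= 1")
        counts = [self.n_genomes, self.n_planted_3gc, self.motif_plants,
                  self.decoy_motif_plants, *self.decoy_spec.values()]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.order_signature not in ("A-P-D", "A-D-P", "mixed"):
            raise ValueError(f"unknown order_signature {self.order_signature!r}")
        if self.phosphatase_class not in (
            "inositol_phosphatase", "HAD_hydrolase", "mixed"
        ):
            raise ValueError(f"unknown phosphatase_class {self.phosphatase_class!r}")
        if self.n_planted_3gc + sum(self.decoy_spec.values()) > self.n_genomes:
            raise ValueError("more planted + decoy genomes than n_genomes")
        if self.motif_plants > self.n_planted_3gc:
            raise ValueError("motif_plants cannot exceed n_planted_3gc")


@dataclass
class GroundTruth:
    """What was planted where; the reference for every downstream check."""

    #: genome_id -> {"members": {"A": fid, "D": fid, "P": fid},
    #:               "order": "APD"/"ADP", "phosphatase_class": ...}
    clusters: dict[str, dict] = field(default_factory=dict)
    #: genome_id -> decoy kind ("two_gene" | "scattered" | "none")
    decoys: dict[str, str] = field(default_factory=dict)
    #: protein_id -> list of 1-based motif plant positions
    motif_plants: dict[str, list[int]] = field(default_factory=dict)

    def positive_genomes(self) -> set[str]:
        return set(self.clusters)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"clusters": self.clusters, "decoys": self.decoys,
                 "motif_plants": self.motif_plants},
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(clusters=data["clusters"], decoys=data["decoys"],
                   motif_plants=data["motif_plants"])


def mutate_protein(seed_sequence: str, target_identity: float,
                   rng_seed: int | np.random.Generator) -> str:
    """Substitute exactly round((1-identity)*L) positions of the seed.

    Positions are chosen without replacement; each is replaced by a uniformly
    drawn *different* residue, so realized ungapped identity equals the target
    to within 1/L.  Deterministic for a fixed seed.
    """
    if target_identity <= 0:
        raise ValueError("target_identity must be > 0")
    if target_identity > 1:
        raise ValueError("target_identity must be <= 1")
    if len(seed_sequence) < 20:
        raise ValueError("seed sequence must be at least 20 residues")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n_sub = round((1.0 - target_identity) * len(seed_sequence))
    if n_sub == 0:
        return seed_sequence
    positions = rng.choice(len(seed_sequence), size=n_sub, replace=False)
    out = list(seed_sequence)
    for pos in sorted(positions):
        alternatives = [c for c in AMINO_ACIDS if c != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def pairwise_identity_to_mutation_rate(pairwise: float) -> float:
    """Per-copy retention rate m so two independent mutants of one ancestor
    have expected pairwise identity ``pairwise``: m^2 + (1-m)^2/19."""
    # solve m^2 + (1-m)^2/19 = p  (take the root in (0,1])
    a = 1.0 + 1.0 / 19.0
    b = -2.0 / 19.0
    c = 1.0 / 19.0 - pairwise
    m = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(np.clip(m, 0.0, 1.0))


def _random_orf(rng: np.random.Generator, length: int = 300) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _decoy_family(rng: np.random.Generator) -> str:
    # dummy accession space disjoint from any schema family
    return f"PF9{rng.integers(0, 10000):04d}"


def _pick(rng: np.random.Generator, options) -> str:
    return options[rng.integers(len(options))]


class _GenomeBuilder:
    """Lay proteins onto a contig left to right with random gaps/strands."""

    def __init__(self, genome_id: str, organism: str, rng: np.random.Generator,
                 circular: bool):
        self.genome_id = genome_id
        self.organism = organism
        self.rng = rng
        self.circular = circular
        self.features: list[GeneFeature] = []
        self.proteins: list[ProteinRecord] = []
        self.cursor = int(rng.integers(50, 500))
        self.n = 0

    def add_gene(self, protein_seq: str, families: frozenset[str],
                 product: str = "hypothetical protein") -> GeneFeature:
        self.n += 1
        fid = f"{self.genome_id}_f{self.n:03d}"
        pid = f"{self.genome_id}_p{self.n:03d}"
        gene_len = 3 * len(protein_seq) + 3
        start = self.cursor
        end = start + gene_len - 1
        strand = "+" if self.rng.random() < 0.5 else "-"
        self.cursor = end + 1 + int(self.rng.integers(50, 451))
        feat = GeneFeature(
            feature_id=fid, contig_id=f"{self.genome_id}_c1", start=start,
            end=end, strand=strand, protein_id=pid, product=product,
            families=families,
        )
        self.features.append(feat)
        self.proteins.append(
            ProteinRecord(protein_id=pid, sequence=protein_seq,
                          organism=self.organism, source_gene=fid,
                          families=families)
        )
        return feat

    def finish(self) -> GenomeRecord:
        length = self.cursor + int(self.rng.integers(50, 500))
        contig = Contig(
            contig_id=f"{self.genome_id}_c1", length=length,
            circular=self.circular, features=self.features,
        )
        return GenomeRecord(genome_id=self.genome_id, organism=self.organism,
                            contigs=[contig])


def generate_dataset(config: SyntheticConfig):
    """Emit annotated genomes, their pooled proteome, and the ground truth.

    Positive genomes carry exactly one three-gene cluster: mutated copies of
    the seed enzymes placed in the configured order with at most
    ``window_spacing`` ORFs between the first and last member, padded by
    decoy ORFs on both sides.  Decoy genomes carry an incomplete (two-gene),
    scattered (> window apart in both circular directions), or empty signature.

    Returns ``(genomes, proteome, truth)`` where proteome is a flat list of
    :class:`ProteinRecord` across all genomes.
    """
    if config.n_planted_3gc > 0 and config.window_spacing < 2:
        raise ValueError(
            "window_spacing < 2 cannot fit three ordered cluster members"
        )
    rng = np.random.default_rng(config.rng_seed)
    truth = GroundTruth()
    genomes: list[GenomeRecord] = []
    proteome: list[ProteinRecord] = []

    kinds = (["positive"] * config.n_planted_3gc
             + ["two_gene"] * config.decoy_spec.get("two_gene", 0)
             + ["scattered"] * config.decoy_spec.get("scattered", 0)
             + ["none"] * config.decoy_spec.get("none", 0))
    kinds += ["none"] * (config.n_genomes - len(kinds))

    combos = []
    for i in range(config.n_planted_3gc):
        if config.order_signature == "mixed":
            order = "A-P-D" if i % 2 == 0 else "A-D-P"
        else:
            order = config.order_signature
        if config.phosphatase_class == "mixed":
            # the two observed combinations travel together
            ph_class = ("inositol_phosphatase" if order == "A-P-D"
                        else "HAD_hydrolase")
        else:
            ph_class = config.phosphatase_class
        combos.append((order, ph_class))

    n_positive_seen = 0
    for g_index, kind in enumerate(kinds):
        genome_id = f"g{g_index:03d}"
        if kind == "positive":
            genus = _POSITIVE_GENERA[n_positive_seen % len(_POSITIVE_GENERA)]
        else:
            genus = _DECOY_GENERA[g_index % len(_DECOY_GENERA)]
        organism = f"{genus} synthetica s{g_index:03d}"
        builder = _GenomeBuilder(genome_id, organism, rng,
                                 circular=bool(rng.random() < 0.5))

        if kind == "positive":
            order, ph_class = combos[n_positive_seen]
            plant_motif = n_positive_seen < config.motif_plants
            n_positive_seen += 1
            members = _make_members(config, rng, ph_class, plant_motif)
            _plant_cluster(builder, rng, order, members, config.window_spacing)
            member_map = {
                letter: feat.feature_id
                for letter, feat in builder.planted.items()  # type: ignore[attr-defined]
            }
            truth.clusters[genome_id] = {
                "members": member_map,
                "order": _realized_order(builder),
                "phosphatase_class": ph_class,
            }
            if plant_motif:
                at_feat = builder.planted["A"]  # type: ignore[attr-defined]
                truth.motif_plants.setdefault(
                    at_feat.protein_id, []
                ).append(MOTIF_PLANT_POSITION)
        elif kind == "two_gene":
            _plant_two_gene(builder, rng, config)
            truth.decoys[genome_id] = "two_gene"
        elif kind == "scattered":
            _plant_scattered(builder, rng, config)
            truth.decoys[genome_id] = "scattered"
        else:
            for _ in range(int(rng.integers(8, 14))):
                builder.add_gene(_random_orf(rng),
                                 frozenset({_decoy_family(rng)}))
            truth.decoys[genome_id] = "none"

        genome = builder.finish()
        genomes.append(genome)
        proteome.extend(builder.proteins)

    _plant_decoy_motifs(config, rng, genomes, proteome, truth)
    return genomes, proteome, truth


def _make_members(config: SyntheticConfig, rng: np.random.Generator,
                  ph_class: str, plant_motif: bool) -> dict[str, tuple[str, frozenset]]:
    ident = config.target_identity_to_seed
    at_seq = mutate_protein(SEED_AMINOTRANSFERASE, ident, rng)
    if plant_motif:
        at_seq = plant_motif_instance(at_seq, rng)
    dh_seq = mutate_protein(SEED_DEHYDROGENASE, ident, rng)
    if ph_class == "inositol_phosphatase":
        ph_seq = mutate_protein(SEED_PHOSPHATASE_INOSITOL, ident, rng)
        ph_fams = frozenset({FAMILY_PH_INOSITOL})
    else:
        ph_seq = mutate_protein(SEED_PHOSPHATASE_HAD, ident, rng)
        ph_fams = frozenset({_pick(rng, FAMILY_PH_HAD)})
    return {
        "A": (at_seq, frozenset({FAMILY_AT})),
        "D": (dh_seq, frozenset({_pick(rng, FAMILY_DH)})),
        "P": (ph_seq, ph_fams),
    }


_PRODUCTS = {
    "A": "aminotransferase class-III",
    "D": "aminopolyol dehydrogenase",
    "P": "phosphatase",
}


def _plant_cluster(builder: _GenomeBuilder, rng: np.random.Generator,
                   order: str, members: dict, window_spacing: int) -> None:
    letters = order.split("-")
    n_lead = int(rng.integers(3, 6))
    for _ in range(n_lead):
        builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))
    # optionally one spacer ORF inside the cluster when the window allows it
    spacer_after = (int(rng.integers(2)) if window_spacing >= 3 else -1)
    planted: dict[str, GeneFeature] = {}
    for pos, letter in enumerate(letters):
        seq, fams = members[letter]
        planted[letter] = builder.add_gene(seq, fams, _PRODUCTS[letter])
        if pos == spacer_after:
            builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))
    for _ in range(int(rng.integers(3, 6))):
        builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))
    builder.planted = planted  # type: ignore[attr-defined]


def _realized_order(builder: _GenomeBuilder) -> str:
    planted = builder.planted  # type: ignore[attr-defined]
    return "".join(sorted(planted, key=lambda L: (planted[L].start, planted[L].end)))


def _plant_two_gene(builder, rng, config) -> None:
    members = _make_members(config, rng, _pick(rng, ("inositol_phosphatase",
                                                     "HAD_hydrolase")), False)
    keep = {0: ("A", "D"), 1: ("A", "P"), 2: ("D", "P")}[int(rng.integers(3))]
    for _ in range(int(rng.integers(3, 6))):
        builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))
    for letter in keep:
        seq, fams = members[letter]
        builder.add_gene(seq, fams, _PRODUCTS[letter])
    for _ in range(int(rng.integers(3, 6))):
        builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))


def _plant_scattered(builder, rng, config) -> None:
    # members separated by > window decoy ORFs in both circular directions
    members = _make_members(config, rng, _pick(rng, ("inositol_phosphatase",
                                                     "HAD_hydrolase")), False)
    gap = config.window_spacing + 2
    for letter in ("A", "D", "P"):
        seq, fams = members[letter]
        builder.add_gene(seq, fams, _PRODUCTS[letter])
        for _ in range(gap):
            builder.add_gene(_random_orf(rng), frozenset({_decoy_family(rng)}))


def plant_motif_instance(sequence: str, rng: np.random.Generator,
                         position: int = MOTIF_PLANT_POSITION) -> str:
    """Overwrite ``sequence`` at 1-based ``position`` with an exact
    instantiation of the packaged 30-mer (X positions drawn at random)."""
    inst = instantiate_motif(AZA_AMINOTRANSFERASE_MOTIF, rng)
    i = position - 1
    if i + len(inst) > len(sequence):
        raise ValueError("sequence too short to plant the motif")
    return sequence[:i] + inst + sequence[i + len(inst):]


def _plant_decoy_motifs(config, rng, genomes, proteome, truth) -> None:
    if config.decoy_motif_plants == 0:
        return
    positive = truth.positive_genomes()
    eligible = [i for i, p in enumerate(proteome)
                if p.protein_id.split("_")[0] not in positive
                and len(p.sequence) >= MOTIF_PLANT_POSITION + 29]
    if len(eligible) < config.decoy_motif_plants:
        raise ValueError("not enough decoy proteins to plant motifs into")
    chosen = rng.choice(len(eligible), size=config.decoy_motif_plants,
                        replace=False)
    for k in sorted(chosen):
        idx = eligible[int(k)]
        rec = proteome[idx]
        new_seq = plant_motif_instance(rec.sequence, rng)
        new_rec = ProteinRecord(
            protein_id=rec.protein_id, sequence=new_seq,
            organism=rec.organism, source_gene=rec.source_gene,
            families=rec.families,
        )
        proteome[idx] = new_rec
        truth.motif_plants.setdefault(rec.protein_id, []).append(
            MOTIF_PLANT_POSITION
        )
        # keep the genome's stored protein list consistent is not needed:
        # genomes carry features only; proteins live in the proteome list.


def make_subfamily_proteins(
    n_families: int = 3,
    members_per_family: int = 8,
    within_identity: float = 0.8,
    cross_identity: float = 0.55,
    seed_length: int = 400,
    rng_seed: int = 0,
    genera: tuple[str, ...] = ("Bacillus", "Paenibacillus", "Chitinophaga",
                               "Streptomyces", "Xenorhabdus"),
) -> list[ProteinRecord]:
    """Protein sets emulating genus-like subfamilies of one enzyme family.

    Family ancestors are star-mutated from a common base so that any two
    members of *different* families have expected pairwise identity
    ``cross_identity``, while two members of the *same* family have expected
    pairwise identity ``within_identity``.  This is the substrate for the
    threshold-sweep experiments: with the defaults, subfamilies form one
    connected network at a 40% identity cutoff and separate into one cluster
    per family by 70%, mirroring how real genus-level subfamilies behave.
    """
    if n_families > len(genera):
        raise ValueError("not enough genus labels for n_families")
    rng = np.random.default_rng(rng_seed)
    base = _random_orf(rng, seed_length)
    m_within = pairwise_identity_to_mutation_rate(within_identity)
    # cross pairs agree where both kept their ancestor's residue and the
    # ancestors agree: m^2 * a  (+ tiny chance agreements), so
    ancestor_pairwise = min(1.0, cross_identity / (m_within * m_within))
    s = pairwise_identity_to_mutation_rate(ancestor_pairwise)
    records = []
    for f in range(n_families):
        ancestor = mutate_protein(base, s, rng)
        for k in range(members_per_family):
            seq = mutate_protein(ancestor, m_within, rng)
            records.append(
                ProteinRecord(
                    protein_id=f"fam{f}_m{k:02d}",
                    sequence=seq,
                    organism=f"{genera[f]} synthetica f{f}m{k}",
                    families=frozenset({FAMILY_AT}),
                )
            )
    return records


def write_dataset(genomes, proteome, truth, out_dir: str | os.PathLike) -> None:
    """Write GFF3 per genome, one pooled proteome FASTA, and truth JSON."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for genome in genomes:
        write_annotations(genome, os.path.join(out_dir, f"{genome.genome_id}.gff3"))
    write_fasta(proteome, os.path.join(out_dir, "proteome.faa"))
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
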
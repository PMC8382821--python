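# Methods

This note records the models, conventions and numerical choices behind
`azamine`, and what the synthetic substrate does and does not establish
about real genomes.

## Alignment kernel and statistics

Pairwise similarity is optimal local alignment under affine gaps (Gotoh's
three-state recurrence), scored with BLOSUM62 and blastp's default
penalties: gap open 11, gap extend 1, with the BLAST convention that a gap
of length *k* costs 11 + *k* (the first gap residue pays open+extend).  The
DP is vectorized row-wise; the horizontal gap state is resolved exactly
with a prefix-maximum scan, which is algebraically equivalent to the
textbook recurrence because the open penalty is at least the extend
penalty.  Traceback is deterministic: the first maximal cell in row-major
order, ties resolved diagonal > up > left.  When several co-optimal local
alignments exist, different but equally optimal tracebacks may be reported
for (a,b) and (b,a); the raw score is always symmetric, and for homologous
pairs (the regime the pipeline works in) identity and alignment length are
symmetric too.

Percent identity is identical residue pairs divided by alignment length
*including* gap columns, and query/subject coverage is the aligned span
over the full sequence length — both the BLAST tabular conventions.
Raw scores map to bit scores and E-values through the Karlin–Altschul
formula with the published gapped BLOSUM62 11/1 constants λ = 0.267,
K = 0.041.  Composition-based statistics and low-complexity masking are
not implemented; E-values on biased-composition sequences will be
anticonservative relative to modern BLAST.  The "alignment score" used as
a network threshold is −log10 of the E-value, floored at zero, the
convention of the EFI enzyme-similarity tools.

## Networks

An SSN keeps one hit per unordered pair at E ≤ 1e−5 (configurable) and
draws an edge when the chosen metric (percent identity by default,
alignment score optionally) meets the threshold.  Clusters are connected
components — the semantics a thresholded similarity graph actually has;
no density-based method is layered on top.  Components of size ≥ 2 are
numbered from 1 by descending size with ties broken by the
lexicographically smallest member id; this numbering is a display
convention, and no meaning attaches to any particular ordinal.  Singletons
are flagged rather than numbered, and two counts are kept: nodes isolated
because they had no above-cutoff hit at all, and nodes isolated only after
thresholding.  A cluster is genus-labeled when one genus reaches 75% of
its nodes, otherwise the two most populous genera are listed (count ties
alphabetical).  Genus is defined as the first whitespace token of the
organism string throughout.

## Neighborhoods, coloring, co-occurrence

A neighborhood is the ±w ORFs (default w = 3) around a focal gene counted
in start-coordinate rank, not base pairs, so intergenic distances and
strand are irrelevant; overlapping genes rank by start then end.  Windows
truncate at linear contig ends and wrap on circular contigs without
double-counting (each distinct neighbor takes its smallest-|offset| slot,
ties to the downstream side).  Neighborhoods never cross contigs.

Activity coloring maps neighbor PFAM families through the schema
aminotransferase {PF00202}, dehydrogenase {PF00107, PF08240, PF16912},
phosphatase {PF13419, PF00459, PF12710, PF07081}; a feature annotated with
families of two activities counts toward both.  The phosphatase class is
`inositol_phosphatase` (PF00459) or `HAD_hydrolase` (PF13419/PF12710/
PF07081); a neighborhood containing both kinds is reported as `both` with
a warning, never silently resolved.  Family annotations are consumed from
the input GFF3 (`Dbxref=Pfam:` or `pfam=`); the package bundles no PFAM
models, and an external profile scanner can be plugged through the
`profile_search_command` hook contract.

Per-cluster co-occurrence is the fraction of a cluster's nodes whose
neighborhood contains at least one member of a family.  The 20% threshold
gates *reporting* only — the full fraction table is always produced —
which is our reading of the co-occurrence parameter in neighborhood-
network tools; the alternative (gating edge drawing) would not change any
number in the full table.

## 3GC detection

Detection runs on annotations directly: every gene carrying a focal-
activity family is a candidate, and it is reported when its window holds
at least one gene from *each* other activity's family set ("at least one
family from each set" — the phosphatase families are alternatives).  When
several neighbors could fill an activity the nearest by |offset| wins,
ties to the lower start coordinate, giving one deterministic record per
focal gene rather than a combinatorial list of triples.  The gene-order
signature sorts the three letters by start coordinate (ties by end);
reverse-strand blocks are deliberately not flipped, since the observed
orders are defined on genome coordinates.  Genus tallies count each genome
once regardless of how many clusters it carries, and genera below the
configurable minimum (default 5) are omitted from the main table but kept
in the full listing.  Multi-source hit sets merge by genome id with
per-source provenance flags; deduplication is at genome level, not strain
or genus.

Because detection is annotation-driven it is independent of sequence
divergence; the SSN-restricted variant of the analysis is reproduced by
intersecting detected genomes with network cluster membership.

## Progressive MSA and consensus

The guide tree is neighbor joining on distances 1 − identity/100 from the
pairwise kernel; subtrees merge by global profile–profile alignment where
the score of two columns is the mean pairwise BLOSUM62 score of their
residue frequency profiles.  Profile-stage gap penalties are the pairwise
values scaled by a fixed factor of 2: column scores are means over row
pairs and shrink with divergence, so unscaled penalties let spurious
compensating gap pairs outscore the gap-free alignment on substitution-only
data; the factor 2 keeps indel-free inputs gap-free across the 40–90%
identity range the pipeline operates in (checked empirically), while
remaining small enough to open genuine indel gaps.  Column-identical
output with Clustal is not promised and not needed downstream.

The consensus is per-column plurality over non-gap residues: uppercase at
≥ 0.9 of the column, lowercase at ≥ 0.5, X otherwise; plurality ties and
all-gap columns give X.  The case thresholds are display conventions only
— matching is case-insensitive.  The packaged screening pattern is the
degenerate 30-mer `SGNXFRXXXFPNXXXXXXXLXVPXPYCXRC` (16 constrained
positions, 14 wildcards).  The scanner reports every offset whose
constrained-position mismatches stay within a budget (default 0; 2 is a
reasonable screening leniency).  Under a uniform-residue null an exact
match occurs at 20⁻¹⁶ per offset, so any exact hit on random sequence is
effectively diagnostic.  Screen validation flags each hit as inside or
outside a detected 3GC via the protein→gene mapping; precision is
in-3GC/mapped hits, undefined (never zero) when there are no mapped hits,
and hits without a gene mapping are counted separately with a warning.
Both protein-level and organism-level hit counts are reported, since
either could be the unit of interest.

## Trees

p-distance is mismatches over columns where neither row has a gap; a pair
with no comparable column is an error naming the pair.  No multiple-hit
correction is applied anywhere ("uncorrected" is the point: the gene-tree
comparison asks about relationships, not time).  Neighbor joining is the
Saitou–Nei algorithm; among minimal-Q pairs the lexicographically lowest
label pair joins first, so output is order-independent; additive matrices
are recovered exactly.  Negative branch lengths are clamped to zero and
counted on the tree object.  Robinson–Foulds counts bipartitions present
in exactly one tree, normalized by 2(n−3); taxonomy references are
consumed as user-supplied Newick.  On the synthetic substrate the gene
tree/taxonomy discordance is built in (all planted aminotransferases
descend from a single seed, while genus labels cycle independently), so a
high normalized RF demonstrates the machinery, not a biological inference.

## Synthetic substrate: what it does and does not show

The generator plants one 3GC per positive genome using four fixed
synthetic length-400 seed enzymes committed in the source (they are
random-sequence stand-ins, deliberately not real enzyme sequences).
Members are seed copies with exactly round((1−identity)·L) substituted
positions (default identity to seed 0.7, giving within-set pairwise
identities near 50%, inside the 40–50% working range of the network
thresholds); gene orders and phosphatase classes follow the two observed
combinations (A-P-D with inositol phosphatase; A-D-P with HAD hydrolase),
cycled in "mixed" mode.  Intergenic gaps are uniform 50–500 bp, strands
random, contigs circular with probability 0.5, decoy ORFs carry dummy
PF9xxxx accessions disjoint from the schema.  Decoy genomes carry a
two-gene (incomplete), scattered (> window in both circular directions) or
empty signature.  Motif instantiations overwrite the planted
aminotransferase at position 146, mirroring the diagnostic span's location.

Genus-like subfamily sets for the threshold-sweep experiments are built
star-wise: family ancestors are mutated from a common base so that
realized *pairwise* identities hit the targets — within-family 0.8 and
cross-family 0.55 by default.  The cross-family default follows the
observed network behavior of real producer subfamilies, which share one
cluster at a 40% identity cutoff and separate only between 60 and 70%:
that requires cross-family identity between 40 and 70, and 0.55 sits in
the middle.  (A cross-family identity of 0.35, which the generator also
supports, produces families that are already separate at 40% — BLAST-style
percent identity of a 35%-identical pair cannot clear a 40% threshold.)

Limitations of the substrate: substitution-only evolution (no indels, so
MSA gap handling is only lightly exercised), uniform residue composition
(no low-complexity regions, so E-values are cleaner than on real
proteomes), annotation-perfect families (detection sensitivity on real
genomes is bounded by annotation quality, which the pipeline treats as
input), and no genuine taxonomic signal in the gene sequences.  Passing
tests therefore establish algorithmic correctness and pipeline wiring, not
recall on real databases.

## Problem sizes and determinism

The shipped analyses use 60 genomes (~730 proteins, ~48 per enzyme
family), 24-sequence subfamily sets, ≥10⁶ scanned motif offsets and 100 NJ
recovery trials — sizes chosen so the full study reruns in a few minutes
on a laptop core while every claimed property is still measured directly.
All randomness flows from a single integer seed per run (numpy
`default_rng`); reruns with the same configuration are byte-identical in
every non-log output, and the pipeline manifest (seed, parameters, input
checksums, package version) suffices to reproduce a run.
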
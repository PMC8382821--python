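# azamine

Comparative-genomics mining of bacterial genomes for the azasugar
biosynthetic signature: a three-gene cluster (**3GC**) of an
**aminotransferase** (PF00202), a **phosphatase** (PF00459 inositol-type, or
PF13419/PF12710/PF07081 HAD-hydrolase-type) and an **aminopolyol
dehydrogenase** (PF00107/PF08240/PF16912) sitting within a few ORFs of each
other.  Azasugars (1-deoxynojirimycin and relatives) are ring-nitrogen
monosaccharide analogs and potent glycosidase inhibitors; in bacteria these
three clustered activities convert a phospho-ketose into the cyclizing
oxo-aminopolyol, so the cluster itself is a usable search signature for new
producer strains.

The package is aimed at people doing enzyme-family and biosynthetic-gene-
cluster bioinformatics.  It implements, as an importable library plus an
analysis pipeline:

- **Pairwise kernel** — Smith–Waterman local alignment under affine gaps
  (Gotoh; BLOSUM62, gap open 11 / extend 1, a length-*k* gap costs 11+*k*),
  with Karlin–Altschul statistics: bit score `(λS − ln K)/ln 2`, E-value
  `mn·2^(−bit)`, and the EFI-style *alignment score* `−log10 E`
  (λ = 0.267, K = 0.041, the gapped BLOSUM62 constants).
- **Sequence similarity networks (SSN)** — all-vs-all hits at E ≤ 1e−5,
  thresholded by percent identity or alignment score; clusters are connected
  components, numbered by descending size; threshold sweeps show subfamily
  separation; clusters are genus-labeled by a 75% majority rule.
- **Genome neighborhoods / colored SSN** — ±3-ORF windows in gene-rank
  order (strand-agnostic, wrapping on circular contigs), activity coloring
  from PFAM annotations, and per-cluster family co-occurrence with a 20%
  reporting threshold.
- **3GC detection** — one record per focal gene whose window holds at least
  one family from each other activity; gene-order signature (`APD` vs `ADP`
  by start coordinate) and phosphatase-class typing; genus tallies and
  multi-source hit merging.
- **Consensus motif screening** — progressive MSA (NJ guide tree,
  profile–profile merges), case-encoded plurality consensus, and a
  degenerate-pattern scanner for the packaged 30-mer
  `SGNXFRXXXFPNXXXXXXXLXVPXPYCXRC` (16 constrained positions, X matches
  anything), validated against detected 3GC membership.
- **Phylogenetic discordance** — p-distance (no multiple-hit correction),
  Saitou–Nei neighbor joining with deterministic ties and clamped negative
  branches, and Robinson–Foulds comparison to a reference taxonomy tree.
- **Synthetic genomes** — a ground-truthed generator planting 3GCs in both
  observed gene orders (`A-P-D` with inositol phosphatase, `A-D-P` with HAD
  hydrolase), decoy genomes with incomplete or scattered signatures, and
  exact motif instantiations, so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic dataset (60 genomes: 30 with a planted 3GC, 30 decoys):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_align_and_network.py
python analysis/03_neighborhoods_and_detect.py
python analysis/04_consensus_screen.py
python analysis/05_phylogeny.py
```

which prints, among other things:

```
wrote 60 genomes (30 positive, 30 decoy) and 730 proteins to .../results/data
planted gene orders: APD x15, ADP x15; motif plants: 10
aminotransferase: 48 proteins, 1128 hits, 1 clusters at 40% identity
subfamily sweep (clusters at 40/50/60/70%): [1, 1, 3, 3]
genus labels at 70%: {1: 'Bacillus', 2: 'Paenibacillus', 3: 'Chitinophaga'}
detected 3GCs in 30 genomes (ground truth: 30)
sensitivity 1.00, false positives 0
motif screen: 10 hits inside 3GCs, 0 outside, precision 1.0
gene tree on 12 aminotransferases; RF vs genus reference = 15 (normalized 0.83)
```

Read: the 48 aminotransferases (30 planted + 18 from incomplete-cluster
decoys) form one 40%-identity network cluster; the three genus-like
subfamilies merge at 40% and separate into three genus-pure clusters by
70%; annotation-driven detection recovers exactly the 30 planted clusters
with no false positives; all 10 planted motif instantiations are found and
every one sits in a detected 3GC (precision 1.0); and the aminotransferase
gene tree is strongly discordant with the genus reference tree (normalized
RF 0.83), the pattern a horizontal-transfer history produces.

The same stages are scriptable via the CLI (`azamine simulate|align|ssn|
color|detect|consensus|screen|tree|run`); `azamine run` executes everything
from a YAML config into a run directory with a reproducibility manifest.

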
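#!/usr/bin/env python
"""Stage 5: gene tree vs. taxonomy discordance.

Neighbor-joining tree from uncorrected p-distances over the detected
aminotransferases (one representative per positive genome), compared by
Robinson-Foulds distance to a genus-structured reference tree built from
the organism labels.  A high normalized RF says the aminotransferase's
sequence relationships do not follow the genus structure — on this
synthetic substrate that is by construction (all copies descend from one
seed regardless of assigned genus), the situation a horizontal-transfer
hypothesis would produce in real data.

Writes the gene tree, the reference tree and the RF summary under results/.
"""

import glob
import json
import os
import sys
from collections import defaultdict

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from azamine.detect import find_3gc
from azamine.io_formats import read_annotations, read_fasta
from azamine.motif import progressive_msa
from azamine.phylo import PhyloTree, neighbor_joining, p_distance, robinson_foulds

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def genus_reference_tree(records) -> PhyloTree:
    """A rake-of-genera reference: genera as sister clades, members inside."""
    by_genus = defaultdict(list)
    for rec in records:
        by_genus[rec.genus].append(rec.protein_id)

    def clade(members):
        if len(members) == 1:
            return f"{members[0]}:1"
        inner = f"({members[0]}:1,{members[1]}:1):1"
        for m in members[2:]:
            inner = f"({inner},{m}:1):1"
        return inner

    clades = [clade(sorted(ms)) for _, ms in sorted(by_genus.items())]
    newick = "(" + ",".join(clades) + ");"
    return PhyloTree.from_newick(newick)


def main() -> None:
    data = os.path.join(BASE, "data")
    genomes = [read_annotations(p) for p in sorted(glob.glob(
        os.path.join(data, "*.gff3")))]
    proteome = read_fasta(os.path.join(data, "proteome.faa"))
    clusters = find_3gc(genomes)
    at_ids = {c.at_feature.protein_id for c in clusters}
    # one aminotransferase per genome, capped for a readable tree
    records = sorted((p for p in proteome if p.protein_id in at_ids),
                     key=lambda p: p.protein_id)[:12]

    msa = progressive_msa(records)
    gene_tree = neighbor_joining(p_distance(msa))
    gene_tree.write_newick(os.path.join(BASE, "gene_tree.nwk"))
    ref = genus_reference_tree(records)
    ref.write_newick(os.path.join(BASE, "taxonomy_reference.nwk"))
    rf, norm = robinson_foulds(gene_tree, ref)
    with open(os.path.join(BASE, "tree_comparison.json"), "w") as fh:
        json.dump({"n_leaves": len(records), "rf": rf,
                   "rf_normalized": norm,
                   "clamped_branches": gene_tree.clamped_branches},
                  fh, indent=2)
    print(f"gene tree on {len(records)} aminotransferases; "
          f"RF vs genus reference = {rf} (normalized {norm:.2f})")
    if norm > 0.5:
        print("high discordance: aminotransferase relatedness does not "
              "follow the genus structure")


if __name__ == "__main__":
    main()
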
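#!/usr/bin/env python
"""Stage 4: aminotransferase consensus and proteome-wide motif screen.

Builds a progressive multiple alignment of the detected 3GC
aminotransferases, derives the case-encoded plurality consensus, then
screens the whole proteome with the packaged degenerate 30-mer
(SGNXFRXXXFPNXXXXXXXLXVPXPYCXRC) and validates every hit against 3GC
membership: the precision of the screen is the fraction of motif hits that
sit inside a detected cluster.

Writes the alignment, consensus and screen report under results/.
"""

import glob
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from azamine.detect import find_3gc
from azamine.io_formats import read_annotations, read_fasta
from azamine.motif import (
    AZA_AMINOTRANSFERASE_MOTIF,
    derive_consensus,
    progressive_msa,
    screen_and_validate,
)

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    data = os.path.join(BASE, "data")
    genomes = [read_annotations(p) for p in sorted(glob.glob(
        os.path.join(data, "*.gff3")))]
    proteome = read_fasta(os.path.join(data, "proteome.faa"))
    clusters = find_3gc(genomes)

    at_ids = {c.at_feature.protein_id for c in clusters}
    at_records = [p for p in proteome if p.protein_id in at_ids]
    msa = progressive_msa(at_records)
    msa.write_fasta(os.path.join(BASE, "aminotransferases.afa"))
    consensus = derive_consensus(msa)
    with open(os.path.join(BASE, "consensus.txt"), "w") as fh:
        fh.write(consensus.pattern + "\n")
    print(f"aligned {len(at_records)} detected aminotransferases "
          f"({msa.n_columns} columns); consensus has "
          f"{consensus.constrained_count} constrained positions")

    report = screen_and_validate(proteome, AZA_AMINOTRANSFERASE_MOTIF,
                                 clusters)
    with open(os.path.join(BASE, "screen_report.json"), "w") as fh:
        json.dump(
            {"n_in_3gc": report.n_in_3gc,
             "n_not_in_3gc": report.n_not_in_3gc,
             "n_unmapped": report.n_unmapped,
             "precision": report.precision,
             "n_proteins_hit": report.n_proteins_hit,
             "n_organisms_hit": report.n_organisms_hit,
             "hits": report.hits},
            fh, indent=2, sort_keys=True,
        )
    print(f"motif screen: {report.n_in_3gc} hits inside 3GCs, "
          f"{report.n_not_in_3gc} outside, precision {report.precision}")


if __name__ == "__main__":
    main()
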
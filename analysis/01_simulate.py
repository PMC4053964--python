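#!/usr/bin/env python
"""Generate the canonical synthetic gPAR-CLIP study and write it to disk.

Produces the reference FASTA, GFF3 annotation, per-library alignment tables
(duplicate gPAR-CLIP and mRNA-seq libraries for rich media and two
starvation conditions), and the planted-truth tables under
results/study_data/.
"""

import os
import sys

from xlinkscape.formats_io import write_alignments, write_annotation_gff3
from xlinkscape.studies import differential_config
from xlinkscape.synthetic_data import (
    simulate_study,
    write_fasta,
    write_truth_tables,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study_data")


def main(seed: int = 1):
    config = differential_config(seed)
    genome, transcripts, truth, libraries = simulate_study(config)
    os.makedirs(OUT, exist_ok=True)
    write_fasta(genome, os.path.join(OUT, "genome.fa"))
    write_annotation_gff3(transcripts, os.path.join(OUT, "annotation.gff3"))
    write_truth_tables(truth, os.path.join(OUT, "truth_sites.tsv"),
                       os.path.join(OUT, "truth_expression.tsv"))
    for (kind, cond, rep), reads in libraries.items():
        write_alignments(
            reads, os.path.join(OUT, f"{kind}_{cond}_rep{rep}.reads.tsv"))
    n_sites = len(truth.sites)
    n_changed = sum(any(f != 1.0 for f in s.fold.values())
                    for s in truth.sites)
    print(f"simulated {config.n_genes} genes, {n_sites} planted sites "
          f"({n_changed} with occupancy changes), "
          f"{len(libraries)} libraries -> {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
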
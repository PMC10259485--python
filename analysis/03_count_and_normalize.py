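#!/usr/bin/env python
"""Count bona fide reads per gene and normalize to reads per million.

Produces the (species, gene) x samples count matrix (all genes kept, zeros
included) and its RPM-normalized counterpart, dividing by each sample's
total library size so foreign-read levels are fractions of sequencing
output.
"""

from pathlib import Path

import pandas as pd

import transferome as tf
from transferome import io as tio

WORKDIR = Path("results/analysis/sim")


def main() -> None:
    design = tio.read_design(WORKDIR / "design.tsv")
    genes = [g for g, _ in tio.read_fasta(WORKDIR / "transcriptome_human.fasta")]
    assignments = {
        s: pd.read_csv(WORKDIR / "assignments" / f"{s}.tsv", sep="\t",
                       dtype={"read_id": str, "gene": str})
        for s in design["sample"]
    }
    counts = tf.count_by_gene(assignments, design, genes, "human", "mouse")
    rpm = tf.rpm_normalize(counts, design.set_index("sample")["library_size"])
    tio.write_counts(counts, WORKDIR / "counts.tsv")
    tio.write_counts(rpm, WORKDIR / "rpm.tsv")

    foreign = tf.foreign_rpm(rpm, design, "human")
    print(f"count matrix: {counts.shape[0]} (species, gene) rows x "
          f"{counts.shape[1]} samples")
    print("total human RPM in acceptor-enriched samples:")
    print(foreign.sum().round(1).to_string())


if __name__ == "__main__":
    main()
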
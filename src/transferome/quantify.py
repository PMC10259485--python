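"""Per-gene counting of species-assigned reads and RPM normalization.

Counting is transcript-level: each bona fide read pair contributes one
count to its best-hit gene on its assigned genome; unassigned reads
contribute nowhere. All genes are always present as rows (zeros kept) so
downstream joins never drop genes. RPM divides by the *total* library size
of the sample - not only assigned reads - so foreign-read proportions are
fractions of total sequencing output and Mix/Co-culture columns stay
comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import TransferomeError


def count_by_gene(
    assignments: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    genes: list[str],
    genome_a: str,
    genome_b: str,
) -> pd.DataFrame:
    """Count bona fide reads per (species, gene) per sample.

    ``assignments`` maps sample name to a classify_sample output table.
    Rows are the full (species, gene) index for both species; an assignment
    referencing an unknown gene is an error.
    """
    full_index = pd.MultiIndex.from_product(
        [[genome_a, genome_b], genes], names=["species", "gene"]
    )
    known = set(genes)
    cols = {}
    for _, row in design.iterrows():
        sample = row["sample"]
        if sample not in assignments:
            raise TransferomeError(f"no assignments for sample '{sample}'")
        table = assignments[sample]
        assigned = table[table["label"] != "unassigned"]
        bad = set(assigned["gene"]) - known
        if bad:
            raise TransferomeError(
                f"sample '{sample}': assignment references unknown gene(s) "
                f"{sorted(bad)[:5]}"
            )
        species = assigned["label"].str.removeprefix("bonafide_")
        grouped = (
            pd.DataFrame({"species": species, "gene": assigned["gene"]})
            .groupby(["species", "gene"])
            .size()
        )
        cols[sample] = grouped.reindex(full_index, fill_value=0)
    counts = pd.DataFrame(cols, index=full_index).astype(int)
    return counts


def rpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per million: ``1e6 * count / library_size`` per sample column."""
    missing = set(counts.columns) - set(library_sizes.index)
    if missing:
        raise TransferomeError(f"no library size for sample(s) {sorted(missing)}")
    libs = library_sizes.reindex(counts.columns).astype(float)
    if (libs <= 0).any():
        raise TransferomeError("library sizes must be > 0")
    return 1e6 * counts / libs


def foreign_rpm(
    rpm: pd.DataFrame, design: pd.DataFrame, donor_species: str
) -> pd.DataFrame:
    """Donor-species genes in acceptor-enriched samples (the transfer signal)."""
    acceptor_samples = design.loc[
        design["enriched_species"] != donor_species, "sample"
    ]
    return rpm.loc[donor_species].loc[:, list(acceptor_samples)]


def donor_single_rpm(
    rpm: pd.DataFrame, design: pd.DataFrame, donor_species: str
) -> pd.Series:
    """Mean donor-gene RPM across donor single-culture replicates."""
    singles = design.loc[
        (design["condition"] == "single_donor")
        & (design["enriched_species"] == donor_species),
        "sample",
    ]
    if singles.empty:
        raise TransferomeError("design has no donor single-culture sample")
    return rpm.loc[donor_species].loc[:, list(singles)].mean(axis=1)
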
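"""Species-of-origin assignment of read pairs from dual-genome alignments.

A read pair is a *bona fide* read of the primary species iff it aligned
uniquely to the primary transcriptome with at most ``max_mismatch_primary``
mismatches (default 0) and its distance to the other transcriptome is at
least ``min_diff_other`` (default 3, i.e. ">2 differences"); a pair that
did not align to the other genome at all satisfies the distance clause (no
alignment is the extreme of divergence). With ``min_diff_other >
max_mismatch_primary`` no read can be bona fide for both species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentSummary
from .errors import TransferomeError

LABELS = ("bonafide_A", "bonafide_B", "unassigned")
REASONS = (
    "unaligned_primary",
    "not_unique",
    "too_many_mm_primary",
    "too_close_to_other",
)


@dataclass(frozen=True)
class SpeciesAssignment:
    read_id: str
    label: str
    reason: str | None
    gene: str | None


def _failure_reason(
    primary: AlignmentSummary, other: AlignmentSummary, max_mm: int, min_diff: int
) -> str | None:
    """First failing condition of the bona fide rule, or None if it passes."""
    if not primary.aligned:
        return "unaligned_primary"
    if not primary.unique:
        return "not_unique"
    if primary.mismatches > max_mm:
        return "too_many_mm_primary"
    if other.aligned and other.mismatches < min_diff:
        return "too_close_to_other"
    return None


def classify_read(
    summary_primary: AlignmentSummary,
    summary_other: AlignmentSummary,
    max_mm_primary: int = 0,
    min_diff_other: int = 3,
) -> SpeciesAssignment:
    """Apply the bona fide rule with ``summary_primary``'s genome as primary.

    Returns ``bonafide_<genome>`` on success, else ``unassigned`` with the
    first failing reason. The mirrored call (genomes swapped) yields the
    mirrored label under the mirrored conditions.
    """
    if summary_primary.read_id != summary_other.read_id:
        raise TransferomeError(
            f"read_id mismatch: {summary_primary.read_id!r} vs "
            f"{summary_other.read_id!r}"
        )
    reason = _failure_reason(summary_primary, summary_other, max_mm_primary, min_diff_other)
    if reason is None:
        return SpeciesAssignment(
            summary_primary.read_id,
            f"bonafide_{summary_primary.genome}",
            None,
            summary_primary.gene,
        )
    return SpeciesAssignment(summary_primary.read_id, "unassigned", reason, None)


def _unaligned_frame(read_ids: pd.Index, genome: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": read_ids,
            "genome": genome,
            "aligned": False,
            "unique": False,
            "mismatches": pd.array([None] * len(read_ids), dtype="Int64"),
            "gene": None,
        }
    )


def classify_sample(
    summaries: pd.DataFrame,
    genome_a: str,
    genome_b: str,
    max_mm_primary: int = 0,
    min_diff_other: int = 3,
    total_reads: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every read of a sample and tally per-sample proportions.

    ``summaries`` holds one row per (read, genome); reads missing a genome
    row are treated as unaligned there. Returns the per-read assignment
    table (read_id, label, reason, gene) and the proportions of
    ``bonafide_<A>``, ``bonafide_<B>`` and ``unassigned`` over
    ``total_reads`` (default: number of distinct reads seen).
    """
    genomes = set(summaries["genome"].unique())
    extra = genomes - {genome_a, genome_b}
    if extra:
        raise TransferomeError(f"unexpected genome label(s) {sorted(extra)}")
    all_reads = pd.Index(summaries["read_id"].unique(), name="read_id")

    per_genome = {}
    for genome in (genome_a, genome_b):
        sub = summaries[summaries["genome"] == genome].set_index("read_id")
        missing = all_reads.difference(sub.index)
        if len(missing):
            sub = pd.concat(
                [sub, _unaligned_frame(missing, genome).set_index("read_id")]
            )
        per_genome[genome] = sub.reindex(all_reads)

    a, b = per_genome[genome_a], per_genome[genome_b]

    def _passes(primary: pd.DataFrame, other: pd.DataFrame) -> pd.Series:
        mm_p = primary["mismatches"].to_numpy(dtype=float, na_value=np.inf)
        mm_o = other["mismatches"].to_numpy(dtype=float, na_value=np.inf)
        ok = (
            primary["aligned"].to_numpy()
            & primary["unique"].to_numpy()
            & (mm_p <= max_mm_primary)
            & (~other["aligned"].to_numpy() | (mm_o >= min_diff_other))
        )
        return pd.Series(ok, index=primary.index)

    is_a = _passes(a, b)
    is_b = _passes(b, a)
    both = is_a & is_b
    if both.any() and min_diff_other > max_mm_primary:
        raise TransferomeError("rule violation: read bona fide for both genomes")
    # with min_diff_other <= max_mm_primary double assignment is possible;
    # such reads are left unassigned rather than arbitrarily attributed
    is_a_only = is_a & ~both
    is_b_only = is_b & ~both

    label = np.where(
        is_a_only, f"bonafide_{genome_a}",
        np.where(is_b_only, f"bonafide_{genome_b}", "unassigned"),
    )
    gene = np.where(
        is_a_only, a["gene"].to_numpy(dtype=object),
        np.where(is_b_only, b["gene"].to_numpy(dtype=object), None),
    )

    reasons = []
    for rid, la in zip(all_reads, label):
        if la != "unassigned":
            reasons.append(None)
            continue
        ra = _failure_reason(_row_summary(a, rid, genome_a),
                             _row_summary(b, rid, genome_b),
                             max_mm_primary, min_diff_other)
        rb = _failure_reason(_row_summary(b, rid, genome_b),
                             _row_summary(a, rid, genome_a),
                             max_mm_primary, min_diff_other)
        ra = ra or "bonafide_both"
        rb = rb or "bonafide_both"
        reasons.append(f"{genome_a}:{ra};{genome_b}:{rb}")

    assignments = pd.DataFrame(
        {"read_id": all_reads, "label": label, "reason": reasons, "gene": gene}
    )
    n_total = total_reads if total_reads is not None else len(all_reads)
    if n_total < len(all_reads):
        raise TransferomeError("total_reads smaller than number of reads seen")
    counts = assignments["label"].value_counts()
    tally = pd.Series(
        {
            f"bonafide_{genome_a}": counts.get(f"bonafide_{genome_a}", 0) / n_total,
            f"bonafide_{genome_b}": counts.get(f"bonafide_{genome_b}", 0) / n_total,
            "unassigned": (
                counts.get("unassigned", 0) + (n_total - len(all_reads))
            ) / n_total,
        },
        name="fraction",
    )
    return assignments, tally


def _row_summary(frame: pd.DataFrame, read_id: str, genome: str) -> AlignmentSummary:
    row = frame.loc[read_id]
    mm = row["mismatches"]
    return AlignmentSummary(
        read_id=read_id,
        genome=genome,
        aligned=bool(row["aligned"]),
        unique=bool(row["unique"]),
        mismatches=None if pd.isna(mm) else int(mm),
        gene=None if pd.isna(row["gene"]) else row["gene"],
    )
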
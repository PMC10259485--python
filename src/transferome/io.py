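"""File formats: FASTA/FASTQ, alignment-summary / counts / design TSVs, logs.

All tables are plain TSV with a mandatory header so every stage output is
diff-able and readable by the next stage without manual edits. Sequence I/O
goes through Biopython, wrapped with validation that reports the offending
line number on malformed input.
"""

from __future__ import annotations

import io as _io
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

VALID_BASES = frozenset("ACGTN")
FASTA_WRAP = 60

ALIGNMENT_COLUMNS = ["read_id", "genome", "aligned", "unique", "mismatches", "gene"]
DESIGN_COLUMNS = ["sample", "condition", "replicate", "enriched_species", "library_size"]
CONDITIONS = ("single_donor", "single_acceptor", "mix", "coculture")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences must be over {A,C,G,T,N} (case-insensitive; returned upper).
    Malformed headers or illegal characters raise :class:`FormatError`
    naming the line number.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                seq = line.strip().upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal character(s) "
                        f"{sorted(bad)} in sequence"
                    )
                chunks.append(seq)
        if header is not None:
            if not chunks:
                raise FormatError(
                    f"{path}:{header_line}: record '{header}' has no sequence"
                )
            records.append((header, "".join(chunks)))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``[(id, sequence), ...]`` as FASTA wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seq_records)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into ``[(id, sequence), ...]`` (qualities dropped)."""
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTQ ({exc})") from exc


def write_fastq(records: list[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    """Write ``[(id, sequence), ...]`` as Phred+33 FASTQ with flat quality."""
    seq_records = []
    for name, seq in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Alignment summaries

def write_alignment_summaries(table: pd.DataFrame, path: str | Path) -> None:
    out = table.loc[:, ALIGNMENT_COLUMNS].copy()
    # censored distances (unaligned) serialize as empty fields, never a number
    out["mismatches"] = out["mismatches"].astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def read_alignment_summaries(path: str | Path) -> pd.DataFrame:
    """Read the per-read, per-genome alignment-summary TSV.

    One row per (read, genome); a read absent for a genome did not align
    there. Duplicate (read, genome) rows are an error listing the read ids.
    """
    table = pd.read_csv(path, sep="\t", dtype={"read_id": str, "genome": str, "gene": str})
    missing = set(ALIGNMENT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    dup = table.duplicated(subset=["read_id", "genome"], keep=False)
    if dup.any():
        offenders = sorted(table.loc[dup, "read_id"].unique())
        raise FormatError(
            f"{path}: duplicate (read, genome) rows for read_id(s) {offenders[:10]}"
        )
    table["aligned"] = table["aligned"].astype(bool)
    table["unique"] = table["unique"].astype(bool)
    table["mismatches"] = pd.to_numeric(table["mismatches"], errors="coerce").astype("Int64")
    if ((~table["aligned"]) & table["unique"]).any():
        raise FormatError(f"{path}: unique=True requires aligned=True")
    return table


# ---------------------------------------------------------------------------
# Design and count matrices

def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.loc[:, DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return validate_design(design, source=str(path))


def validate_design(design: pd.DataFrame, source: str = "design") -> pd.DataFrame:
    for _, row in design.iterrows():
        if row["condition"] not in CONDITIONS:
            raise FormatError(
                f"{source}: unknown condition '{row['condition']}' "
                f"(expected one of {CONDITIONS})"
            )
        expected = f"{row['condition']}_r{row['replicate']}"
        if row["sample"] != expected:
            raise FormatError(
                f"{source}: sample name '{row['sample']}' does not encode its "
                f"condition and replicate (expected '{expected}')"
            )
    if design["sample"].duplicated().any():
        raise FormatError(f"{source}: duplicate sample names")
    if (design["library_size"] <= 0).any():
        raise FormatError(f"{source}: library_size must be > 0")
    return design


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a (species, gene) x samples matrix as TSV.

    Rows are all genes (zeros kept) with leading ``species`` and ``gene``
    columns; remaining columns are sample names.
    """
    out = counts.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"species": str, "gene": str})
    for col in ("species", "gene"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    counts = table.set_index(["species", "gene"])
    sample_cols = list(counts.columns)
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return counts


# ---------------------------------------------------------------------------
# Logging

def log_kv(handle, **fields) -> str:
    """Append one line-oriented ``key=value`` log record; returns the line."""
    line = " ".join(f"{k}={v}" for k, v in fields.items())
    if handle is None:
        handle = sys.stderr
    if isinstance(handle, (str, Path)):
        with open(handle, "a") as fh:
            fh.write(line + "\n")
    else:
        handle.write(line + "\n")
    return line
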
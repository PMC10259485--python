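"""Synthetic two-species co-culture generator with known ground truth.

Emulates the study design: a donor ("human"-like) and an acceptor
("mouse"-like) transcriptome of orthologous genes with controlled per-gene
divergence; four sample conditions (donor single culture, acceptor single
culture, Mix control, Co-culture); and three sources of foreign reads in
acceptor-enriched samples:

* ``transfer``      - donor transcripts residing in acceptor cells, per-gene
                      fraction of the donor's expression (Co-culture only;
                      forced to zero in Mix, mirroring the control logic of
                      cells mixed only after harvest),
* ``contamination`` - residual donor cells that survive sorting (identical
                      in Mix and Co-culture),
* ``hop``           - a uniform index-hopping background: a fraction of each
                      sample's reads is drawn from the pool of all samples
                      in the run (the only foreign source in single
                      cultures).

Per-cell transcript totals of the two species are set equal, so RPM ratios
map directly onto per-cell fractions and the per-gene transfer fraction is
recoverable from the percentage-transfer statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationParams
from .errors import ConfigError
from . import io as tio

DONOR = "human"
ACCEPTOR = "mouse"
SOURCES = ("native", "transfer", "contamination", "hop")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode()


def revcomp(seq: str) -> str:
    return _decode(_COMPLEMENT[_encode(seq)][::-1])


# ---------------------------------------------------------------------------
# Transcriptomes

@dataclass
class TranscriptomePair:
    """Orthologous donor/acceptor transcripts with known divergence.

    ``seq_a`` (donor) and ``seq_b`` (acceptor) hold equal-length sequences
    per gene; ``divergence`` is the per-gene substitution rate used to
    derive the acceptor copy from the donor copy.
    """

    genes: list[str]
    seq_a: dict[str, str]
    seq_b: dict[str, str]
    divergence: pd.Series

    def records(self, species: str) -> list[tuple[str, str]]:
        seqs = self.seq_a if species == DONOR else self.seq_b
        return [(g, seqs[g]) for g in self.genes]

    def realized_divergence(self) -> pd.Series:
        """Observed per-gene Hamming fraction between the two copies."""
        frac = {
            g: np.mean(_encode(self.seq_a[g]) != _encode(self.seq_b[g]))
            for g in self.genes
        }
        return pd.Series(frac, name="hamming_fraction")


def generate_transcriptome_pair(
    n_genes: int,
    length: int,
    divergence: float | np.ndarray,
    seed: int,
) -> TranscriptomePair:
    """Draw a donor transcriptome and mutate it into the acceptor copy.

    The acceptor sequence of gene *g* differs from the donor sequence by
    i.i.d. substitutions at rate ``divergence[g]`` (a substituted site is
    always changed to a different base). Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    div = np.broadcast_to(np.asarray(divergence, dtype=float), (n_genes,)).copy()
    if ((div < 0) | (div > 1)).any():
        raise ConfigError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    seq_a: dict[str, str] = {}
    seq_b: dict[str, str] = {}
    for g, d in zip(genes, div):
        codes = rng.choice(_BASES, size=length)
        mutated = codes.copy()
        mask = rng.random(length) < d
        if mask.any():
            # shift by 1-3 within ACGT: always lands on a different base
            idx = np.searchsorted(_BASES, codes[mask])
            shift = rng.integers(1, 4, size=mask.sum())
            mutated[mask] = _BASES[(idx + shift) % 4]
        seq_a[g] = _decode(codes)
        seq_b[g] = _decode(mutated)
    return TranscriptomePair(
        genes=genes,
        seq_a=seq_a,
        seq_b=seq_b,
        divergence=pd.Series(div, index=genes, name="divergence"),
    )


# ---------------------------------------------------------------------------
# Design and expression

def make_design(n_replicates: int = 2, library_size: int = 20_000) -> pd.DataFrame:
    """Four-condition design: donor/acceptor single cultures, Mix, Co-culture.

    The donor single culture is donor-enriched; all other conditions are
    the acceptor-enriched fraction (the study's human-to-mouse direction).
    """
    rows = []
    for condition in tio.CONDITIONS:
        enriched = DONOR if condition == "single_donor" else ACCEPTOR
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": f"{condition}_r{rep}",
                    "condition": condition,
                    "replicate": rep,
                    "enriched_species": enriched,
                    "library_size": int(library_size),
                }
            )
    return pd.DataFrame(rows)


def draw_expression(
    n_genes: int, decades: float, total: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform per-gene expression spanning ``decades`` orders of
    magnitude, rescaled to a fixed per-cell transcript total."""
    expr = 10 ** rng.uniform(0.0, decades, size=n_genes)
    return expr * (total / expr.sum())


# ---------------------------------------------------------------------------
# Mixture weights (the closed-form ground truth)

@dataclass
class SimTruth:
    """Ground truth of a simulated run.

    ``weights[sample]`` is a table over (species, gene, source) whose
    ``weight`` column sums to 1: the probability that a read pair of that
    sample originates from that transcript via that source. Expected RPM of
    any (species, gene) in a sample is 1e6 times its summed weight.
    """

    design: pd.DataFrame
    expression_donor: pd.Series
    expression_acceptor: pd.Series
    transfer_fraction: pd.Series
    contamination_fraction: float
    hop_rate: float
    weights: dict[str, pd.DataFrame] = field(repr=False)

    def expected_rpm(self, sample: str) -> pd.Series:
        w = self.weights[sample].groupby(["species", "gene"])["weight"].sum()
        return 1e6 * w

    def expected_counts(self, sample: str) -> pd.Series:
        lib = int(
            self.design.set_index("sample").loc[sample, "library_size"]
        )
        return lib * self.weights[sample].groupby(["species", "gene"])["weight"].sum()


def _component(species: str, source: str, weights: pd.Series) -> pd.DataFrame:
    df = weights.rename("weight").rename_axis("gene").reset_index()
    df.insert(0, "species", species)
    df.insert(2, "source", source)
    return df


def mixture_weights(
    design: pd.DataFrame,
    expr_donor: pd.Series,
    expr_acceptor: pd.Series,
    transfer_fraction: pd.Series,
    contamination_fraction: float,
    hop_rate: float,
) -> dict[str, pd.DataFrame]:
    """Per-sample read-origin probabilities over (species, gene, source).

    Mix and Co-culture share every parameter except the transfer fraction,
    which is zero in Mix. Index hopping redistributes a ``hop_rate``
    fraction of each sample's reads across the library-size-weighted pool
    of all samples.
    """
    c = float(contamination_fraction)
    f = transfer_fraction.reindex(expr_donor.index)
    pre: dict[str, pd.DataFrame] = {}
    for _, row in design.iterrows():
        cond = row["condition"]
        if cond == "single_donor":
            parts = [_component(DONOR, "native", expr_donor / expr_donor.sum())]
        elif cond == "single_acceptor":
            parts = [_component(ACCEPTOR, "native", expr_acceptor / expr_acceptor.sum())]
        else:
            transfer = f * expr_donor if cond == "coculture" else 0.0 * expr_donor
            acceptor_cell = expr_acceptor + transfer
            total = (1 - c) * acceptor_cell.sum() + c * expr_donor.sum()
            parts = [
                _component(ACCEPTOR, "native", (1 - c) * expr_acceptor / total),
                _component(DONOR, "transfer", (1 - c) * transfer / total),
                _component(DONOR, "contamination", c * expr_donor / total),
            ]
        tab = pd.concat(parts, ignore_index=True)
        pre[row["sample"]] = tab[tab["weight"] > 0].reset_index(drop=True)

    if hop_rate > 0:
        libs = design.set_index("sample")["library_size"].astype(float)
        pool = (
            pd.concat(
                [pre[s].assign(weight=pre[s]["weight"] * libs[s]) for s in pre],
                ignore_index=True,
            )
            .groupby(["species", "gene"], as_index=False)["weight"]
            .sum()
        )
        pool["weight"] /= libs.sum()
        pool["source"] = "hop"
        final = {}
        for s, tab in pre.items():
            own = tab.assign(weight=tab["weight"] * (1 - hop_rate))
            hopped = pool.assign(weight=pool["weight"] * hop_rate)
            final[s] = pd.concat([own, hopped], ignore_index=True)
        return final
    return pre


def _per_gene_transfer(params: SimulationParams, genes: list[str]) -> pd.Series:
    f = params.transfer_fraction
    arr = np.broadcast_to(np.asarray(f, dtype=float), (len(genes),))
    return pd.Series(arr.copy(), index=genes, name="transfer_fraction")


def build_truth(
    params: SimulationParams,
    design: pd.DataFrame | None,
    seed: int,
    transfer_fraction: pd.Series | np.ndarray | float | None = None,
) -> SimTruth:
    """Draw expression vectors and assemble the mixture ground truth."""
    params.validate()
    if design is None:
        design = make_design(params.n_replicates, params.library_size)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    genes = [f"g{i + 1:04d}" for i in range(params.n_genes)]
    expr_donor = pd.Series(
        draw_expression(params.n_genes, params.expression_decades,
                        params.transcripts_per_cell, rng),
        index=genes, name="expression_donor",
    )
    expr_acceptor = pd.Series(
        draw_expression(params.n_genes, params.expression_decades,
                        params.transcripts_per_cell, rng),
        index=genes, name="expression_acceptor",
    )
    if transfer_fraction is None:
        f = _per_gene_transfer(params, genes)
    else:
        arr = np.broadcast_to(np.asarray(transfer_fraction, dtype=float),
                              (len(genes),)).copy()
        f = pd.Series(arr, index=genes, name="transfer_fraction")
    if ((f < 0) | (f > 0.1)).any():
        raise ConfigError("transfer_fraction must lie in [0, 0.1]")
    weights = mixture_weights(
        design, expr_donor, expr_acceptor, f,
        params.contamination_fraction, params.hop_rate,
    )
    return SimTruth(
        design=design,
        expression_donor=expr_donor,
        expression_acceptor=expr_acceptor,
        transfer_fraction=f,
        contamination_fraction=params.contamination_fraction,
        hop_rate=params.hop_rate,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# Count-matrix shortcut generator

def simulate_count_matrix(
    params: SimulationParams,
    seed: int,
    design: pd.DataFrame | None = None,
    transfer_fraction=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-gene counts directly from the expected mixture.

    Counts are negative binomial around mean = library_size x weight with
    configurable dispersion (Poisson at dispersion 0); no reads are
    generated. Returns the (species, gene) x samples matrix with all genes
    present (zeros kept) and the attached ground truth.
    """
    truth = build_truth(params, design, seed, transfer_fraction)
    design = truth.design
    genes = list(truth.expression_donor.index)
    full_index = pd.MultiIndex.from_product(
        [[DONOR, ACCEPTOR], genes], names=["species", "gene"]
    )
    ss = np.random.SeedSequence([int(seed), 37])
    children = ss.spawn(len(design))
    cols = {}
    for child, (_, row) in zip(children, design.iterrows()):
        rng = np.random.default_rng(child)
        mu = (
            truth.weights[row["sample"]]
            .groupby(["species", "gene"])["weight"]
            .sum()
            .reindex(full_index, fill_value=0.0)
            * float(row["library_size"])
        )
        if params.dispersion > 0:
            n = 1.0 / params.dispersion
            p = n / (n + mu.to_numpy())
            draw = np.where(
                mu.to_numpy() > 0, rng.negative_binomial(n, p), 0
            )
        else:
            draw = rng.poisson(mu.to_numpy())
        cols[row["sample"]] = draw
    counts = pd.DataFrame(cols, index=full_index)
    return counts, truth


# ---------------------------------------------------------------------------
# Read-level simulation

def simulate_reads(
    pair: TranscriptomePair,
    design: pd.DataFrame,
    params: SimulationParams,
    seed: int,
    outdir: str | Path | None = None,
    transfer_fraction=None,
) -> tuple[dict[str, dict[str, list[tuple[str, str]]]], pd.DataFrame, SimTruth]:
    """Simulate stranded paired-end reads for every sample in the design.

    Read pairs are drawn gene-proportionally from the sample's mixture
    weights; fragments are placed uniformly on the (sense-strand)
    transcript; mate 1 is the fragment 5' end, mate 2 the reverse
    complement of its 3' end; sequencing errors are i.i.d. substitutions.
    Returns per-sample reads, the per-read truth table, and the ground
    truth; optionally writes FASTQ (Phred+33) and the truth TSV under
    ``outdir``.
    """
    params.validate()
    length = len(next(iter(pair.seq_a.values())))
    if params.read_length > length:
        raise ConfigError("read_length exceeds transcript length")
    truth = build_truth(params, design, seed, transfer_fraction)
    design = truth.design
    rl, fl = params.read_length, params.fragment_length

    mats = {
        DONOR: np.vstack([_encode(pair.seq_a[g]) for g in pair.genes]),
        ACCEPTOR: np.vstack([_encode(pair.seq_b[g]) for g in pair.genes]),
    }
    gene_pos = {g: i for i, g in enumerate(pair.genes)}

    ss = np.random.SeedSequence([int(seed), 53])
    children = ss.spawn(len(design))
    reads: dict[str, dict[str, list[tuple[str, str]]]] = {}
    truth_rows = []
    for child, (_, row) in zip(children, design.iterrows()):
        rng = np.random.default_rng(child)
        sample = row["sample"]
        n = int(row["library_size"])
        tab = truth.weights[sample].reset_index(drop=True)
        p = tab["weight"].to_numpy()
        pick = rng.choice(len(tab), size=n, p=p / p.sum())
        species = tab["species"].to_numpy()[pick]
        gene = tab["gene"].to_numpy()[pick]
        source = tab["source"].to_numpy()[pick]

        tr_idx = np.fromiter((gene_pos[g] for g in gene), dtype=np.int64, count=n)
        start = rng.integers(0, length - fl + 1, size=n)
        offsets = np.arange(rl)
        m1 = np.empty((n, rl), dtype=np.uint8)
        m2 = np.empty((n, rl), dtype=np.uint8)
        for sp in (DONOR, ACCEPTOR):
            sel = species == sp
            if not sel.any():
                continue
            rows_ = mats[sp][tr_idx[sel]]
            pos1 = start[sel, None] + offsets[None, :]
            pos2 = start[sel, None] + (fl - rl) + offsets[None, :]
            m1[sel] = np.take_along_axis(rows_, pos1, axis=1)
            frag3 = np.take_along_axis(rows_, pos2, axis=1)
            m2[sel] = _COMPLEMENT[frag3[:, ::-1]]
        for m in (m1, m2):
            err = rng.random((n, rl)) < params.error_rate
            if err.any():
                idx = np.searchsorted(_BASES, m[err])
                shift = rng.integers(1, 4, size=err.sum())
                m[err] = _BASES[(idx + shift) % 4]

        ids = [f"{sample}:{i:07d}" for i in range(n)]
        reads[sample] = {
            "R1": [(rid, _decode(m1[i])) for i, rid in enumerate(ids)],
            "R2": [(rid, _decode(m2[i])) for i, rid in enumerate(ids)],
        }
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": ids,
                    "sample": sample,
                    "origin_species": species,
                    "origin_gene": gene,
                    "source": source,
                }
            )
        )
    truth_table = pd.concat(truth_rows, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        tio.write_fasta(pair.records(DONOR), outdir / "transcriptome_human.fasta")
        tio.write_fasta(pair.records(ACCEPTOR), outdir / "transcriptome_mouse.fasta")
        tio.write_design(design, outdir / "design.tsv")
        for sample, mates in reads.items():
            for mate, recs in mates.items():
                tio.write_fastq(recs, outdir / "reads" / f"{sample}_{mate}.fastq")
        truth_table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return reads, truth_table, truth
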
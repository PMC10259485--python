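# Methods

## Problem and model

When two cell populations of different species are co-cultured, a small
fraction of donor-cell mRNA ends up inside acceptor cells (contact-dependent
transfer, e.g. through tunneling nanotubes). Bulk RNA-seq of the sorted
acceptor fraction then contains a low level of donor-species reads that must
be separated from two confounders: residual donor *cells* that survive
sorting, and a uniform library-preparation/sequencing background (index
hopping). The experimental design this package models has four conditions,
each with replicates:

* **single_donor** — pure donor culture (endogenous expression reference);
* **single_acceptor** — pure acceptor culture (any foreign reads are pure
  library background);
* **mix** — cultures grown separately, combined only after harvest and
  immediately sorted (contamination + background, but no transfer);
* **coculture** — grown together (transfer + contamination + background).

All inference reduces to comparisons of donor-species ("foreign") read
levels across these conditions.

## Species-of-origin classification

Reads are assigned by a two-genome mismatch rule. Each read pair is placed
end-to-end (no soft clipping, no gaps) at every offset of every transcript
in both orientations, on both transcriptomes; mates must land on the same
transcript in opposite orientations and their Hamming distances are summed.
A pair is a *bona fide* donor read iff it (i) aligns uniquely to the donor
transcriptome, (ii) with at most `max_mismatch_primary` mismatches
(default 0), and (iii) its best distance to the acceptor transcriptome is at
least `min_diff_other` (default 3, i.e. "more than two differences"); a
pair that does not align to the other genome at all satisfies (iii), since
no alignment is the extreme of divergence. The rule is symmetric, and with
`min_diff_other > max_mismatch_primary` it is a theorem (asserted in tests)
that no read can be bona fide for both species.

Design choices here, made where a real aligner leaves latitude:

* "Differences" is operationalized as ungapped Hamming distance; indels are
  outside the model. End-to-end, no-soft-clip alignment makes mismatches
  the operative quantity; users with real aligner output can supply edit
  distances through the alignment-summary TSV bridge instead.
* "Unique" means exactly one placement attains the minimum summed distance
  (equivalently, the second-best placement is strictly worse) — the
  conservative reading of "uniquely aligned".
* Distances above `mismatch_cap` (default 10) are censored: the pair is
  reported unaligned, never with a fabricated finite distance.

## Quantification

Bona fide reads are counted per best-hit gene on the assigned genome
(transcript-level counting; unassigned reads count nowhere), and RPM is
`1e6 * count / library_size` with library size equal to the sample's
**total** read pairs, not only assigned ones. This keeps foreign-read
levels interpretable as fractions of total sequencing output and makes Mix
and Co-culture columns directly comparable.

## Transfer statistics

**Background-corrected proportions.** With replicate percentages of foreign
reads in Mix, Co-culture and acceptor single cultures, the corrected values
are `mean(condition) − mean(single)`, and the headline ratio is
`corrected_coculture / corrected_mix`. The ratio is reported as undefined
(with a diagnostic, not an exception) when the corrected Mix value is ≤ 0.

**Robust-transfer detection.** Genes whose RPM exceeds 10 in *every*
co-culture replicate enter a one-tailed unpaired Student t-test (co-culture
\> mix) followed by the two-stage Benjamini–Krieger–Yekutieli (BKY) linear
step-up FDR procedure: stage one runs Benjamini–Hochberg at
α′ = α/(1+α) to estimate the number of true nulls m₀ = m − r₁; stage two
steps up at α′·m/m₀. Reported q-values satisfy `reject ⇔ q ≤ α`. A gene is
*robust* when fold change (co/mix of mean RPM) exceeds 2 and q < 0.05.
Equal-variance Student rather than Welch: with two replicates per group,
Welch's degrees-of-freedom estimate is degenerate. Fold change with a zero
Mix mean is +∞ with no pseudocount — the RPM pre-filter already guards the
numerator, and the division is documented rather than hidden.

*Degenerate-variance convention:* when both groups have zero sample
variance the pooled standard error is 0 and the t statistic is undefined;
such genes get p = 1 (t = 0) regardless of the means. Exact within-group
ties arise from small integer counts, carry no variance information in a
2+2 design, and treating them as infinitely significant would destroy FDR
control; deep libraries never produce them for genes that matter.

**Percentage transfer.** Per gene,
`(mean RPM co-culture − mean RPM mix) × 100 / mean RPM donor single culture`,
i.e. the ×100 multiplies the numerator difference — the only reading that
yields percentages ≪ 100 at realistic signal levels. Genes with donor
single-culture RPM < 100, co-culture RPM < 10, or FC < 2 are excluded
(strict inequalities, matching the printed thresholds); excluded genes carry
their failing filter flags rather than a number. The cohort summary reports
the median over unfiltered genes, its log10, and — because a log-scale
distribution summary may equally be read as the median of per-gene logs —
the median of per-gene log10 values as well.

**Spot-count transfer.** For single-molecule FISH validation data the same
quantity is simply `100 × mean acceptor-cell spots / mean donor-cell
spots`, reported at full precision and rounded to 2 significant figures
(the convention for human-readable summaries; machine outputs keep full
precision).

**Expression dependence.** OLS of foreign signal on donor expression,
by default on log10(RPM + 1) (base-10 axes; pseudocount 1 RPM,
configurable, since none is dictated by the data), with Pearson and
Spearman coefficients and a pointwise mean-response confidence band at 99%
from the t distribution.

**Distribution shift.** Gaussian (mean, sd) fits to per-gene
log10(RPM + pseudocount) in Co-culture and Mix; the rightward shift of the
co-culture distribution is assessed by a two-sample t-test on the per-gene
log values. The shift test is a declared choice: the underlying analysis
style (fitting log distributions and quoting a p-value for the shift) does
not pin down the test.

**Overlap enrichment.** Upper-tail hypergeometric test
P(X ≥ observed overlap) for two gene sets in a finite universe, via the
exact hypergeometric distribution.

**Differential-expression thresholding.** The DE model itself (e.g.
DESeq2's shrinkage estimator) is out of scope; given an upstream table with
log2 fold changes, adjusted p-values and normalized counts, genes are
called up (down) when |log2FC| ≥ 1 with the right sign, padj < 0.05, and
≥ 50 normalized counts in ≥ 2 samples.

## Synthetic co-cultures

The simulator provides a recoverable answer for every stage.

* **Transcriptomes.** `n_genes` ortholog pairs of equal length; the
  acceptor copy differs from the donor copy by i.i.d. substitutions at a
  per-gene `divergence` rate (default 5%, roughly the coding-sequence
  divergence regime that motivates the mismatch rule). A substituted site
  always changes base, so divergence 1 means every site differs.
* **Expression.** Per-gene expression is log-uniform over 4 orders of
  magnitude (default), giving the dynamic range that expression-dependence
  regression needs. Both species' per-cell totals are rescaled to the same
  constant (`transcripts_per_cell`, default 3×10⁵ — a typical mammalian
  per-cell mRNA count), so RPM ratios map directly onto per-cell fractions
  and the designed transfer fraction is recoverable from percentage
  transfer without a cell-content correction.
* **Foreign-read sources.** Co-culture acceptor cells carry
  `transfer_fraction[g] × donor expression[g]` donor transcripts (default
  0.5%, the "typically < 1%, median ≈ 0.34%" regime); a
  `contamination_fraction` of cells in Mix **and** Co-culture samples are
  donor cells (default 0.1%, within the reported 0.02–0.3% sorting range);
  and a `hop_rate` fraction of every sample's reads (default 1%) is drawn
  from the library-size-weighted pool of all samples, emulating index
  hopping. Mix and Co-culture are generated from identical parameters
  except that transfer is forced to zero in Mix — the control logic of
  cells mixed only after harvest. Single cultures have no contamination;
  their only foreign source is hopping.
* **Reads.** Stranded 2×`read_length` pairs (sense strand only — the
  modeled libraries are directional; the aligner still checks both
  orientations) from uniformly placed fixed-length fragments, with i.i.d.
  per-base substitution errors (default 0.1%). No junctions, PCR
  duplicates, quality-dependent errors or 3′ bias. A count-level shortcut
  (`simulate_count_matrix`) draws negative-binomial counts (dispersion
  0.05 by default; Poisson at 0) around the same expected mixture, for
  statistics tests that need no reads.
* **Determinism.** All randomness flows from one integer seed; each stage
  and sample derives an independent substream, so identical seed + config
  gives byte-identical outputs.

What passing tests show — and do not. Recovery and FDR results on these
simulations validate the *inference machinery* under the stated generative
model. Real data add mappability structure, homology hot-spots, indels,
non-uniform hopping and composition effects that the simulator deliberately
omits, so desk-scale green tests do not certify genome-scale operating
characteristics.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: transcriptomes
of 10–150 genes × 200–400 bp, libraries of 10⁴–10⁶ read pairs (10⁵ for the
recovery study), 20 seeds per recovered fraction, 200 simulated experiments
for the null-FDR study. Parameter-recovery checks select genes by their
*expected* (truth-known) co-culture signal — at least 3× the RPM filter —
so that the measurement captures estimator bias rather than
threshold-selection effects, and evaluate the percentage-transfer formula
with filters disabled on that pre-defined gene set. Empirically the
recovered medians sit within a few percent of the designed fractions, with
the residual attenuation ≈ (1−c)²(1−h)/(1+f) predicted by the mixture
algebra.

## Known limitations

* The toy aligner is exhaustive and transcript-level; it is meant for
  desk-scale references, with the alignment-summary TSV as the bridge to
  STAR-class aligners on real genomes.
* Two replicates per condition make the one-tailed t-test underpowered;
  at a 0.5% transfer fraction only the strongest transfers reach the
  robust set (visible in `analysis/05`). This conservatism is inherent to
  the design, not a defect of the correction.
* Percentage transfer compares RPM across samples with different RNA
  content; the equal-per-cell-total assumption built into the simulator is
  exactly the assumption the statistic makes on real data.
* The hypergeometric universe for overlap tests must be chosen by the
  user (genes detected and tested); results are sensitive to it.
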
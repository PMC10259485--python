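# transferome

Quantification of intercellular mRNA transfer from mixed-species co-culture
RNA-seq.

When human donor cells and mouse acceptor cells are grown in contact, a
small fraction (typically < 1%) of donor mRNAs ends up inside acceptor
cells. After sorting the acceptor fraction and sequencing it deeply, the
transferred RNA appears as a low level of human-genome reads in a mouse
sample — entangled with reads from residual human *cells* that survive
sorting and with an index-hopping background from library preparation.
This package implements the full computational path from reads to
transfer estimates for that design, aimed at researchers analyzing
xenograft-style or co-culture RNA-seq:

* **Species-of-origin classification** — each read pair is aligned
  end-to-end (ungapped, both orientations) to both transcriptomes and
  called a *bona fide* human read iff it aligns uniquely to the human
  reference with 0 mismatches and has > 2 differences to the mouse
  reference (symmetrically for mouse). A TSV bridge accepts summaries from
  external aligners.
* **Background correction** — foreign-read percentages in the Mix control
  (cells combined only after harvest: contamination without transfer) and
  in Co-culture are corrected by subtracting the single-culture background.
* **Transfer detection** — per-gene RPM (`1e6·count/library size`), a
  pre-filter of RPM > 10 in all co-culture replicates, a one-tailed
  unpaired Student t-test (co-culture > Mix), the two-stage
  Benjamini–Krieger–Yekutieli FDR, and the robust-transfer call
  FC > 2 ∧ q < 0.05.
* **Percentage transfer** — per gene,

  ```
  % transfer = (mean RPM co-culture − mean RPM mix) · 100 / mean RPM donor single culture
  ```

  with genes excluded when donor single-culture RPM < 100, co-culture
  RPM < 10, or FC < 2; plus the smFISH spot-count analogue
  `100 · acceptor spots / donor spots`.
* **Downstream statistics** — expression-dependence regression with 99%
  confidence bands, Gaussian fits to log10 RPM distributions,
  hypergeometric gene-set overlap, and post-hoc DE thresholding
  (|log2FC| ≥ 1, padj < 0.05, ≥ 50 counts in ≥ 2 samples).
* **A ground-truthed simulator** of two-species co-cultures (ortholog
  transcriptomes with controlled divergence, four-condition design,
  per-gene transfer fractions, sorting contamination, index hopping,
  sequencing error), so every stage is testable without downloads.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

The five pipeline stages run from a single seeded config, as a CLI
(`transferome simulate|classify|count|transfer|report`) or through the
numbered drivers in `analysis/`:

```bash
python analysis/01_simulate_cocultures.py
python analysis/02_classify_reads.py
python analysis/03_count_and_normalize.py
python analysis/04_transfer_statistics.py
python analysis/05_distributions_and_dependence.py
```

Stage 02 prints the per-sample species tallies, e.g.:

```
single_acceptor_r1: bona fide human 0.167%  mouse 79.58%  unassigned 20.25%
mix_r1:             bona fide human 0.333%  mouse 80.08%  unassigned 19.58%
coculture_r1:       bona fide human 0.583%  mouse 79.83%  unassigned 19.58%
```

— foreign (human) reads are rarest in the pure mouse culture (index
hopping only), higher in Mix (plus cell contamination) and highest in
Co-culture (plus genuine transfer); the unassigned ~20% are pairs whose
100 bp of sequence happens to carry ≤ 2 cross-species differences at 5%
divergence, exactly the homology loss the mismatch rule pays for
specificity. Stage 04 then corrects and summarizes:

```
corrected foreign-read proportions: mix 0.2083%, coculture 0.5833%, ratio 2.80
median percentage transfer over 5 unfiltered genes: 0.957% (designed transfer fraction 0.500%)
```

and stage 05, on a deeper count-level simulation, recovers the global
signatures of transfer:

```
rightward shift of the co-culture distribution: 0.234 log10 units (t-test p = 1.21e-02)
transfer vs donor expression (log10 scale): Pearson 0.960, Spearman 0.968, slope 0.703
spot-count transfer, low-expression reporter: 7/429 molecules = 1.6% (full precision 1.6317%)
```

In the library:

```python
>>> import transferome as tf
>>> corr = tf.corrected_foreign_proportion(
...     pct_mix=[1.11, 1.15], pct_coculture=[1.71, 1.39], pct_single=[1.04, 1.07])
>>> corr.corrected_mix, corr.corrected_coculture, round(corr.ratio, 1)
(0.075, 0.495, 6.6)
```

i.e. after background subtraction the co-culture acceptor fraction carries
6.6× more foreign reads than residual-cell contamination alone explains —
the signature of genuine transfer.

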
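# dimerqc

Quality control for small-RNA sequencing libraries with a focus on
**adapter-dimer contamination** — the failure mode that quietly ruins
extracellular-vesicle and other low-input sRNA-seq experiments.

During library preparation, a 5' adapter can ligate directly onto a 3'
adapter with no biological insert between them. These adapter dimers carry
everything needed to cluster and sequence — often *more* efficiently than
real library molecules — so a contaminated library spends its sequencing
capacity on reads that are pure adapter. Post-sequencing, those reads are
removed during pre-processing, producing massive read loss; worse, when the
dimer fraction varies across samples it induces batch effects that can
dominate the biology.

`dimerqc` is a Python library (plus a thin CLI) that covers the whole
QC arc:

- **Adapter matching** (`dimerqc.adapters`) — error-tolerant semi-global
  alignment of an adapter inside a read under unit-cost edit distance. An
  alignment of *k* adapter bases is admissible when
  `errors ≤ ⌊error_rate · k⌋`; ends are free so adapter prefixes running
  off the read's 3' end (read-through) and suffixes hanging off the 5' end
  are handled. Built-in presets: Illumina TruSeq small RNA
  (`TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC`, error rate 0.1) and Ion Torrent
  small RNA (`ATCACCGACTGCCCATAGAGAGGAAAGCGG`, error rate 0.2, matched on
  either strand side).
- **Read classification** (`dimerqc.preprocess`) — every raw read becomes
  `DIMER` (3' adapter with ≤ 2 nt of insert in front of it), `SHORT`
  (insert below 15 nt), `LOW_QUALITY` (below 15 nt only after 3' quality
  trimming at Q20) or `CLEAN`; the four counts partition the total exactly
  and `read loss = 100 · (raw − clean)/raw`. Per-sample diagnostics mirror
  the familiar FastQC modules: cumulative adapter content per position,
  overrepresented sequences (> 0.1% of reads), mean quality per position.
- **Cohort analysis** (`dimerqc.cohort`) — samples ordered by read loss are
  segmented by exhaustive piecewise OLS of loss on rank with BIC model
  selection, separating background loss from a contaminated subgroup;
  per-sample loss is decomposed into dimer / short / low-quality causes;
  RNA input vs. loss is tested by Spearman correlation (exact permutation
  p for n ≤ 9).
- **Batch-effect detection** (`dimerqc.expression`) — counts are
  transformed to `log2((c + p)/(lib + 2p) · 10⁶)` (prior p = 2), samples
  embedded by classical MDS on leading-log-fold-change distances (RMS of
  the top-500 |Δlog-CPM| per pair), and each coordinate is tested for
  association with the per-sample dimer percentage via Spearman rho with a
  seeded permutation p-value.
- **Electropherogram screening** (`dimerqc.electropherogram`) — pre-
  sequencing, adapter dimers appear as a discrete peak below the library
  peak (~88 bp on Ion Torrent, ~120 bp on Illumina TruSeq small-RNA
  traces). `detect_dimer_peak` calls peaks per window and reports
  `dimer_area / (dimer_area + library_area)`.
- **Simulator** (`dimerqc.simulate`) — a seeded generator of libraries
  with known composition (dimer/short/clean mixtures, platform-specific
  read construction, substitution/indel noise, quality decay) and of
  multi-sample cohorts with an optional dimer-coupled composition bias, so
  every stage above can be validated against ground truth without any
  external data.

## Worked example

`examples/scan_simulated_library.py` simulates a 75-nt Illumina library of
10,000 reads with 40% dimers and 10% short inserts, then runs per-sample QC:

```
raw reads        : 10000
adapter dimers   : 40.48%  (simulated truth 40.52%)
short inserts    : 9.16%  (truth 9.18%)
low quality      : 0.00%
clean reads      : 50.36%
read loss        : 49.64%
adapter content at read positions 0..4: [40.5, 40.5, 40.5, 41.4, 42.1]
top overrepresented sequence: TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC... (19.4% of reads)
```

The classifier recovers the simulated dimer fraction to a fraction of a
percentage point; the adapter-content curve already sits at 40% at read
position 0 (the dimer fingerprint — a clean library starts near 0), and the
top overrepresented sequence is the 3' adapter itself.

The other examples each exercise one capability end to end:
`adapter_matching.py`, `cohort_stratification.py`, `batch_effect_mds.py`,
`electropherogram_peaks.py`. The same functionality is available from the
shell via `dimerqc scan / cohort / mds / epg / simulate` (see
`dimerqc --help`).

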
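# atacatlas

Downstream analysis of multi-tissue ATAC-seq atlases: per-sample quality
control, replicate-reproducible peak consolidation, consensus peak × sample
count matrices with RPM normalization, Shannon-entropy tissue-specificity
scoring, replicate-reproducibility analysis, and motif-enrichment-matrix
summarization — plus a synthetic atlas generator so the entire pipeline is
testable and demonstrable without any sequencing data.

## Who this is for

ATAC-seq measures chromatin accessibility: the Tn5 transposase inserts
sequencing adapters preferentially into open chromatin, so fragment density
maps candidate regulatory elements genome-wide. Building a *tissue atlas*
from dozens of such libraries raises a standard set of downstream
questions — are the libraries any good, which peaks are reproducible, how
do samples relate, and which elements (and transcription-factor motifs) are
tissue-specific? `atacatlas` packages those computations as a tested Python
library with a thin CLI, aimed at anyone assembling or reanalyzing a
bulk ATAC-seq panel across tissues or conditions.

## The statistics at the core

* **TSS enrichment score** — aggregate per-base fragment coverage across
  transcription-start-site-centered windows (±1 kb, orientation-flipped for
  minus-strand genes), normalized by the outer-flank background and
  smoothed; the maximum is the score. Flat coverage scores ≈ 1.
* **Fragment-size periodicity** — the fragment-length histogram of a good
  library is multimodal: sub-nucleosomal plus mono/di/tri-nucleosome modes
  spaced ~200 bp. Modes are detected on a smoothed histogram and their
  median spacing reported.
* **Sample exclusion rule** — libraries with TSS enrichment < 10.0 or
  fewer than 10,000 replicate-reproducible peaks are dropped.
* **Consensus matrix** — peaks reproducible between technical replicates
  (reciprocal overlap ≥ 0.5 of the shorter peak) are merged across tissues
  into a standard peak list; fragments are counted per peak and normalized
  to RPM = count × 10⁶ / usable reads, with a log₁₀(RPM + 1) layer.
* **Entropy specificity index** — for each peak with per-tissue
  accessibility `E_i` (replicate-averaged RPM), the relative accessibility
  is `R_i = E_i / ΣE` and the specificity index

  `H = −Σ_i R_i log₂ R_i`  (bits),  `0 ≤ H ≤ log₂ N`.

  `H ≈ 0` means accessible in essentially one tissue; `H = log₂ N` means
  ubiquitous. Peaks with `H` strictly below 3.5 bits (for a 20-tissue
  panel; rescaled otherwise) are called tissue-restricted and assigned to
  their argmax tissue.
* **Motif summary** — a motif × tissue matrix of −log₁₀ hypergeometric
  enrichment P-values (consensus matching with a mismatch budget, both
  strands) over restricted-peak sequences; the display rule keeps motifs
  with row mean > 20 and shows the 50 with the highest coefficient of
  variation; tissues are clustered on Euclidean distance.

The synthetic generator (`simulate_atlas`) emulates exactly these
structures — shared and tissue-restricted peaks, nucleosomal fragment-length
mixtures, TSS-proximal excess, negative-binomial-like replicate noise, and
per-replicate peak-call dropout — and returns closed-form ground truth so
every stage can be checked against an oracle.

## Worked example

```python
import atacatlas as aa

atlas = aa.simulate_atlas(aa.SimulationConfig(seed=1))   # 20 tissues x 2 reps
cm = aa.build_counts_matrix(
    atlas.fragments, atlas.truth.peaks,
    library_sizes={r.sample_id: r.usable_reads for r in atlas.records},
)
tm = aa.aggregate_by_tissue(cm.rpm, atlas.records)
ri, h = aa.entropy_scores_matrix(tm)
print((h < 3.5).sum())        # 178 peaks called tissue-restricted
```

Running `python examples/04_tissue_specificity.py` (the same computation
with the comparison against ground truth) prints:

```
entropy range: 0 (one tissue only) .. log2(20) = 4.322 bits
observed: min 2.787, median 4.300, max 4.318
179 peaks called tissue-restricted at the 3.5-bit cutoff
vs ground truth (200 planted): recall 89.5%, precision 100.0%
data-driven cutoff 3.72 bits: recall 100.0%, precision 100.0%
peak_00001: H = 3.15 bits, assigned to tissue_18 (truth: tissue_18)
```

Shared peaks sit near the 4.32-bit maximum; the planted tissue-restricted
peaks fall well below it and are recovered essentially perfectly, with the
fixed 3.5-bit rule trading a little recall for exact precision. The other
scripts under `examples/` each demonstrate one capability (QC metrics,
the synthetic oracle, consensus matrices, replicate agreement, motif
summaries, the end-to-end pipeline) and can be run the same way.

The package also ships the metadata/mapping-statistics sheet of a published
66-library mouse tissue atlas (20 tissues, both sexes, two technical
replicates each) as `aa.load_atlas_records()`; `examples/01_sample_qc.py`
recomputes its usable-read percentages and applies the exclusion rule.

A thin CLI mirrors the stages:

```sh
atacatlas run --out demo_run          # one-command synthetic demonstration
atacatlas simulate --out inputs       # or stage by stage: qc, peaks,
atacatlas qc --sheet ... --out qc.tsv # matrix, specificity, correlate, motifs
```

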
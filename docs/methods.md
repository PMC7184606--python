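# Methods

## Scope and model

`polyatails` analyses per-read poly(A) tail-length estimates from nanopore
direct RNA sequencing, as produced by a signal-level tail caller in the
Nanopolish `polya` output dialect. The package covers four stages:

1. **QC and ingest** — only reads whose tail segmentation carries the
   `PASS` tag enter any analysis; all other tags are excluded
   unconditionally.
2. **Summarization** — per transcript (or transcript class) and condition,
   the sample median and the peak (mode) of a Gaussian-kernel density
   estimate, with the density rescaled to a maximum of 1 for plotting-style
   export.
3. **Differential polyadenylation** — per transcript, an ordinary
   least-squares fit of `log2(tail) ~ condition + replicate` on per-read
   PASS estimates. The Gaussian family with identity link makes this the
   GLM it is usually described as; the condition coefficient is a log2 fold
   change of tail length and its two-sided Wald p-value is the test
   statistic. p-values are Benjamini–Hochberg adjusted across exactly the
   transcripts that pass the read-count pre-filter. A transcript is called
   significant when padj < 0.05, |Δmedian| ≥ 10 nt (computed on raw-nt
   medians), and each condition has ≥ 20 supporting reads.
4. **Spike-in calibration and half-lives** — barcode demultiplexing of
   synthetic tail standards by normalized local alignment, and half-life
   estimation from 4sU-style metabolic labeling fractions or
   actinomycin-D-style shutoff time courses.

## Differential test: choices and edge cases

* **Response transform.** Tails below 1 nt are floored to 1 nt before the
  log2 (configurable `tail_floor`); PASS estimates are rarely
  sub-nucleotide, and the floor keeps the response finite.
* **Design.** Condition enters as a single indicator with the first
  condition (sample-sheet order) as reference; replicates enter as
  treatment contrasts against the first replicate level present for that
  transcript. With a single replicate level the model reduces to the
  two-group comparison, and the reported p-value is algebraically the
  pooled-variance two-sample t-test — the property the test suite checks to
  1e-10.
* **Inference.** t-based Wald p-values (OLS small-sample inference), two
  sided.
* **Degenerate fits.** A tested transcript with fewer than two distinct
  tail values, or a singular design yielding a non-finite p-value, is
  reported with p = 1 and a `degenerate` flag rather than dropped, so the
  BH family remains the set of transcripts that passed the read filter.
* **Filter semantics.** The ≥ 20-reads filter is applied *before* testing
  and therefore defines the multiple-testing family; the padj and Δmedian
  filters are applied after.

## KDE mode estimation

Densities use a Gaussian kernel on a fixed grid (0–350 nt, 0.5 nt step;
ties in the argmax resolve to the smallest tail). The default bandwidth for
the scalar mode is a *mode-targeted oversmoothed rule*

    h = σ̂ · (0.75·n)^(−1/7)

rather than a density-targeted rule (Silverman/Scott, both still
selectable, as is a fixed bandwidth in nt). The argmax of a KDE is a
different estimand than the density itself: its optimal bandwidth shrinks
at the n^(−1/7) rate, i.e. slower than the n^(−1/5) of L2-optimal rules, so
density-optimal bandwidths systematically undersmooth the peak and leave
the argmax noisy. At the package's desk scale (≈5,000 reads per class) the
oversmoothed rule cuts the argmax sampling variability severalfold at the
price of a small (≲1 nt) upward bias on right-skewed tail distributions —
a good trade for peak reporting. Samples with zero variance are reported as
a spike at the observed value.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
(WT/KO), three-replicate nanopore tail-profiling experiment:

* **Classes.** Three transcript classes, 25 transcripts each:
  an immunoglobulin-like class whose modal tail shortens from 60 nt (WT) to
  41 nt (KO); a mitochondria-like class fixed at 52 nt in both conditions;
  and a condition-invariant bulk class at 75 nt. The Ig and mitochondrial
  peaks are the experiment's reported values; the bulk peak is not reported
  anywhere and 75 nt was chosen once as a realistic mammalian bulk mRNA
  peak between the mitochondrial and long-tail regimes.
* **Tail law.** True per-read tails are gamma distributed, parameterized by
  the mode m and a scale θ (default 6 nt): shape = m/θ + 1. The gamma is
  right-skewed and non-negative, matching published tail densities; θ = 0
  is the documented degenerate point-mass limit.
* **Measurement noise.** Multiplicative log-normal with mean 1 and relative
  sd 0.15 by default. The tail caller's error is not quantified publicly,
  so this is a tunable assumption.
* **Mode calibration.** The configured class mode is defined as the mode of
  the *emitted* (noise-convolved) distribution, because reported peak
  values in real experiments are peaks of measured densities. The generator
  numerically solves for the latent gamma mode whose product with the noise
  and batch mixture peaks at the configured value (fixed-point iteration on
  a numerically integrated product density). The truth table's
  `true_median` is likewise the median of the measured law.
* **Replicates and batch.** Three replicates per condition with additive
  shifts on the log2 scale (default 0, +0.05, −0.05), so the differential
  model's replicate predictor is correctly specified under the default
  generator. Read counts per transcript per sample are negative binomial
  (mean 75, size 10), giving ≈5,600 reads per class per condition and
  ≈5,000 after QC.
* **QC failures.** Assigned uniformly at random at rate 0.10, independent
  of tail length. Real failures may be length-biased; this simplest-null
  choice means QC-related length biases are *not* exercised by the tests.
* **Spike-ins.** Reads are 5ʹ padding + barcode (independent per-base
  substitutions, default 2%) + anchor + body; the anchor and body are the
  first 60 nt of the eGFP coding sequence. The six 18-mer barcode sequences
  are synthetic stand-ins (the published standards' sequences are not
  available); they were constructed so that the maximal pairwise normalized
  local-alignment score is 0.28, below the 0.3 assignment threshold. The
  paired tail estimate is `true_tail × (1 + ε)`, ε ~ N(0, 0.15²). Indels
  inside the barcode are not simulated.
* **Decay.** Labeling mode emits `nascent/total = 1 − 2^(−tL/t½)`; chase
  mode emits `A(t) = A₀·2^(−t/t½)` at the given timepoints; both with
  optional multiplicative noise and exact ground truth recorded.

What passing tests therefore show: the pipeline recovers truth under
gamma-shaped tails, length-independent QC failure, log-scale batch shifts
and substitution-only barcode errors. They do not certify behaviour under
length-biased QC failure, heteroskedastic caller error, barcode indels, or
transcript-specific tail laws.

## Spike-in assignment

The anchor is located by exact, case-insensitive leftmost match; reads
without the anchor are unassigned (a mutated anchor is a documented
limitation of exact matching). The candidate region is the 60 nt
immediately preceding the anchor. Each barcode is scored by a
Smith–Waterman-style local DP with match +1, mismatch −1, gap opening 0
and gap extension −1 — i.e. a length-k gap costs k (the Biostrings
convention; affine conventions differ, so this is stated explicitly). `N`
never matches, including against `N`. The raw score is divided by the
barcode length, giving a normalized score in [0, 1]; the best barcode is
assigned if its normalized score exceeds 0.3, and ties between barcodes are
left unassigned (ambiguity is safer than an arbitrary pick). The DP is
implemented with a row-wise prefix-scan recurrence (exact for linear gap
costs) and is checked in the tests against both a brute-force full-matrix
DP and Biopython's `PairwiseAligner` with the equivalent parameterization.

## Half-life estimation

* **Labeling:** `t½ = −tL·ln2 / ln(1 − nascent/total)`, defined for
  fractions strictly inside (0, 1); the default pulse length is tL = 1 h.
  How a qPCR enrichment chain is collapsed into the scalar nascent/total is
  protocol-specific, so the estimator takes the fraction as its primary
  input; `relative_expression_ddct` (fold = 2^−ΔΔCt) and
  `normalize_by_spikein` (per-sample division by spike recovery, anchored
  to the first sample) are provided as composable pieces.
* **Chase:** nonlinear least squares of `A(t) = A₀·e^(−kt)` with A₀, k ≥ 0,
  initialized from a log-linear fit. The plateau is fixed at 0 by default —
  with ≤5 timepoints a free plateau is poorly identified — and available
  via `with_plateau=True`. A fit pinned at k ≈ 0 is flagged
  `no_decay` with an infinite half-life rather than an error. The optimizer
  is cross-checked against a dense (A₀, k) grid search in the tests.

## Problem sizes

Default test and acceptance scale: ≈33,000 reads for the three-class tail
dataset (≈5,000 PASS reads per class per condition), 500 transcripts for
null-calibration checks at ≈90 reads per condition, 500 reads per barcode
for the six spike-in standards, and 50 replicate decay series of 5
timepoints. These sizes give stable recovery statistics while keeping a
full run in minutes on one core.

## Known limitations

* QC failure is simulated independent of tail length.
* The anchor must match exactly; reads with sequencing errors inside the
  anchor are dropped from assignment rather than rescued.
* Barcode errors are substitution-only in the generator, although the
  aligner itself handles indels.
* The differential model assumes log2 tails are homoskedastic across
  conditions within a transcript; no robust/quantile variant is provided.
* The oversmoothed mode bandwidth slightly biases peaks of strongly
  right-skewed distributions upward; use `bandwidth="silverman"` when the
  density curve itself, rather than a stable peak location, is the goal.
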
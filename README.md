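# polyatails

Poly(A) tail profiling from nanopore direct RNA sequencing: per-read tail
QC and summarization, differential polyadenylation testing, spike-in
barcode calibration, and mRNA half-life estimation.

Nanopore direct RNA sequencing reads native mRNA molecules 3ʹ→5ʹ, so the
poly(A) tail of every read can be measured from the raw signal (e.g. by the
Nanopolish `polya` caller). That turns questions like *"does knocking out a
cytoplasmic poly(A) polymerase shorten the tails of its target mRNAs?"*
into a per-read statistical comparison. `polyatails` is for
transcriptomicists who have per-read tail tables (or want realistic
simulated ones) and need the downstream analysis:

* **QC filtering** — only reads with the caller's `PASS` tag are analysed.
* **Summaries** — per transcript × condition: sample median and the KDE
  peak ("mode") of the tail distribution, plus max-scaled density curves.
* **Differential polyadenylation** — per transcript, the GLM
  `log2(tail) ~ condition + replicate` on per-read PASS estimates
  (Gaussian family ≡ OLS); two-sided Wald p for the condition coefficient;
  Benjamini–Hochberg adjustment across tested transcripts; a transcript is
  significant when padj < 0.05, |Δmedian| ≥ 10 nt, and both conditions have
  ≥ 20 reads.
* **Spike-in calibration** — barcoded tail standards (predefined tails
  A10, A30, A40, A60, A100, A150) are demultiplexed by locating an anchor
  sequence and locally aligning barcodes against the preceding region
  (match +1, mismatch −1, gap open 0, gap extend −1; score normalized by
  barcode length; assignment above 0.3, ties unassigned), then per-barcode
  tail recovery is evaluated against truth.
* **Half-lives** — from metabolic-labeling fractions,
  t½ = −tL·ln2/ln(1 − nascent/total); from transcription-shutoff time
  courses, one-phase decay A(t) = A₀·e^(−kt) with t½ = ln2/k; plus 2^−ΔΔCt
  relative quantification and spike-in normalization helpers.
* **Synthetic data** — a seeded generator that emulates the statistical
  structure of such an experiment (class-structured tail laws, estimation
  noise, replicate batch shifts, QC failures, barcoded spike-in reads,
  decay curves) with exact ground-truth tables, so the whole pipeline is
  testable without sequencing data.

The core estimators follow scikit-learn conventions
(`DifferentialTailTester`, `BarcodeAssigner`, `OnePhaseDecayFitter`,
`TailKDE` — `fit`, `predict`, `get_params`, fitted `*_` attributes); thin
module-level functions wrap them for one-shot use.

## Worked example

```python
from polyatails import (
    default_config, simulate_tail_dataset, filter_qc_pass,
    summarize_tails, test_differential_tails,
)

records, samples, truth = simulate_tail_dataset(default_config(seed=1))
passed = filter_qc_pass(records)

merged = passed.merge(samples, on="sample_id")
for cond in ("WT", "KO"):
    tails = merged.query(
        "condition == @cond and transcript_id.str.startswith('ig_like')"
    )["polya_length"]
    s = summarize_tails(tails)
    print(f"Ig-like {cond}: n={s.n}  median={s.median:.1f} nt  mode={s.mode:.1f} nt")

results = test_differential_tails(passed, samples)
print(results["significant"].sum(), "of", len(results), "transcripts significant")
```

prints

```
Ig-like WT: n=4981  median=65.5 nt  mode=60.5 nt
Ig-like KO: n=5131  median=46.1 nt  mode=41.0 nt
25 of 75 transcripts significant
```

The default generator encodes an immunoglobulin-like transcript class whose
modal tail shortens from 60 nt (WT) to 41 nt (KO), a mitochondria-like
class fixed at 52 nt, and a condition-invariant bulk class at 75 nt; the
summarization stage recovers the modal peaks, and the differential test
flags exactly the 25 Ig-like transcripts — the two invariant classes pass
the |Δmedian| and padj filters for none of their transcripts.

The same stages are exposed on the command line:

```sh
polyatails simulate --kind tails --seed 1 --out-dir sim/
polyatails difftails --tails sim/tails.tsv --read-samples sim/read_samples.tsv \
    --samples sim/samples.tsv --out-dir results/
polyatails spikein --fasta reads.fasta --barcodes barcodes.tsv \
    --tails spike_tails.tsv --out-dir spike_results/
polyatails halflife --input decay_series.tsv --method decay --out-dir hl/
```

Every run logs its parameters to stderr and writes a JSON run manifest;
identical arguments and seed reproduce identical outputs.

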
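# Methods

`funcmotif` identifies candidate *functional* transcription-factor binding
motifs in enhancer-like sequences by requiring two independent lines of
evidence at the same location: a position-weight-matrix (PWM) match above an
empirically calibrated score cutoff, and concentrated per-nucleotide
importance under a trained enhancer classifier. This note describes each
model and procedure, the defaults, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Labelled dataset construction

Candidate regulatory elements arrive as called accessibility peaks with a
histone-acetylation (H3K27ac-style) tag count per peak. Positives are peaks
with `tag_count >= 32` (inclusive) on non-sex chromosomes, standardised to a
fixed 300 bp window centred on the peak midpoint — summit positions are not
assumed available, so the midpoint is the only anchoring that uses nothing
beyond the interval itself. Windows running off a chromosome end or
containing more than 10 % N are dropped with a warning.

Negatives are the same number of 300 bp random genomic windows, GC-matched
*bin-for-bin*: each negative is drawn uniformly from the eligible window
starts whose GC fraction falls in the same 2 %-wide bin as its paired
positive, excluding windows that overlap any positive. The implementation
indexes every eligible start by GC bin with cumulative sums, which is
distribution-identical to rejection sampling but cannot stall on rare bins;
a genuinely empty bin raises a `SamplingError`. Per-sequence binned matching
was chosen over distribution-level matching because it is reproducible and
directly testable (every emitted pair differs by at most one bin width).

Splits are a pure function of chromosome: one chromosome held out for
validation (default chr8), one for testing (default chr9), the rest train.
This makes split leakage structurally impossible.

## Enhancer classifier

A small convolutional network maps the one-hot window (300 × 4, N rows
encoded 0.25) to a probability of being an active enhancer:

    conv(32 filters × width 12) → ReLU → max-pool(4)
    → conv(32 × 8) → ReLU → global max-pool
    → dense(1) → sigmoid

The final pooling stage is *global*: the planted/biological signal is a
motif at an arbitrary offset, and a flatten-plus-dense head would have to
relearn the same detector at every position — at desk scale (≈1,000
training windows) that fails to generalise, whereas a global max over each
filter's activation profile is the standard translation-invariant head for
motif models (DeepBind-style). The network is implemented directly in NumPy
(im2col convolution, explicit backward passes) so that the attribution
backward pass below has access to every intermediate quantity.

Training: binary cross-entropy, Adam (learning rate 3 × 10⁻³, β₁ = 0.9,
β₂ = 0.999), batch 64, at most 50 epochs, early stopping on validation
auROC with patience 5; the returned parameters are those of the best
validation epoch. All randomness (initialisation, shuffling) flows from one
seed, and the whole path is deterministic under a fixed BLAS. Gradients are
verified against central finite differences in the test suite's development
history; the shipped tests verify seeded determinism and the learning
outcome instead. Evaluation is rank-based auROC with midrank ties
(scikit-learn), cross-checked in tests against a brute-force
pair-concordance estimator.

## Per-nucleotide importance

Importance is computed against a **uniform nucleotide background** — a
reference input of 0.25 in every channel at every position — with DeepLIFT
multipliers under the rescale rule:

* affine layers (conv, dense): linear rule, multipliers propagate exactly
  like gradients;
* elementwise nonlinearities (ReLU, the output sigmoid): rescale rule,
  multiplier = Δoutput/Δinput, falling back to the local derivative when
  |Δinput| < 10⁻⁷;
* max-pool: the gradient path through the actual input's argmax.

Contributions `m · (x − x_ref)` then satisfy **summation-to-delta**: they
sum to `σ(f(x)) − σ(f(x_ref))` on the probability scale. The max-pool
gradient path is exact here (not merely approximate) because the uniform
reference is position-invariant, so every reference activation is constant
within each pooling window and the pooled reference value equals the
reference at the routed position. A `grad_x_input` back-end (gradient of
the output probability times input difference) is available as a fallback
and makes no conservation guarantee; tracks record which method produced
them.

Per-base contributions collapse to one signed score per position by
**summing the four channels**. The observed-base-only convention was
considered and rejected: against a uniform reference the three "off"
channels carry real (negative) contribution mass, and discarding it breaks
summation-to-delta at the per-position level.

Strands are handled at interpretation time: the window and its reverse
complement are attributed separately, the reverse track is re-aligned by
index reversal, and the final score at each position is the absolute
maximum of the two — making the final track strand-symmetric by
construction. The per-sequence "predicted functional nucleotides" are the
top 20 % of positions (k = ⌊0.2 × L⌋ = 60 for L = 300); ties at the k-th
value resolve to the larger score, then the smaller coordinate.

## PWM scanning and FPR calibration

JASPAR-format count matrices are regularised with a pseudocount of 1 % of
each column's total (spread uniformly over the four cells), normalised to
frequencies, and converted to log₂-odds against a uniform background —
the scoring function itself (log-odds vs probability) is a package choice,
as is the background. A window of the motif's width scores as the sum of
per-position log-odds; the minus-strand score of a window is the
plus-strand score of its reverse complement.

The score cutoff is calibrated empirically, not analytically. A background
window (element-sized, default 300 bp) counts as a false positive if *any*
offset on *either* strand scores at or above the cutoff — the per-element
unit matches how elements are filtered downstream. The cutoff is the
smallest value on the grid of observed per-window best scores whose
recomputed FPR is strictly below the target (default 0.2 %); the achieved
FPR is recorded. At least `10 / target_fpr` background windows are required
(≥ 5,000 at the default) so the estimate at the cutoff rests on ≥ 10
effective counts. A target of 1.0 is vacuous and returns the minimum
observed score. In the pipeline the background set is GC-matched random
genomic windows (matching the positive GC profile, consistent with the
negative-set philosophy) drawn to exclude **all** peaks, not just the
positives — peaks below the tag threshold still carry planted motifs and
would otherwise contaminate the null distribution.

Matches are reported at every passing offset on both strands in
forward-strand coordinates; overlapping matches are all kept and the
`>= cutoff` comparison is inclusive, so the downstream functional filter
sees everything the calibration admitted.

## Functional motif calls

A match is **functional** when at least `min_overlap = 3` of its footprint
positions (forward coordinates, strand-agnostic — the importance track is
already strand-symmetric) lie inside the window's top-20 % position set.
Both clauses are asserted on every emitted call; raising `min_overlap` can
only shrink the call set.

Against planted ground truth, a functional call is a true positive iff a
truth interval of the same motif id overlaps it (optionally within a bp
tolerance; default 0); recall counts truth entries hit by at least one
functional call. An empty call set reports precision 0 with an explicit
`undefined_precision` flag rather than NaN.

## Synthetic benchmark

The generator emulates the *processed inputs* of an enhancer study — a
genome, called peaks, per-peak tag counts — with known ground truth:

* **Genome**: i.i.d. bases, GC 0.42 (mammalian-like), ten 200 kb autosomes
  plus chrX (100 kb) and chrY (50 kb) so the sex-chromosome filter is
  exercised. Coordinates are 0-based half-open throughout.
* **Peaks**: 650 active + 650 inactive non-overlapping 300 bp intervals,
  chromosomes chosen proportionally to length.
* **Tags**: negative-binomial with dispersion 10 and means 120 (active)
  vs 8 (inactive). Real ChIP-seq tag counts are overdispersed relative to
  Poisson; mean/dispersion is the minimal realistic stand-in. With these
  means the 32-tag threshold passes essentially all active and no inactive
  peaks (≈1–2 % of active peaks fall below it, a deliberate source of
  label imperfection).
* **Motifs**: each active peak receives one instance per PWM, sampled
  column-wise from the PWM's frequencies, placed at non-overlapping offsets
  on a uniformly random strand (placement by rejection, capped at 1,000
  retries, then a hard error — deterministic failure beats silent overlap).
  The two shipped matrices are *synthetic*, shaped like the TCF3 E-box
  (consensus `CAACAGCTGTTG`) and the ELK1 ETS site (`AACCGGAAGTGG`), with
  ~86–97 % dominant bases and deliberately varied column totals so that
  background best-scores do not collapse onto a few tied values (tied grid
  values coarsen empirical FPR calibration).

What passing on this benchmark shows: every contract of the pipeline —
filtering, matching, splitting, learning, conservation of attributions,
calibration soundness, and end-to-end recovery of planted signal — holds
under controlled conditions. What it does not show: performance on real
chromatin data, where enhancer grammar is combinatorial, motif instances
are degenerate and clustered, background sequence is repeat-rich and
non-i.i.d., and tag counts confound copy number and mappability. Recall on
the benchmark (≈0.6–0.7 pooled) is bounded above by construction: planted
instances are *sampled* from the PWM, so a calibrated cutoff at 0.2 % FPR
necessarily rejects the weak tail of true instances, and ~8 % of truth
lies in peaks removed by the sex-chromosome or tag filters.

## Pipeline determinism and problem sizes

One global seed derives per-stage seeds as `sha256("{seed}:{stage}") mod
2³¹`, so reconfiguring one stage never reshuffles another's randomness.
All non-training stages are bit-reproducible; training is reproducible
under single-threaded execution. The default problem sizes (1.3 k peaks,
≈1.2 k examples, 5,000 calibration windows, ≤ 50 epochs) were chosen so a
complete run finishes in about a minute on one CPU while keeping ≥ 500
examples per class and ≥ 10 expected counts behind every calibrated
cutoff; they are configuration, not hard-coded limits.

## Known limitations

* The classifier is a desk-scale stand-in: no pretraining, no multi-task
  chromatin objective, no reverse-complement augmentation (strands are
  reconciled at interpretation time instead).
* Empirical calibration only; no analytic p-values and no higher-order
  background models.
* The rescale rule is implemented for the layer set used here (conv,
  dense, max-pool, ReLU, sigmoid); other layers require the
  `grad_x_input` fallback.
* `recovery_report` matches calls to truth by interval overlap and motif
  id only; it does not score strand agreement.
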
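# funcmotif

Identify candidate **functional transcription-factor binding motifs** in
enhancer sequences by combining two orthogonal signals at single-nucleotide
resolution:

1. a **PWM match** whose log-odds score clears a cutoff calibrated to an
   empirical false-positive rate below 0.2 % on background windows, and
2. **concentrated importance** under a convolutional enhancer classifier —
   at least 3 of the match's positions must fall in the window's top-20 %
   (top 60 of 300) DeepLIFT-style importance positions.

The package is aimed at regulatory-genomics analysts who have candidate
enhancers (accessibility peaks with histone-acetylation tag counts) and
want motif calls that are supported by a sequence model rather than by PWM
score alone.

## The method in brief

A peak table is turned into a labelled dataset: positives are 300 bp
windows centred on peaks with ≥ 32 H3K27ac tags (sex chromosomes removed),
negatives are an equal number of GC-matched random genomic windows, and
splits are by chromosome (chr8 validation, chr9 test). A small CNN
(conv 32×12 → pool → conv 32×8 → global max-pool → dense → sigmoid) is
trained to separate the classes and evaluated by auROC. For each positive
window, per-nucleotide importance is computed with DeepLIFT (rescale rule,
uniform 0.25 background) for the sequence and its reverse complement, and
the final track is the absolute maximum at each aligned position. A PWM
match `m` in a window with top-importance set `T` is called functional iff

    score(m) ≥ cutoff_FPR<0.2%   and   |footprint(m) ∩ T| ≥ 3.

Everything runs offline: a synthetic-data module generates genomes, peaks,
overdispersed tag counts, and planted PWM-sampled motif instances with
known ground truth, so the whole pipeline is testable end to end. The two
shipped motif matrices are synthetic E-box (TCF3-like) and ETS (ELK1-like)
matrices in JASPAR text format (see `docs/methods.md`).

## Worked example

```python
from funcmotif.pipeline import PipelineConfig, run_end_to_end

report = run_end_to_end(PipelineConfig().with_seed(1), "run1/")
print(report["stages"]["train"]["test_auroc"])
print(report["stages"]["calibrate"])
print(report["recovery"]["pooled"])
```

prints (seed 1, default configuration):

```
0.9881
{'SYN0522.1': {'cutoff': 13.6036, 'achieved_fpr': 0.0016, 'n_background_windows': 5000},
 'SYN0028.2': {'cutoff': 13.1955, 'achieved_fpr': 0.0018, 'n_background_windows': 5000}}
{'precision': 0.9984, 'recall': 0.6392, 'f1': 0.7794, 'n_truth': 1300, 'n_calls': 1258}
```

Reading these numbers: the classifier separates active from background
windows on the held-out chromosome with auROC 0.988; the calibrated score
cutoffs (13.6 and 13.2 bits) keep the per-window false-positive rate at
0.16 % and 0.18 %, under the 0.2 % target; and of 1,300 planted motif
instances the functional calls recover 64 % at 99.8 % precision — recall
is capped by design, since instances sampled from the PWM include a weak
tail that a 0.2 %-FPR cutoff must reject (see `docs/methods.md`).

The same run from the shell, stage by stage or end to end:

```bash
funcmotif pipeline run --seed 1 --out run1/
funcmotif pipeline validate --config config.yaml
funcmotif simulate --config sim.yaml --out sim/ --seed 5
funcmotif build-dataset --genome sim/genome.fa --peaks sim/peaks.tsv --out ds/
funcmotif train --dataset ds/ --out model/
```

Outputs are plain text: FASTA genome, BED-like peak/truth/call tables,
TSV importance tracks, YAML calibration reports, and a JSON run report
whose counts match the persisted files line for line.

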
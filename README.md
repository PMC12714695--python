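# chipdeconv

Joint deconvolution and de-biasing of multi-assay histone-modification
ChIP-seq data.

## The problem

ChIP-seq coverage of a histone mark is confounded by the chromatin
landscape of the sample itself: sonication, cross-linking and mappability
all favour accessible chromatin, so treatment and input-control tracks are
strongly correlated even where the mark is absent.  Input controls are
usually too shallow to correct this bin by bin.  When several marks are
measured on the *same* sample, however, they all share one chromatin bias
— and that sharing can be exploited.

`chipdeconv` models binned coverage multiplicatively: a control replicate
has expectation `D·a·m·n` and a treatment replicate for mark *h* has
`D·a·m·(k·s_h + n)`, where `a` is accessibility, `m` mappability, `n`
non-specific signal, `s_h` the true enrichment, `D` sequencing depth and
`k` antibody specificity.  Three steps recover `s_h`:

1. **Constrained KL-NMF** factorizes all samples jointly into one signal
   column per condition plus a shared chromatin-bias column `x = a·m·n`,
   staged (control-only fit → background coefficients → residual signal
   fit → relaxed alternating refinement) so the decomposition keeps its
   interpretation.  The mixing matrix absorbs `D` and `k`; its background
   row is a per-sample antibody-quality readout.
2. **Half-sibling regression** removes the remaining `a·m` confounder:
   `log ŝ_h = log y_h − E[log y_h | log x]`, the expectation fitted by
   OLS, the divisor floored at 0.1 so amplification is capped at 10×.
3. **Peak calling** thresholds the resulting fold-change track, merging
   nearby regions and dropping tiny ones (no p-values, so no
   multiple-testing burden).

A generative simulator reproduces the observation model exactly — Markov
genome layout with fixed state lengths (background 1000 bp, narrow 450 bp,
broad 1200 bp, random 750 bp), smooth latent bias processes, Poisson
counts — so the whole pipeline is testable against known ground truth
without downloading anything.  See `docs/methods.md` for the full model
description.

## Worked example

```python
import numpy as np
from chipdeconv import (FactorizationConfig, call_regions, debias_signal,
                        deconvolve, evaluate_regions, simulate_experiment)

truth, tracks = simulate_experiment(seed=11)     # 3 marks x 3 reps + 2 controls, 1 Mb
result = deconvolve(tracks, FactorizationConfig(n_train_bins=5000), seed=11)
x = result.bias                                  # learned chromatin bias
r = np.corrcoef(np.log(x[x > 0]), np.log(truth.bias[x > 0]))[0, 1]

s_hat, _, fit = debias_signal(result.signal("narrow_mark"), x)
regions = call_regions(s_hat, tracks.bins, threshold=2.0)
f1 = evaluate_regions(regions, truth.peak_regions("narrow_mark"), tracks.bins)["f1"]
```

Running `examples/03_debias_and_call_peaks.py` (which does the above for
all three marks) prints:

```
narrow_mark  slope= 0.63  corr(fc, bias)= 0.049 (raw 0.256)  peaks=110  F1=0.981
broad_mark   slope= 0.81  corr(fc, bias)= 0.058 (raw 0.290)  peaks=124  F1=0.978
random_mark  slope= 0.84  corr(fc, bias)= 0.102 (raw 0.296)  peaks=123  F1=0.976
```

Raw treatment coverage correlates ~0.26–0.30 with the chromatin bias; the
de-biased fold-change tracks drop to ~0.05–0.10 while recovering the true
peak sets at F1 ≈ 0.98.  The learned bias itself matches the simulated
`a·m·n` at Pearson r ≈ 0.94 (log scale).

## Command line

```bash
chipdeconv simulate  --outdir sim --seed 7          # synthetic experiment + truth
chipdeconv preprocess --sample-sheet sheet.csv --chrom-sizes sizes.tsv \
                      --blacklist blacklist.bed    # BAM/bedGraph -> binned matrix
chipdeconv run --simulate --seed 7 --outdir out    # full pipeline + manifest
chipdeconv diagnose --mixing-matrix out/deconvolution/mixing_matrix.csv
chipdeconv call-peaks --foldchange fc.bedgraph --chrom-sizes sizes.tsv
```

The sample sheet is a CSV with header
`filepath,condition,is_control,replicate`.  All genomic I/O is plain-text
bedGraph/BED (0-based, half-open); every run writes a JSON manifest with
content hashes, and a re-run with the same seed reproduces them exactly.
The `examples/` directory holds one short narrative script per capability.

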
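# Methods

## The observation model

ChIP-seq coverage of a histone modification is confounded by the chromatin
landscape of the sample itself: sonication and cross-linking favour
accessible chromatin, and alignability varies along the genome.  We model
binned coverage multiplicatively.  For genomic bin *b*, a control (input)
replicate *r* has expected coverage

    c_b^(r) = D^(r) · a_b · m_b · n_b

and a treatment replicate for mark *h* has

    t_{h,b}^(r) = D_h^(r) · a_b · m_b · (k_h^(r) · s_{h,b} + n_b)

where `a` is chromatin accessibility, `m` mappability, `n` any remaining
non-specific signal, `s_h` the latent mark-specific enrichment we want,
`D` a per-sample sequencing-depth factor and `k` the antibody-specificity
factor of that replicate.  The product `x = a·m·n` is the *chromatin
bias*: it is what the input control measures, and it contaminates every
treatment track through the additive `n_b` term and the multiplicative
`a·m` factor.

Estimation proceeds in two steps: a constrained non-negative matrix
factorization (NMF) removes the additive background and pools replicates,
and half-sibling regression (HSR) then removes the multiplicative `a·m`
confounder from each mark's signal.

## Preprocessing

Input is an indexed BAM (or pre-binned bedGraph) per sample plus a CSV
sample sheet (`filepath,condition,is_control,replicate`).  Reads failing
vendor QC, duplicates, secondary/supplementary and unmapped records are
excluded; upstream trimming/alignment/duplicate marking is assumed done.

- **Fragment length** is estimated once per treatment condition as the
  shift in 50–500 bp maximizing the Pearson cross-correlation between
  plus- and minus-strand 5′-end profiles (pooled over replicates and
  chromosomes).  The control condition uses the median of the treatment
  estimates.  The 50–500 bp window brackets typical sonication fragment
  sizes while excluding the read-length phantom peak.
- **Extension**: treatment reads are extended 5′→3′ to the fragment
  length; control reads grow symmetrically about their midpoint (a control
  fragment has no directional pull-down).  Intervals are clipped at
  chromosome ends.
- **Library normalization**: each read carries weight `25·10⁶ / N_reads`,
  so every sample's weighted total is exactly 25 million reads.  Weighting
  (rather than subsampling) keeps the result deterministic.  The library
  size is the retained-alignment count before extension.
- **Binning**: average weighted coverage over contiguous, non-overlapping
  200-bp bins (0-based, half-open); a chromosome's final short bin is
  averaged over its true width.  Binning conserves mass: Σ value·width
  equals total weighted extended-read length up to end clipping.
- **Blacklist**: any bin overlapping a blacklist interval by ≥1 bp is
  dropped from all samples (conservative and deterministic); the retained
  bin index keeps coordinates round-trippable.

## Staged constrained KL-NMF

The G×N matrix V (columns: controls first, then treatments grouped by
condition) is factorized as V ≈ W·K with W ≥ 0 (G×l), K ≥ 0 (l×N) and
l = number of experimental conditions.  W's last column is the chromatin
bias `x`; the others are per-condition signals `y_h = a·m·s_h`.  All fits
minimize generalized KL divergence with L2 penalties — λ_W = 0.01 on W,
λ_K = 0.001 on K — using multiplicative updates with the penalty folded
into the denominator (`W ← W ⊙ ((V/WK)Kᵀ) / (ΣK + 2λ_W W)`), which keeps
iterates non-negative and the penalized loss non-increasing.

Unconstrained NMF would happily mix background into signal columns.  The
factorization is therefore staged:

1. **Control stage** — rank-1 NMF of the control block learns `x` and the
   control coefficients.  Initialization is deterministic (mean control
   column), so results do not depend on a random init.
2. **Background coefficients** — with `x` fixed, each treatment column
   gets the scalar β ≥ 0 minimizing KL(V_j ‖ βx) + λ_K β².  The
   stationarity condition is the quadratic 2λβ² + (Σx)β − ΣV = 0, solved
   in closed form (β = ΣV/Σx when λ = 0).  This deliberately explains as
   much of each treatment as possible with background alone.
3. **Specific stage** — the residual max(V_j − βx, 0) of each condition's
   replicates is factorized rank-1 into `y_h` and per-replicate
   coefficients.  Clipping at zero is required for NMF input and discards
   only noise-driven negative residuals.
4. **Relaxation** — the block structure of K is freed and W, K are
   jointly refined by alternating multiplicative updates.  Multiplicative
   updates cannot leave an exact zero, so blocked-out K entries are
   re-seeded at 1% of the mean positive K entry (and zero W entries at a
   much smaller floor) before optimization.  Stopping: relative loss
   improvement < 1e-6 or 500 iterations per stage.  A loss increase beyond
   slack aborts with diagnostics.

The mixing matrix is learned on a uniform subsample of training bins —
100,000 by default, 400,000 for deeply sequenced real data (restricted to
bins with mean coverage > 1), 5,000 for the simulated genomes used here
(no coverage threshold; simulated bins are never empty in practice).  K is
then fixed and W is solved genome-wide: with K fixed the penalized KL
objective is convex and separable per bin, so rows are solved
independently with per-row stopping — the result is independent of how
the genome is chunked (to floating-point associativity).

Finally each W column is rescaled so its 98th percentile equals 1, with
the inverse factor pushed into the matching K row; W·K is unchanged and
the per-sample depth factors `D` concentrate in K.  The 98th percentile
(not the max) avoids outlier domination.  `D` and `k` are not separated;
they live jointly in K's entries.  The background row of K, as a fraction
of each sample's total weight, is the antibody-quality diagnostic:
controls sit near 1, well-enriched ChIP samples well below.

## Half-sibling regression

Assuming the true enrichment s_h is independent of the chromatin bias x,
the confounder's effect on y_h is removed in log scale:

    log ŝ_h = log y_h − E[log y_h | log x]

with the conditional expectation fitted by OLS of log y on log x.  The fit
uses only bins with y > 0 and x > 0 (no pseudocount — the bound below
handles zeros at prediction time), restricted to the NMF training bins for
consistency and speed, and is applied genome-wide.  In linear scale this
divides y by the fitted divisor, i.e. a fold-change.  The divisor is
floored at 0.1 (bins with x = 0 use the floor directly), so the signal is
amplified at most 10-fold where the predicted background is essentially
zero.  Natural logs are used internally; the floor and cap are
linear-scale quantities, so the base is immaterial.  A constant x
degenerates to division by the geometric mean of y.

## Peak calling

Maximal runs of bins with fold-change ≥ threshold become candidate
regions; regions separated by ≤ merge_gap are merged (runs never bridge
chromosome boundaries or blacklisted gaps beyond the merge gap) and
regions narrower than min_width are dropped.  No significance test is
performed, hence no multiple-testing correction.  Defaults — threshold 2,
merge gap 2 bins, minimum width 2 bins (5 suggested for broad marks) —
are pragmatic choices, all overridable.  Raising the threshold never
increases the total called bases.

## The simulator

The simulator emits exactly the observation model above, so every latent
quantity is known.

- **Layout**: a run-length Markov chain over background and three peak
  states.  Run lengths are fixed per state — background 1000 bp, narrow
  450 bp, broad 1200 bp, randomly-placed 750 bp — so every peak has its
  exact configured length (stated as single values, not expectations).
  After background the chain stays in background with probability 1/2 or
  picks a peak type uniformly; after a peak it always returns to
  background.  This yields per-mark enrichment of roughly 5–15% of the
  genome, the regime typical of narrow plus broad histone marks.  A peak
  that would overrun the genome end is replaced by background fill.
- **Latents**: log a and log n are stationary AR(1) processes (defaults:
  sd 0.3 with lag-1 autocorrelation 0.95 for accessibility — smooth — and
  0.8 for non-specific signal); m = 1 − 0.5·Beta(1,5), i.i.d. in
  (0.5, 1] — rough, as mappability is.  Setting the sd/range parameters
  to 0 gives the pure-signal limit a = m = n = 1.  Peak amplitudes are
  per-occurrence log-normal around the mark's strength (narrow 8, broad
  4, random 5 — narrow marks are taller; all in fold units against the
  mean-1 non-specific level), spread over bins by the bin/peak overlap
  fraction, giving flat tops with one-bin linear shoulders.
- **Samples**: default design is 3 marks × 3 replicates + 2 controls.
  Depth factors D jitter log-normally (sd 0.15) around a base depth of 20
  expected control reads per bin — a 1 Mb genome at realistic coverage;
  specificity factors k jitter similarly around 1.
- **Noise**: Poisson by default; negative-binomial (gamma–Poisson) and
  noiseless modes are available.  All randomness flows from one seed
  through spawned generators; identical seeds give identical output.

What the simulator does *not* emulate: read-level sequences and
sequencing error, GC bias, copy-number variation, chromatin-state
correlation between marks, or irregular peak shapes.  Passing tests
therefore demonstrate correct inference *under the model's own
assumptions* — independence of s_h and x, multiplicative bias, additive
background — not robustness to real-data violations of them.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 1 Mb / 5,000-bin design
(about 2 s per seed for the full pipeline) and a 10 Mb / 50,000-bin
simulation for the rescaling check; these sizes give stable correlation
and F1 estimates while keeping the suite fast.  Numerical guards: division
floors at 1e-12 inside multiplicative updates; KL terms with V = 0
contribute only their reconstruction mass; all-zero bins yield all-zero W
rows; an all-zero control block or bias vector is an error rather than a
silent degenerate fit.

## Known limitations

- Treatment-only designs (no control sample) can be preprocessed but not
  deconvolved; the model is built around a shared control.
- The HSR step assumes a single global log-linear relation between each
  signal and the bias; locally varying confounding is not modelled.
- The mixing-matrix diagnostic is qualitative: K entries conflate depth
  and specificity, so only within-experiment comparisons are meaningful.
- Peak-calling defaults are heuristics; for broad marks the minimum width
  should be raised.
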
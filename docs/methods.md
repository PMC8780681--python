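# Methods

## Assay model

The pipeline analyzes targeted paired-end sequencing of cfDNA in a
panel of open-chromatin regions. Library construction (not part of this
package) ligates a UMI-carrying universal adapter to each cfDNA
molecule and amplifies from one gene-specific primer per region, so
read 2 of every proper pair starts at the primer and read 1 starts at
the preserved, biology-determined fragment end. Everything downstream
rests on two observables per molecule:

- the **relative end position**: the offset of read 1's alignment start
  (`+` primers) or end (`-` primers) from the primer anchor, measured
  in the primer-extension direction; support is fixed to 0–300 bp and
  positions outside it are tallied and dropped;
- the **end dinucleotide**: the first two bases of the fragment at its
  preserved end, read 5'→3' on the fragment's own strand.

## Preprocessing

A read pair is retained iff (i) it is flagged a proper pair, (ii) both
mates have MAPQ ≥ 30 (default), and (iii) read 2 covers the primer's
3'-terminal base. The primer-overlap rule is deliberately the coverage
of the extension-start base rather than any-1-bp overlap with the
primer interval: every genuine extension product must contain the 3'
terminus, while a loose overlap rule admits unrelated fragments ending
inside the primer site.

PCR duplicates are collapsed by UMI **within each (sample, region, end
position) group** — identical UMIs at different end positions are
different molecules by construction of the assay. Two modes:

- `exact` (default): one molecule per distinct UMI string. Fully
  deterministic; correct when UMI reads are error-free.
- `directional`: UMIs at Hamming distance ≤ 1 (configurable) are linked
  when the more abundant has ≥ 2·count(less) − 1 supporting reads, and
  each connected component collapses to its most abundant UMI
  (lexicographically smallest on ties). This is the standard
  count-ratio network rule for absorbing sequencing-error satellite
  UMIs; it trades a small risk of over-merging for robustness to UMI
  errors.

Deduplication here happens after alignment, using positions as part of
the grouping key. Pre-alignment UMI clustering would collapse the same
read families for this assay, since family members share both UMI and
fragment coordinates.

## Fragmentation score

Per region, the pooled **training-split** end profile is smoothed with
a centered moving average (half-width 2 bp, edge windows shrink) and
the most prominent peak is taken in each window: Peak1 = argmax over
0–99 bp, Peak2 = argmax over 100–300 bp, ties toward the smaller
position. Peak positions are then frozen and applied unchanged to test
samples — freezing on the training split only avoids the leakage that
pooling all samples would introduce into downstream evaluation.

The per-sample score is FS = log2((c₁+ε)/(c₂+ε)) with c₁, c₂ the
molecule counts in ±5 bp windows (clipped to the support) around the
frozen peaks and ε = 0.5 (a Jeffreys-style half count, making FS finite
and 0 for empty profiles). Windowed exact counts are used instead of a
kernel density estimate: they are exact, fast, and oracle-checkable,
and the score is a ratio statistic so the common normalization cancels.
"Normalization" of FS across samples is realized as per-feature
standardization inside the classifier using training-set statistics;
no separate normalization formula is applied at the feature level.

Features per sample: one raw FS per region (columns sorted by region
id) plus the 16 dinucleotide end-motif frequencies (lexicographic
order, NN-ambiguous records excluded from the denominator; an all-NN
sample falls back to the uniform vector with a warning). The feature
assembly uses a vectorized windowed-count path that is asserted in the
test suite to agree exactly with the per-profile score computation.

## Classifier

SVM with hyperparameters selected on mean out-of-fold ROC AUC under
repeated stratified CV (default 10 repeats × 10 folds, stratified by
class only — stage is not known at training time in deployment). The
default grid is kernel ∈ {linear, RBF} × C ∈ {0.01, 0.1, 1, 10, 100},
with RBF gamma = m·(n_features·var)⁻¹ for m ∈ {0.1, 1, 10}. The scaler
is re-fit inside every fold. Exact AUC ties resolve to the earlier grid
entry; the grid is ordered linear-before-RBF, then ascending C, then
ascending gamma, so ties prefer the simpler model. AUC itself is
computed by the rank (Mann–Whitney) formulation with ties counted 1/2;
the test suite checks it against an O(n²) pairwise oracle.

The winning configuration is refit on the full training set. Its
decision values are mapped to probabilities by a Platt sigmoid
(logistic regression with negligible regularization) fitted on
out-of-fold decision values from a single stratified 10-fold pass —
fitting on out-of-fold values avoids the optimistic calibration that
in-sample decision values would give. The calibrated probability is the
**cancer score**; predicted class is cancer at score ≥ 0.5.

Batch is recorded in metadata and reportable but is not used as a
feature or correction by default. Degenerate cases: single-class CV
folds are skipped and counted; constant feature columns pass through
the scaler with unit scale (zero-variance guard).

Evaluation reports overall and stratified AUC/accuracy: early-stage
(I, II) and late-stage (III, IV) cancers, and each cancer type, always
against all healthy samples as the negative class; plus per-group score
medians and SDs. Empty strata are reported as `null` with their n.

## Synthetic cohorts

The simulator generates the structure the analysis assumes, with
defaults mirroring the emulated study design: 96 regions, 60 healthy +
115 cancer samples (COAD : RCC ≈ 58 : 57) in batches of 116 and 59,
uniform stage distribution over I–IV (the real composition is not
modeled), and a train/test split that yields 52 test samples.

Per region, end positions are drawn from
w₁·N(μ₁,σ₁) + w₂·N(μ₂,σ₂) + b·U[0,300], rounded and clipped to
integer bp. Region parameters are drawn once per cohort: μ₁ ~ U[30,80],
μ₂ ~ U[130,260], σ₁ ~ U[5,10], σ₂ ~ U[8,16], w₁ ~ U[0.35,0.55],
background b = 0.05. The spreads are those of sharp cleavage hotspots
at nucleosome boundaries — narrow enough that peak modes are
identifiable to ±3 bp at assay depth (several thousand pooled molecules
per region), which is the regime the peak-freezing step is designed
for; broader, flatter peaks would make single-bp peak positions
ill-defined.

Cancer is planted as (i) w₁ → clip(w₁ + δ, 0, 1−b) at a random subset
of informative regions (default 24 of 96, δ = 0.25) — a mixture-weight
shift rather than a mode shift, because FS is a density-ratio statistic
— optionally scaled per stage for stage-effect studies; and (ii) a
+0.05 shift of the CC end-motif frequency (remaining motifs rescaled
proportionally). Healthy motif frequencies are a plausible plasma
profile with CC most frequent (0.101). Molecule counts per
sample-region are negative-binomial (default mean 100, dispersion 10);
PCR emits each molecule 1+Poisson(2) times with a 10-base UMI,
optionally corrupted per base. An optional per-batch additive motif
shift exists and is off by default.

All draws flow from one seed; identical configs give byte-identical
output files. What the simulator does **not** emulate: GC and
amplification bias, off-target reads, alignment error, sample
contamination, real stage composition, inter-region correlation, and
any batch effect on fragmentation (only motifs can be batch-shifted).
Passing tests therefore demonstrate that the pipeline recovers the
signal it is designed for when present, and stays at chance when
absent — not clinical performance on patient cfDNA.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale cohorts chosen for statistical
power at interactive runtimes: full-size default cohorts (175 samples ×
96 regions × ~100 molecules) for signal recovery, 20 full null cohorts
at reduced depth (60 molecules/region; null calibration is
depth-insensitive) for calibration, 100 regions × 20k pooled molecules
for peak recovery, and a small 8-sample cohort for the exact UMI-dedup
check. The acceptance script mirrors these but with 5 null cohorts.

Numerical conventions: all genomic coordinates 0-based half-open (BED);
relative positions inclusive in [0, 300]; peak search windows [0, 99]
and [100, 300] inclusive; argmax ties toward smaller positions; UMI
component ties toward lexicographically smaller UMIs; region selection
(target score minus best off-target score) breaks ties by higher target
score then peak id. Every such tie-break makes the corresponding
operation order-invariant and deterministic.

## Known limitations

- The directional UMI rule can over-merge when two true molecules at
  the same position carry UMIs at distance 1 with skewed counts; exact
  mode is the default for this reason.
- Peak freezing assumes unimodal-per-window pooled profiles; secondary
  peaks of nearly equal height make the frozen position sensitive to
  sampling noise (mitigated, not removed, by smoothing).
- Platt calibration with ~120 training samples yields scores whose
  ranking is reliable but whose absolute probabilities are coarse.
- The classifier is binary (cancer vs. healthy); tissue-of-origin
  (COAD vs. RCC) classification is out of scope.
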
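# Methods

This note documents the models and procedures implemented in `miaa`, the
defaults and the reasoning behind them, and what the synthetic-data tests do
and do not establish about real assay data.

## The assay readout and its processing

A MIAA library member is scored by the proportion of DpnII reads among the
DpnI+DpnII digest pair, computed from reads-per-million (RPM) normalized
counts: `openness = DpnII_rpm / (DpnI_rpm + DpnII_rpm)`. Normalization is
per (condition, replicate, digest) — each digest is a separately sequenced
pool, so library-size correction must happen within the digest before the
two digests are compared. The proportion is computed per replicate from RPM,
not raw counts, and replicate proportions are averaged only at the
statistics layer (one value per background and condition).

Reads are assigned by exact match: the reverse complement of each read is
truncated to the variable-sequence length and looked up against the library.
No mismatch tolerance is applied; with synthesized libraries the match is
either perfect or ambiguous, and mismatch tolerance would silently merge
shuffled controls with near-identical composition. Duplicate variable
sequences in a library are rejected as unassignable.

Sequences with low total RPM across all replicates and digests are removed
before analysis, because the proportion estimator has high variance at low
totals. The threshold is an explicit parameter (default 0, i.e. keep all);
`readproc.coverage_diagnostic` tabulates the SD of the proportion by
total-RPM bin so users can place the threshold where the variance stops
inflating, rather than relying on a hard-coded value.

## Generative model of the synthetic data

The simulator draws counts from an explicit openness model so every
downstream stage can be tested against recorded truth:

```
p(s, c, r) = floor + (ceiling − floor) ·
             logistic( gc_slope_c · (GC(s) − 0.5)
                       + Σ_m effect(m, c) · copies(m, s)
                       + b(c, r) )
```

* `floor` (default 0.2) — residual methylation of closed chromatin.
  Accessibility-neutral sequences in this kind of assay are still methylated
  at roughly 20–50%, and closed native loci sit near 20%.
* `ceiling` (default 0.95) — methylation of fully open chromatin, matching
  the 85–95% seen at strong activator binding sites.
* `gc_slope_c` — per-condition logit slope on GC fraction, centered at 0.5
  so a 50%-GC background sits at the model midpoint. GC content is a real,
  condition-dependent driver of accessibility and is the main confounder the
  shuffled controls and the regression's GC term exist to absorb.
* `effect(m, c)` — additive logit effect per placed copy of motif `m` in
  condition `c`. Packed designs carry 7 copies, so per-copy effects ≥ 0.5
  saturate openness toward the ceiling; this matches the qualitative
  behaviour of strong motifs in the assay.
* `b(c, r) ~ N(0, replicate_sd)` — a batch effect drawn once per
  (condition, replicate) and shared across sequences, the structure the
  regression's replicate indicators absorb.

Counts: per-sequence abundance is Gamma with mean 1 and shape
`1/dispersion` (default dispersion 0.25), and digest counts are Poisson
with means `abundance·depth·p` and `abundance·depth·(1−p)`. This
Gamma–Poisson mixture gives the overdispersion typical of sequencing counts
while keeping the mean structure analyzable (expected total reads per
sequence and digest pair equal `abundance·depth` regardless of openness).
The dispersion default is a placeholder chosen for test power, not an
estimate from real data, which does not report one.

The truth sidecar records the replicate-noise-free `p(s, c)` per sequence
and condition; oracles correlate estimates against it.

**What the generator does not emulate:** PCR amplification bias, sequencing
errors, integration-efficiency variation, position effects within the
locus, or saturation of Dam methylation kinetics. Passing tests establish
that the pipeline recovers parameters *of this generative family*; on real
data the same estimators face additional noise sources the simulation does
not represent.

The four-class labeled training sets plant exact motif instances (DE-only,
ESC-only, shared, none) at uniform positions in motif-free random
backgrounds. Real accessible regions differ in essentially every way that
matters for difficulty: degenerate motifs, correlated composition,
multiple interacting sites. CNN results on these sets demonstrate correct
mechanics (learning, calibration of null AUROC at 0.5, saliency
localization), not genomic performance.

## Library design conventions

* Positions are 1-based inclusive everywhere, including file output.
* Motif insertion overwrites background characters, preserving length —
  forced by fixed position lists combined with fixed-length output.
* Only one strand/orientation is designed.
* Spacing between motifs in an arrangement is the gap in nt from the last
  base of one motif to the first base of the next; the motif block is
  centered in the background (`floor((L − span)/2) + 1`).
* IUPAC ambiguity codes are resolved uniformly at random (seeded) at design
  time, since synthesis oligos must be concrete.
* Background perturbation substitutes exactly `ceil(rate·length)` positions
  (default rate 0.1) and rejection-samples against a forbidden-motif list
  (e.g. GATC, which would create spurious Dam substrates); the standard
  panel is 6 natives plus 3 perturbations each, 24 total.
* Chained packing extends greedily by the highest-scoring motif whose first
  `overlap` (default 4) bases match the current suffix; score ties break
  lexicographically by motif id.
* Oligo assembly enforces 25-nt arms with GATC starting at the second base
  of the 3′ arm — one neutral base downstream of the variable sequence.

## Two-stage differential testing

A motif is called differentially accessible only if it passes both:

1. **Condition stage** — a paired two-sided test (paired t by default,
   Wilcoxon signed-rank as the agreement check) of per-background mean
   openness between the two conditions. The pairing unit is the background
   (up to 24 pairs), with replicates averaged per (background, condition)
   first; this sidesteps the unequal replicate structure (8 ESC vs 4 DE)
   without weighting assumptions.
2. **Shuffle stage** — the same paired test of designs against their
   nucleotide-shuffled controls within each condition, separating motif
   content from composition.

BH correction is applied within each stage's family separately (one family
per stage and test type), and the differential call requires rejection in
stage 1 AND in at least one condition of stage 2. Degenerate inputs
(all-zero differences) return p = 1 rather than NaN; zero-variance nonzero
differences return p = 0 (the t statistic diverges). Rejection uses
q < FDR.

Calibration: with 24 paired null observations the paired t is exact at the
nominal level; the exact signed-rank test at n = 24 has an attainable level
of 0.0491 at the 0.05 cut (discreteness), and the rank-sum test at
n = 50 + 50 uses the continuity-corrected normal approximation. All three
sit within 0.05 ± 0.006 over 10,000 null simulations.

## Motif-effect regression

Observations are per (sequence, condition, replicate) proportions; features
are intercept, GC fraction, replicate indicators (condition-specific
levels, reference dropped), and one indicator per (motif unit × condition).
Motif membership comes from design metadata, never from rescanning
sequences — scanning could spuriously match shuffled controls, whose rows
must be exactly zero in the motif block (they also break the collinearity
between the intercept and the motif indicators). The response is the raw
proportion; a logit transform is available but not default, since the
proportion scale is where the assay's effect sizes are reported.

Train/test splits are grouped at the sequence level so test correlation
measures generalization to unseen sequences. Fits are OLS; nested models
are compared by partial F test alongside the adjusted-R² difference.
Motif-weight clustering is agglomerative (Euclidean distance, average
linkage) on each motif's vector of per-condition coefficients, processed in
sorted unit order for input-order invariance. Overexpression response is
the coefficient difference between the overexpression condition and
baseline, with a z-test from the OLS coefficient covariance
(`var(Δ) = var_a + var_b − 2cov_ab`), BH-corrected within the motif family.

## CNN ensemble

Ten members: eight single-conv networks spanning filter width
{5, 9, 13, 17} × filter count {32, 64}, one two-layer conv network, and one
linear model with no hidden layer (flatten → dense). All end in a 2-unit
sigmoid output (P(open in ESC), P(open in DE)) trained with per-task binary
cross-entropy, Adam (default lr 5e-3, 6 epochs, batch 128), fully seeded.
The ensemble prediction is the unweighted mean of member probabilities. The
layer stack (valid-mode conv1d via strided windows, ReLU, global max pool,
dense) is implemented directly on NumPy with hand-written backpropagation,
which also supplies the input gradients that saliency needs; at the scales
used here (≤ 40k sequences of 100 nt) training is minutes on one CPU.

Saliency targets the **logit difference** `z_DE − z_ESC` rather than the
probability difference: the gradient of a linear member is then its weight
matrix exactly, giving a closed-form correctness check, and the logit scale
avoids sigmoid-saturation shrinkage of gradients on confident sequences.
Smoothed gradients average over 25 Gaussian perturbations (sd 0.1 on the
one-hot scale) by default, are multiplied elementwise by the one-hot input
(gradients assign weight to absent bases otherwise), and averaged across
members with uniform weights (held-out-AUROC weighting available).

Window extraction slides a width-10 window over per-position saliency
(sum over the base axis), ranks all windows globally, greedily skips
windows overlapping a higher-scoring window in the same sequence, breaks
ties by (sequence index, start), and aggregates identical selected strings
(support = occurrences, score = mean). Saliency *gain* ranks windows by
deep-member minus linear-member saliency, flagging motifs whose importance
comes from learned context rather than additive content.

`predicted_motif_effect` groups designs by motif content and reports the
mean of (p_DE − p_ESC) across backgrounds — the same estimator as the
measured stage-1 effect, so predicted and measured effects correlate
directly.

## Problem sizes and tolerances used in the test suite

Simulated recovery experiments use 24 backgrounds × 12 motifs (half with
planted condition-specific per-copy effects of 0.5–1.0 logit, half null) at
depth 500 with 8+4 replicates; calibration uses 10,000 null trials; CNN
checks train the full ten-member ensemble on 8,000 sequences (2,000 per
class) and require per-task held-out AUROC > 0.9, ≥ 80% of the top-20
saliency windows containing the planted differential motif, and agreement
of the linear member's saliency with its analytic gradient to 1e-5 relative
error. These sizes were chosen as the smallest at which the statistical
claims have adequate power.

## Known limitations

* The simulator's noise model is Gamma–Poisson with a single dispersion;
  real digest counts may have digest-specific dispersion and correlated
  replicates.
* The regression treats motif presence as a binary indicator (no dosage
  term for copy number, no motif×motif interactions), matching the effect
  definition it estimates but blind to sub-additive packing effects.
* BH family boundaries (per stage and test type) are a convention; joint
  correction across stages would be slightly more conservative.
* The CNN ensemble is sized for desk-scale synthetic data; genome-scale
  training (hundreds of thousands of regions) would need a GPU framework
  and real DNase-seq labels, both out of scope.
* Only exact motif matches are planted and scanned in the synthetic data;
  degenerate (IUPAC) motif effects are supported in design but the CNN
  recovery tests use concrete instances.
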
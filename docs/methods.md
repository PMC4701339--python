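# Methods

This note records the models, conventions and design choices behind
`fallgrf`, in the order the pipeline applies them.

## Preprocessing and sample entropy

Each GRF series is divided by `weight_kg × g` (g = 9.81 m/s²) and then
z-scored with the **population** SD (divisor N). The divisor choice is
irrelevant at the series lengths used but is pinned so the exact-count
oracle tests are well defined. Because standardization absorbs any affine
rescaling, weight normalization cannot change the entropy features; the test
suite asserts this as a regression guard, and the step is kept because the
intermediate body-weight-unit series are the physically meaningful ones.

Sample entropy uses the Richman–Moorman conventions: Chebyshev distance
between embedded templates, tolerance `r` applied to the standardized series
(so `r = 0.25` means 0.25 SD), no self-matches, and **both** the length-m
count B and the length-(m+1) count A taken over the same `N − m` templates.
`A = 0` or `B = 0` yields an explicit NaN sentinel rather than infinity;
feature extraction converts that sentinel into an error naming the channel.
Defaults `m = 2`, `r = 0.25`.

One consequence of the shared `N − m` template set is worth recording: the
B count omits the final length-m window, so reversing a series drops the
*opposite* boundary window and B may differ by a few boundary pairs (A is
exactly reversal-invariant, as is the length-m count over the full window
set). SampEn is therefore reversal-invariant only up to a boundary term that
vanishes with series length; the tests assert the exact symmetries.

Subjects with several trials of one channel can be summarized either by
averaging per-trial entropies (default; robust to inter-trial offsets) or by
concatenating raw trials before preprocessing (introduces one artificial
junction template per boundary). Synthetic cohorts have one trial per
channel, where the modes coincide.

## Classifiers

LMKNN, PNN and LMPNN are implemented exactly as their defining equations:
per class, the k nearest neighbours by Euclidean distance (k truncated to
the class size — reachable under LOOCV on small cohorts), then respectively
the distance to the local mean, the 1/j-weighted distance sum, and the
1/j-weighted sum of distances to cumulative local means. Weights are exactly
1/j, not normalized to sum to one. Two deterministic tie-breaks are our
convention (the source equations are silent): equal neighbour distances
resolve by training-row index (stable sort), and equal class scores resolve
toward the earlier class in the declared order — faller first, so ambiguity
fails toward sensitivity. At k = 1 all three rules provably collapse to
per-class nearest neighbour; the suite checks this and transliterated-
equation agreement to 1e-12.

## Evaluation and subset selection

LOOCV holds out each subject once; the n held-out predictions form one
confusion matrix with faller as the positive class, from which
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
Zero denominators give NaN, which ranks below any defined value during
selection. All 255 nonempty subsets are enumerated (ascending cardinality,
lexicographic within) for every classifier and k; the default k sweep is
1..min(10, smallest class size − 1). Selection is a total order:
sensitivity, accuracy, specificity, fewer features, lexicographically
smaller mask, smaller k — the first two stages are the published rule, the
rest are determinism conventions. When several k values tie on the winning
subset's metrics, all are reported. `full_search` uses a vectorized LOOCV
path that scores all rules and all k in one pass per subset; its
decision-level equivalence with the per-fold estimator route is asserted on
random data.

## Statistics

Group differences use the two-sided Wilcoxon rank-sum test: the exact null
when both groups have ≤ 10 tie-free observations, otherwise the
tie-corrected normal approximation (scipy's `mannwhitneyu` stands behind
this operation). Significance is flagged at α = 0.1 — the exploratory
threshold of the source analysis — with no multiple-testing correction by
default (Bonferroni/Benjamini-Hochberg are available but off). Association
uses Spearman rank correlation with mid-ranks and t-approximation p-values.
The published magnitude thresholds are typographically garbled in their
source; they are implemented as half-open intervals so every |r| receives
exactly one bucket: high [0.50, 1], moderate [0.30, 0.50), weak
[0.10, 0.30), negligible [0, 0.10). An all-tied comparison is reported as
degenerate (NaN p, not significant) rather than raising.

## Synthetic cohorts

The generator emulates only what the analysis consumes: the per-channel,
per-group distribution of sample entropy. Each channel is a MIX(p) series —
`x_t = (1−z_t)·sin(2πt/period) + z_t·e_t`, `z_t ~ Bernoulli(p)`, `e_t`
uniform with unit variance — whose SampEn rises monotonically from the
sinusoid floor to the white-noise ceiling (≈ 1.98 at m = 2, r = 0.25,
N = 1000).

- **Period = 8 samples/cycle.** The sampled phases of an 8-sample sinusoid
  are spaced more than r apart after standardization, so every template
  match extends and the p = 0 floor is exactly 0; coarser-grained periods
  near 12 leave near-coincident phase pairs inside the tolerance and a floor
  around 0.29, which would put the sit-to-stand targets (≈ 0.09–0.13) out
  of reach.
- **Series length 1000** (default): long enough that SampEn's realization SD
  is ≈ 0.02 at mid-range p, short enough for fast tests. Sampling frequency
  and stride counts are not modelled at all.
- **Calibration.** A seeded 17-point curve of mean SampEn vs p (12
  realizations per point, common random numbers, forced monotone) is
  inverted by interpolation. Per subject and channel, entropy targets are
  drawn from a latent Gaussian, *exactly* re-standardized to the group
  target mean/SD (removing the draw's sampling error, so realized group
  means track targets to within curve-inversion error plus realization
  noise — well inside ±0.05 at n = 100/group), clipped to the achievable
  range, and mapped through the curve. `calibrate_irregularity` exposes the
  same calibration as monotone bisection with a ±0.05 tolerance.
- **Correlation structure.** The latent draws of (L_SI_F, R_ML_F) and
  (L_V_F, R_V_F) share a correlation of 0.5, qualitatively reproducing the
  published cross-feature association; exact r values are not targets.
- **Body weight** uniform on 40–90 kg (only the range is known); forces are
  affinely scaled into plausible Newton magnitudes per axis, which cannot
  affect the entropies.
- **Default targets** are the reference cohort's group means/SDs; fallers
  are lower on every channel, markedly on the STS verticals.

What passing tests on these cohorts shows: the pipeline's operations are
correct and the selection machinery recovers signal that lives in
group-wise entropy differences. What it does not show: performance on real
gait data, where entropy differences coexist with biomechanical structure
(gait cycles, STS phases, sensor noise) that MIX(p) does not model. The
published real-cohort classification rates are therefore not reproduction
targets here.

## Planted-signal experiment design

The recovery tests plant group separation in a known channel subset
(baseline mean 0.40, SD 0.05 everywhere; faller means shifted down on
planted channels only). The planted gap is 2.5 SD per channel at n = 25 per
group — chosen once, at design time, so that single planted features are
informative but imperfect (single-feature LOOCV error ≈ 8–15%) while
multi-feature subsets approach perfect separation; a much larger gap would
make a singleton subset win (minimal-cardinality tie-break) and a much
smaller one would let noise features crowd the winner. The
perfectly-separable variant uses a 10-SD gap on one channel with SD 0.02,
where every classifier must reach 100% sensitivity and specificity.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen for a single-CPU test run while
keeping effect sizes decisive: generator calibration and rank-sum power on
one shared n = 100/group cohort; group-ordering sign checks at n = 30/group
over 10 replicates (the R_V_F gap is ≈ 3.5 standard errors per replicate);
planted-star statistics at n = 40/group over 3 seeds; null calibration of
the rank-sum test over 2000 simulated comparisons at the reference group
sizes (23/15).

## Known limitations

- MIX(p) realizations are stationary and memoryless given p; real GRF series
  are cyclic and nonstationary. Only entropy-level claims transfer.
- The entropy SD targets are approximate: realization noise adds in
  quadrature (≈ +0.01–0.02 inflation), and clipping to the achievable range
  slightly biases extreme draws; group means are the calibrated quantity.
- Sensitivity-first selection can prefer degenerate high-sensitivity/
  low-specificity solutions on weakly separated cohorts (visible in the
  README example); this is the selection rule's documented behaviour, not a
  defect.
- With two walking passes per subject the averaging/concatenation choice is
  a config switch; no evidence privileges either.
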
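# fallgrf

Fall-risk screening of older adults from ground-reaction-force (GRF)
recordings: sample-entropy features, outlier-robust nearest-neighbour
classification, exhaustive feature-subset selection, and nonparametric group
statistics — with a calibrated synthetic cohort generator so the entire
pipeline runs without any data download.

## The problem and the method

Community-dwelling elderly people at risk of falling tend to move more
*regularly*: reduced muscle strength and balance smooth out the force signals
their feet exert on the ground. The pipeline quantifies that regularity on
eight GRF channels per subject — medial-lateral (ML), anterior-posterior (AP)
and superior-inferior (SI) walking forces for each foot, plus the vertical
(V) force of each foot during a sit-to-stand (STS) transfer:

| # | feature | channel |
|---|---------|---------|
| 1–3 | `L_ML_F`, `L_AP_F`, `L_SI_F` | left-foot walking GRF (ML/AP/SI) |
| 4–6 | `R_ML_F`, `R_AP_F`, `R_SI_F` | right-foot walking GRF (ML/AP/SI) |
| 7–8 | `L_V_F`, `R_V_F` | left/right vertical GRF during STS |

Each channel is normalized by body weight, standardized to zero mean and unit
variance, and summarized by **sample entropy**

SampEn(m, r) = −ln(A/B),

where B counts ordered pairs of distinct length-m templates within Chebyshev
tolerance r and A counts those still matching at length m+1 (no
self-matches; defaults m = 2, r = 0.25 in SD units). Lower SampEn means a
more regular signal; fallers sit lower on the discriminative channels.

Subjects are classified as faller / non-faller with three k-NN variants that
score each class *separately* over its own k nearest neighbours (Euclidean
distance) and pick the class with the minimal score:

- **LMKNN** — distance to the class's local mean, ‖x − x̄ᵢ(k)‖;
- **PNN** — weighted distance sum Σⱼ (1/j) · d(x, xᵢ⁽ʲ⁾);
- **LMPNN** — weighted sum of distances to the cumulative local means,
  Σⱼ (1/j) · d(x, x̄ᵢ(j)).

All 2⁸ − 1 = 255 nonempty feature subsets × classifiers × k are scored by
leave-one-out cross-validation; the winning subset maximizes **sensitivity
first**, then accuracy (missing a faller is the costly error), then
specificity, with deterministic tie-breaks. Selected features are verified
with the Wilcoxon rank-sum test (two-sided, α = 0.1) and Spearman
correlations bucketed as high (|r| ≥ 0.50), moderate (≥ 0.30), weak
(≥ 0.10) or negligible.

Because no public cohort exists, `fallgrf.synthetic` generates one: each
channel is a MIX(p) process (sinusoid samples replaced by uniform noise with
probability p) whose SampEn increases monotonically with p. A seeded
calibration curve maps per-subject entropy targets — drawn around per-group
means/SDs that default to the reference cohort's published statistics — to
irregularities p, giving cohorts whose group entropy structure matches the
targets to within ±0.05 at n = 100 per group.

## Worked example

```bash
fallgrf run --seed 7 --out demo/
```

simulates the reference-sized cohort (23 fallers, 15 non-fallers, 1000
samples per channel), extracts the eight entropies, searches all 255 subsets
with LMKNN/PNN/LMPNN for k = 1..10, and prints:

```
fall-risk pipeline summary
==========================

LMKNN  features=L_SI_F k=9 accuracy=65.79% sensitivity=100.00% specificity=13.33%
PNN    features=L_AP_F+L_SI_F+R_ML_F+R_AP_F+L_V_F+R_V_F k=9/10 accuracy=73.68% sensitivity=95.65% specificity=40.00%
LMPNN  features=L_AP_F+L_SI_F+R_V_F k=9 accuracy=81.58% sensitivity=91.30% specificity=66.67%

features significant at alpha=0.1: R_AP_F, L_V_F, R_V_F
```

Reading this: LMPNN's best subset classifies 31/38 subjects correctly while
catching 21/23 fallers; the sensitivity-first rule happily trades
specificity for sensitivity (LMKNN reaches 100% sensitivity by flagging
nearly everyone at k = 9 — a faithful consequence of the selection ordering
on an overlapping synthetic cohort). The sit-to-stand entropies (`L_V_F`,
`R_V_F`) separate the groups most strongly, matching the calibration's
design. `demo/` also holds the full 255 × 3 × 10 search grid, the
group-comparison and correlation tables, and a manifest; two runs with the
same seed are byte-identical.

The same stages are available piecemeal (`fallgrf simulate / extract /
classify / search / stats`) and as a library:

```python
from fallgrf import (CohortSpec, generate_cohort, extract_feature_table,
                     ExhaustiveSubsetSearch, FEATURE_NAMES, GROUP_ORDER)

df = extract_feature_table(generate_cohort(CohortSpec(23, 15, seed=7)))
search = ExhaustiveSubsetSearch(class_order=GROUP_ORDER).fit(
    df[list(FEATURE_NAMES)].to_numpy(), df["group"].to_numpy())
print(search.summary())
```

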
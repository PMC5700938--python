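# Methods

## Problem setting

Vaginal microbiome samples, summarized as OTU-level count vectors, are
collected from pregnant subjects at known gestational weeks; each subject
has a recorded delivery outcome, term (TERM) or preterm (PTD). The question
the package operationalizes is whether a scalar summary of a single sample's
community structure, taken early in pregnancy, separates the two outcomes
well enough to serve as a screening marker. PTD is the positive class in
every derived statistic.

## Data model and inclusion rules

A cohort is a taxa × samples integer count table over a shared taxon
universe plus per-sample metadata (subject, study, gestational week,
outcome). Samples with fewer than 500 taxonomically assigned reads are
excluded; the boundary is inclusive (exactly 500 reads is kept). Outcome
labels are normalized case-insensitively ({term, full-term} → TERM;
{ptd, preterm} → PTD). Gestational weeks may be fractional and must lie in
(0, 45].

Cumulative groups `Week_N` (N = 8…40) contain every sample taken at or
before week N — 33 nested groups whose sizes are monotone in N. Grouping is
per sample, not per subject; a `per_subject` flag keeps only each subject's
latest qualifying sample for users worried about within-subject leakage.
For week-resolved trend displays, overlapping windows are used instead;
the default is 15 windows of width 6 weeks, step 2.5, starting at week 1
(covering weeks 1–40 with ~58% overlap). The window construction is fully
configurable; only the count of 15 windows is fixed by convention.

## Metrics

All nine per-sample measures are computed with natural logarithms and a
uniform zero-handling policy:

| metric | definition | domain notes |
|---|---|---|
| shannon | −Σ pᵢ ln pᵢ over nonzero pᵢ | ≥ 0; ≤ ln(observed richness) |
| simpson | 1 − Σ pᵢ² (Gini–Simpson) | inverse form available as option |
| chao1 | S_obs + F₁(F₁−1)/(2(F₂+1)) | integer counts only; bias-corrected form avoids F₂ = 0 blow-ups |
| gini | Σᵢⱼ\|xᵢ−xⱼ\| / (2n²μ) | zeros included; no small-sample correction |
| ricci_schutz | Σ\|xᵢ−μ\| / (2nμ) | Pietra/Schutz coefficient |
| atkinson | 1 − [(1/n)Σ xᵢ^{1−ε}]^{1/(1−ε)}/μ | ε = 0.5 default; geometric-mean limit at ε = 1; any zero with ε ≥ 1 gives 1 |
| theil | (1/n)Σ (xᵢ/μ) ln(xᵢ/μ), 0·ln 0 ≡ 0 | Theil T |
| decile_ratio | P90/P10 of *nonzero* abundances | linear-interpolation quantiles; missing (NaN) with < 2 nonzero taxa |
| tcs | pluggable; default g₁ = m₃/m₂^{3/2} of the full p vector | 0 for numerically constant vectors |

Inequality indices run over the full vector of the cohort taxon universe,
zeros included, mirroring how econometric inequality packages treat a fixed
population; the decile ratio alone restricts to nonzero values to avoid a
zero denominator. Everything except Chao1 is scale-invariant, so counts and
relative abundances give identical values; Chao1 requires integer counts
and is reported from raw counts without rarefaction. A seeded
rarefy-to-depth preprocessor exists but is off by default in every
pipeline.

The taxonomic composition skew is deliberately a strategy interface
(`tcs(profile, variant=...)`, `register_tcs_variant`): the default variant
is the Fisher–Pearson moment skewness of the relative-abundance vector — a
natural scalar for "one dominant taxon plus a rare tail" compositions, for
which a single outlier among n taxa gives (n−2)/√(n−1) regardless of its
magnitude — and the `supplementary` name is reserved for an exact published
formula to be registered by users who have it. All downstream machinery is
agnostic to the variant.

## Threshold classification

For one metric on one sample group, candidate thresholds are the midpoints
between consecutive sorted unique values plus ±∞ sentinels, scanned in both
directions (PTD below vs. PTD at-or-above the cut); the rule maximizing MCC
wins. Midpoint candidates visit the same confusion matrices as scanning
observed values but place the cut in the interior of gaps, which matters
when a threshold is later transferred to new data. Values exactly equal to
a transferred threshold go to the above-or-equal side. Tie-breaks are
deterministic: higher ES, then smaller threshold, then the
below-direction — ES depends only on the two class value-sets, so within a
single fit the first criterion never discriminates and is retained only for
interface stability. MCC is defined as 0 when any denominator factor
vanishes; 0/0 rates (sensitivity etc.) are reported as missing rather than
raising, which keeps week-wise sweeps total.

ES ∈ [0, 100] is computed from the class extreme values as described in the
README; it is reported alongside MCC and printed in brackets in sweep
tables only when MCC = 1, since it is most informative as a margin measure
for perfectly separating metrics. The direction of each rule is learned
from the data, never assumed.

## Validation protocols

**Internal.** Samples at or before the week cutoff (15 or 20) are split
into 2/3 training / 1/3 test corpora, stratified by outcome by default
(an unstratified mode matches the plainest reading of a random 2/3 split;
stratification guarantees estimable parameters every iteration). Per
iteration and metric, the threshold is refit on the training corpus and the
frozen rule scored on the test corpus; 1000 iterations by default. Child
seeds are spawned per iteration from one master `SeedSequence`, so results
are reproducible and individual iterations re-derivable. Single-class
splits (possible only unstratified) are resampled up to a retry cap;
stratified runs detect upfront when a class is too small to appear in both
corpora.

**External.** The transferable rule per metric is the arithmetic mean of
per-iteration best thresholds plus the majority direction (disagreement
rate logged). It is applied frozen to the external cohort's
early-pregnancy samples.

**Comparisons.** Metric A vs. metric B uses the two-sided Wilcoxon
signed-rank test on values paired per iteration (internal CV) or per
Week_N row (sweeps, default weeks 8–20, 13 pairs), with zero differences
dropped; the exact null distribution is used up to 25 retained pairs and
the continuity-corrected normal approximation beyond. P-values are
Benjamini–Hochberg–adjusted across competitors. Pairs with fewer than five
nonzero differences (common when both metrics sit at MCC = 1 in early
weeks) report a missing p-value rather than a fabricated one.

## Synthetic cohort generator

Each sample's composition is Dirichlet with one dominant component
(concentration `dominance_alpha` = 40) and n−1 tail components at a shared
"evenness" concentration; counts are multinomial at a depth uniform on
[500, 50 000], so every generated sample clears the inclusion filter.
Defaults: 300 subjects, 13.8% PTD, 200 taxa, 1–3 visits per subject at
uniform weeks 4–40.

The outcome effect lives entirely in the tail evenness: TERM samples use
concentration 0.15 at every week, PTD samples 0.002 through week 15, then
log-linear interpolation up to the TERM value at week 20, constant
afterwards. This realizes a preterm arm with markedly lower early-pregnancy
diversity on every evenness-sensitive metric — matching the motivating
observation of depressed PTD diversity in the first 15–20 weeks with
convergence thereafter — while keeping dominant-taxon prevalence realistic
(median dominant relative abundance > 0.5). Placing the effect on tail
evenness rather than dominant-taxon presence makes all nine metrics
responsive, which is the regime the week-sweep analysis presumes.

External cohorts reuse the same generative family and effect structure
with perturbed nuisance parameters; the default shift halves the depth
range and scales dominance by 1.1, modelling protocol/primer differences
between studies. Stronger shifts (different taxon count, larger dominance
change) are available but change metric scales enough that frozen-threshold
transfer is not guaranteed — which is the realistic caveat of the
mean-threshold protocol, not a defect of the generator.

What the generator does **not** emulate: within-subject longitudinal
autocorrelation (samples are independent given arm and week), community
state transitions, taxon identities or phylogeny, compositional zeros from
contamination, or batch effects beyond the scalar shifts above. Tests that
pass on these cohorts therefore validate the statistical machinery and the
qualitative early-separation/late-convergence pattern, not clinical
performance on real cohorts.

## Problem sizes used in the shipped checks

The structural tests and `scripts/acceptance.py` use the 300-subject
default cohort (~600 samples), 100-iteration internal validation at the
15-week cutoff, and 200 random instances per oracle-equivalence check —
sizes at which every acceptance-level property is stable across seeds
while the whole suite runs in well under a minute of compute.

## Known limitations

- The default TCS variant is a generic moment skewness; on 200-taxon
  compositions it saturates near its one-outlier ceiling for extreme
  dominance, compressing contrast between highly dominated samples. It
  remains the weakest early-week separator among the nine metrics on the
  synthetic cohorts; variant plug-in exists precisely so a sharper formula
  can replace it without touching validation code.
- Mean-threshold transfer assumes the metric's scale is comparable across
  cohorts; depth- or richness-sensitive metrics (Chao1, TCS over a
  different taxon universe) violate this under strong shifts.
- The decile ratio is undefined for near-monocultures (< 2 nonzero taxa)
  and extremely heavy-tailed otherwise; it is retained for completeness
  but is the noisiest of the nine measures.
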
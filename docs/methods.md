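# Methods

This note documents the models, conventions and numerical choices behind
`meapipe`, in the spirit of a statistical-methods appendix.

## Spike-level conventions

Times are seconds (float64) from recording start; sample indices are
0-based with index = ⌊t·f_s⌋ at f_s = 12.5 kHz (one sample = 0.08 ms). A
guard of 10⁻⁶ sample absorbs float rounding of on-grid times. All windows
are half-open `[start, end)`; spikes exactly on a 5-minute unit boundary
belong to the later unit. Recordings are concatenations of 5-minute units
(default 4 → 20 min).

## Spontaneous-activity metrics

* **MFR** — total well spikes / recording time. The per-well total (rather
  than a per-electrode mean) is used; the weighting formulas below only
  make sense on the total.
* **Active electrode** — spike rate ≥ 0.1 Hz, boundary inclusive. The count
  comparison uses the exact spike-count threshold, so "30 spikes in 300 s"
  is active regardless of float quotients.
* **wMFR / wMBR** — the two printed weighting conventions differ: wMFR
  scales *up* by e_max/e_act while wMBR scales *down* by e_act/e_max. One
  weighting function with an explicit `{scale_up, scale_down}` flag
  implements both; each metric defaults to its printed form, and either can
  be overridden in `RunConfig` if a user decides the asymmetry is a typo.
  e_max is the active-electrode count at the reference timepoint (taken as
  the maximum over the reference window's recording days), or at baseline
  for treatment experiments.
* **Mean ISI** — within-electrode consecutive intervals pooled over active
  electrodes; cross-electrode intervals are never formed.
* **Bursts** — maximal runs of ≥ 5 consecutive single-electrode spikes with
  every ISI ≤ 100 ms. The threshold is inclusive with 10⁻⁹ relative slack
  so grid-spaced ISIs exactly at 100 ms stay in-burst despite float
  representation. **Network bursts** apply the same run rule to the pooled
  well train (ties broken by electrode label, stable) with minima of 50
  spikes and 5 distinct channels. Inter-NB intervals are onset-to-onset.

## STTC

STTC = ½[(P_A−T_B)/(1−P_A·T_B) + (P_B−T_A)/(1−P_B·T_A)] with Δt = 100 ms.
P_A is the fraction of A's spikes within ±Δt (inclusive) of any B spike;
T_A is the fraction of [0, T] covered by the union of ±Δt windows around
A's spikes, computed by exact interval arithmetic (windows clipped at the
recording edges, overlaps merged), not by rasterization. Degenerate rules:
a term that is 0/0 is defined as 0; an empty train makes the pair
undefined (excluded from summaries); full coverage is snapped to exactly
1.0 (relative slack 10⁻¹²) so the 0/0 rule fires consistently. Mean and
skewness run over defined upper-triangle pairs; all-equal pair values give
skewness 0 with a flag so downstream parameter vectors stay complete.
Skewness is the adjusted Fisher–Pearson G1 (bias-corrected). By default
STTC is computed on full recordings; `restrict_to_nb=True` first clips
trains to the concatenated NB windows (the descriptions of the measure in
the source material differ between whole-recording and within-NB
computation, so both are available and neither is asserted as canonical).

## Quality control

Wells are selected at the reference timepoint (DIV 21–24 for time series,
baseline for treatment, the first spontaneous block for stimulation
experiments) by active-electrode count, boundary inclusive (≥ 10; ≥ 8 for
evoked analysis). Integrity censoring beyond the reference requires *both*
a drop of ≥ 2 contributing channels *and* wMFR < 70 % of reference; the
first triggering day and all later days are excluded. Stability of
stimulation experiments is tested by Welch's t on per-electrode rates of
the two flanking spontaneous blocks (keep iff p ≥ α = 0.05); per-electrode
rates were chosen over per-unit rates as the more plausible unit of the
"MFR and SD" the protocol names, with the alternative available by flag.
The tetanus outlier screen uses Tukey fences (quartiles ± 1.5·IQR,
inclusive) on the per-well STIM2/STIM1 evMFR_norm ratio — the original
outlier rule is unspecified, so a standard, configurable one is used and
each decision is logged. Filters are idempotent and every excluded well
carries a reason code.

## Parameter vectors and cluster separation

The default 19-parameter vector covers every well-level parameter the
pipeline computes (active electrodes; MFR/wMFR/wtMFR/ISI; MBR/wMBR, burst
duration, spikes/burst, % spikes in bursts; NB count/duration/spikes/
channels/rate, % spikes in NBs, inter-NB interval; mean and skewness of
STTC). The exact historical list is not public, so the composition is a
declared reconstruction and fully configurable
(`ParameterVectorSpec`). Rates and durations enter as log₁₀ (a
non-positive value makes the well missing for that vector, and the
completeness rule then excludes it); counts, percentages and STTC moments
enter untransformed. The printed feature presets are `spiking_4`
(contributing electrodes, log wMFR, log wtMFR, log ISI), `bursting_3`
(log wMBR, log burst duration, log spikes/burst) and `network_4` (NB
count, mean NB duration, spikes/NB, channels/NB).

Vectors are z-scored per timepoint (sample SD, ddof = 1), which removes
the systematic developmental activity increase; zero-variance columns are
dropped with a warning and recorded. PCA is the covariance
eigendecomposition of the z-scored matrix (scikit-learn backend, full SVD)
with a deterministic sign rule: the largest-magnitude loading of each
component is positive. Feature PC1 projections are additionally
sign-aligned so that higher activity (the preset's anchor parameter) maps
to positive PC1. PCA is fit per age cohort by default (a global fit is a
flag); wells with any missing value over the analyzed course are excluded
beforehand.

Separation of the two genotype clouds is computed in the PC1–PC2 plane
(p = 2, matching the F_critical = 3.1 magnitude for 2 numerator dof):

    D² = (μ_a−μ_b)ᵀ S_pooled⁻¹ (μ_a−μ_b),  S_pooled with n_a+n_b−2 dof
    T² = n_a n_b/(n_a+n_b) · D²
    F  = (n_a+n_b−p−1)/((n_a+n_b−2)p) · T²  ~  F(p, n_a+n_b−p−1)

A singular pooled covariance raises with a hint to a configurable ridge ε
(default off). Full-dimensional separation is available by flag.

## Evoked activity and tetanus effect

evMFR′ per electrode and session is the mean over pulses of the spike
count in [pulse, pulse+1 s)/1 s; pulses whose window would cross the
recording end are skipped with a warning. Normalization divides by the
same electrode's spontaneous rate from the full immediately preceding
spontaneous block (20 min before STIM1, 10 min before STIM2/3); electrodes
below 0.1 Hz spontaneous rate are excluded from normalization. The
stimulating electrode's own channel is excluded during its session
(artifact contamination; configurable — the original protocol is silent on
this). Well-level evMFR_norm is the grand mean over electrode-session
values, reported with CV (sample SD/mean) and G1 skewness.

X = log₁₀(evMFR_norm@STIM3)/log₁₀(evMFR_norm@STIM2); X = 1 means no
tetanus effect; X is undefined (well excluded, coded) for non-positive
inputs or evMFR_norm@STIM2 = 1. Experiments are pooled per genotype as
mean-of-means, mean-of-variances and total n, then compared by Welch's t.
The printed aggregate formula has S²/n² in the denominator where standard
Welch has S²/n; the standard form is the default and the printed variant a
flag, with the convention named in the output. Note an intrinsic
limitation of X as a null statistic: if the evoked gain itself is 1
(evMFR_norm ≈ 1), both logarithms are near-zero noise and X is unstable;
"no tetanus effect" is therefore modeled as equal pre/post gains
(g′ = g > 1), which gives X = 1 ± sampling error, while the g = 1 null is
checked on evMFR_norm directly.

## Disinhibition time courses

Four 5-minute baseline units are averaged to define 100 %; the 10-minute
unrecorded gap after compound application is represented as missing units,
never zeros; post-treatment units are indexed in minutes from application
(+10 … +60). e_max for weighted rates is fixed at baseline.

## Synthetic data generator

The generator is a background + event-superposition model (the analysis
consumes only spike times, so no biophysical network model is needed):

* homogeneous Poisson background per electrode at λ(DIV), rising
  piecewise-linearly from 0.3 Hz (DIV 10) to a 2.0 Hz plateau (DIV 25) —
  typical of developing cortical cultures on MEAs;
* single-electrode burst events (Poisson process, 0.5→3 events/min per
  electrode over development), each ≥ 5 spikes with intra-burst ISIs drawn
  uniformly in [2, 90] ms, guaranteeing detectability;
* network-burst events (0.3→3 events/min per well) recruiting K(DIV) = 5→12
  channels, each event a pooled packet of ≥ 55 spikes with pooled gaps in
  [1, 4] ms;
* a mutant-genotype factor γ(DIV) multiplying λ and ν: 1.5 up to DIV 20,
  fading linearly to 1.0 at DIV 24 — early hyperactivity that converges
  with maturation;
* persistent per-well lognormal rate heterogeneity (SD 0.15 log₁₀, drawn
  once per well) plus per-day jitter (SD 0.05 log₁₀) — MEA well-to-well
  variability is notoriously large and largely stable across days;
* electrode dropout (2 %/day) modeled as sub-threshold noise firing
  (0.05 Hz) rather than silence, so active-electrode counting is
  exercised;
* evoked datasets: Poisson background with the rate multiplied by a gain g
  inside each 1-s post-pulse window (g′ after tetanus), pulses at 0.2 Hz
  from 6 electrodes in 5-minute sessions, tetanus of 20 bursts × 11 pulses
  at 20 Hz.

All outputs are pure functions of (config, seed); identical inputs give
byte-identical files. Ground truth (per-well rates, γ, dropout, gains) is
emitted alongside.

What the generator does *not* emulate: refractoriness and non-Poisson ISI
statistics, amplitude realism, spatial correlation between neighboring
electrodes, slow non-stationarity within a recording, and culture death.
Passing tests therefore demonstrate correctness of the measurement chain
and of the statistical machinery under the assumed event structure, not
robustness to every pathology of real recordings.

## Problem sizes and statistical design of the end-to-end checks

The developmental-convergence check uses 20 wells/genotype, three age
cohorts of two recording days each (DIV 11/13, 21/23, 29/31) and 2×300-s
recordings, and evaluates the *median* separation curve over 9 replicate
datasets. Medians are used because the persistent well heterogeneity
induces, per dataset, a random genotype imbalance that is common to all
cohorts of that dataset; at 20 wells/genotype this makes single-dataset
cohort-to-cohort D comparisons noise-dominated (the mid-vs-late gap in
particular carries a true difference of ≈ 0.15 against a seed-level SD of
≈ 0.4, so it is reported but not asserted). The asserted pattern is the
convergence itself: early F above the 3.1 critical value, early D above
both later cohorts, late F below early F.

The null calibration runs 150 independent single-cohort datasets with two
identical genotypes at 60 wells/genotype — chosen so the F denominator dof
(2, 117) puts the true 5 % critical point at ≈ 3.1, matching the critical
value used for the effect analysis — and requires ≥ 93 % of F values below
3.1 (the true rate is ≈ 95 %).

Evoked checks: gain recovery uses the full 0.2 Hz/5-min protocol (60
pulses/session, 6 sessions); the power check scales the protocol down
(2 sessions of 150 s, 4 wells/genotype, 3 experiments per replicate, 10
replicates) — the tetanus effect (g′ = 4.5 vs 3.0, X ≈ 1.37 vs 1.0) is
large relative to measurement noise, so power is essentially 1 at this
size.

## Known limitations

* The aggregate Welch test treats per-experiment variances as exchangeable
  (mean of variances); heteroscedastic experiments with very different
  well counts would be better served by a mixed model, which the pipeline
  deliberately delegates to established software rather than
  re-implementing.
* Mahalanobis/Hotelling inference assumes approximate bivariate normality
  of PC scores within groups; the permutation calibration performed in the
  tests shows the F approximation is accurate for data of this type, but
  heavy-tailed wells (e.g. near-silent cultures surviving QC) could
  distort it.
* The NB definition (pooled 100-ms gaps) saturates at high pooled
  background rates: above ≈ 20–30 Hz pooled, cluster boundaries reflect
  background statistics as much as genuine population events. This mirrors
  the behavior of the original detector and is inherited deliberately.
* The timestamp-matrix path collapses same-sample spikes to a single 1;
  counts are preserved only in the spike table.
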
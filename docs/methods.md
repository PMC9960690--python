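# Methods

This note documents the scientific and numerical choices behind the
package: what each stage computes, the defaults and why, what the synthetic
generator does and does not emulate, and the known limitations.

## RR preprocessing

The pipeline order is fixed: delete abnormal beats → cut windows → score
missing data → filter on quality → impute → label. On a gap-free record the
chain reproduces the input beat sequence exactly (asserted by test).

**Abnormal beats.** RR values strictly above 1.3 s or strictly below 0.3 s
are deleted — the strict inequalities are deliberate, so the physiological
bounds themselves (45 and 200 bpm) are retained. Deletion removes samples
but never shifts surviving timestamps: the gap it creates is what the
missing-data scorer sees.

**Windows.** Half-open intervals `[k·step, k·step + 300 s)` anchored at the
record start; `step = 300 s` (side by side) for ambulatory data, `60 s`
(sliding) for lab data, mirroring the two study designs. The trailing span
shorter than one window is dropped. A record carries an explicit nominal
length (`record_len_s`) so that a 45-minute protocol yields
`floor((2700−300)/60)+1 = 41` sliding windows even though the last beat
falls fractionally short of 2700 s.

**Missing-data score.** For each inter-beat gap strictly above 1.3 s, the
number of missing beats is `N = floor(gap/meanRR)` with `meanRR` the mean
of the up-to-10 observed RR values immediately preceding the gap (the
window median if none precede it — only reachable in degenerate inputs,
since a gap always has a beat before it). The window score is
`Pmissing = 100·ΣN/(n_observed + ΣN)`; the denominator's first term is the
*count* of observed RR values, the only reading commensurate with ΣN.
`floor(gap/meanRR)` is used verbatim even though a gap of `g` seconds
bridged by beats of `meanRR` strictly contains `g/meanRR − 1` missing
beats; the alternative is noted here and not implemented. Windows with
`Pmissing ≤ 50%` (inclusive) are kept; windows with fewer than two beats
are unusable and scored 100%.

**Imputation.** Each counted gap receives its `N` beats, evenly spaced
inside the gap (the method only constrains the RR-value interpolant, not
beat placement; even spacing is the symmetric choice). RR values come from
a PCHIP interpolant through the observed `(beat time, RR)` pairs; PCHIP is
shape preserving, so imputed values never overshoot the local data. Because
the imputed spacing `gap/(N+1)` is strictly below `meanRR ≤ 1.3 s`, no
over-threshold gap survives imputation, which also makes the operation
idempotent. At least 4 observed beats are required for a cubic Hermite fit.

**Labels.** A window takes a segment's label only when fully contained in
it; windows straddling a boundary are dropped rather than majority-labelled,
avoiding label noise of unknown magnitude. Relaxation and recovery phases
both map to the non-stress class, reflecting parasympathetic dominance in
both states.

## The 61-feature battery

Conventions are pinned for reproducibility rather than being claims about
any particular toolbox:

- SDNN and heart-rate standard deviation use sample (n−1) normalisation;
  Poincaré SD1/SD2 use population variances
  (`SD1 = sqrt(var(Δ)/2)`, `SD2 = sqrt(2·var(RR) − var(Δ)/2)`).
- NN50/NN20 use strict `> 50 ms` / `> 20 ms`; pNN values are per successive
  difference.
- TINN and the triangular index use the standard 7.8125 ms histogram bin.
  The triangular fit minimises the squared deviation between the histogram
  and a triangle anchored at the modal bin; the left and right vertex
  errors are independent, so the least-squares search is separable and
  exact over bin centers. A numerically constant series degenerates to
  `TINN = 0`, triangular index 1.
- All quantiles (IQR features, outlier fences, robust scaling) use the
  linear-interpolation (type-7) convention.
- The spectrum is a plain FFT periodogram — not Welch, which is available
  behind `use_welch` but off by default — of the tachogram PCHIP-resampled
  at 8 Hz over `[first beat, last beat]` and linearly detrended. The PSD is
  renormalised so that `Σ PSD·Δf` equals the variance of the detrended
  signal (Parseval), units s²/Hz. Windows spanning under 60 s are rejected:
  the frequency resolution would not resolve the LF band.
- Band powers use rectangular integration with half-open `[low, high)`
  membership over VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz; total power
  is their sum, so the band decomposition is exact by construction. A zero
  HF power turns LF/HF into the largest finite float (sentinel, logged)
  rather than an exception.
- Shannon entropy of the RR distribution uses a 10-bin histogram, base 2,
  empty bins skipped. Spectral entropy is normalised by `log2(#bins)` so a
  flat PSD scores 1. The "spectral distribution" cutoff (0.15 Hz) and
  "human range energy" band (0.6–2.5 Hz) are fixed artifact conventions
  exposed in the configuration.
- Zero-variance guards: entropy, kurtosis, skewness, slope, lag-1
  autocorrelation and the SD1/SD2 ratio all return 0 on (numerically)
  constant input, with a warning, never NaN.

The registry holds exactly 61 names in a fixed order. The direct
enumeration of the classical battery yields 60 names; the 61st member is
spectral spread, kept separate from its square (spectral variance) as a
deliberate registry decision. A window failing any feature precondition is
skipped and logged — never silently zero-filled.

## Classification stage

Per training fold, in order:

1. **1.5×IQR outlier removal** — per feature, fences at
   `(Q1 − 1.5·IQR, Q3 + 1.5·IQR)`; a row is dropped iff any feature lies
   strictly outside. On Gaussian data these fences sit at ±2.7σ. With 61
   features the any-feature rule is aggressive (it can drop over half the
   rows — a logged warning, not an error); by default it runs inside each
   training fold only (`outlier_scope="train"`), whole-table filtering
   being available for sensitivity analysis.
2. **SMOTE** — minority class grown to the majority count; each synthetic
   row is `x + u·(x_nn − x)`, `u ~ U(0,1)`, toward one of `k = 5` nearest
   minority neighbours (Euclidean). `k` is clipped to `minority − 1` when
   needed; a singleton minority is an error. Implemented in-package and
   deterministic under the pipeline seed.
3. **Robust scaling** — subtract the training median, divide by the
   training IQR (divisor 1 when the IQR is 0, logged). Test rows are always
   transformed with training statistics.
4. **Classifier** — logistic regression (ridge penalty at default strength,
   iteration cap 1000, tolerance 1e-4) or random forest with the tuned
   configuration: entropy criterion, sqrt features per split, max depth 6,
   min samples split 2, 200 trees; `min_samples_leaf` stays at the
   conventional default 1 and is recorded in the model spec. Stress is
   encoded 1 (positive class) internally.

Grid search optimises the mean rank-based ROC AUC of the continuous score
over subject-grouped folds (10 by default, reduced with a warning when
there are fewer subjects); ties break toward the first spec in the given
order.

## Evaluation

The reported ROC AUC is the hard-label form `(1 + TPR − FPR)/2`, which is
algebraically balanced accuracy `(TPR + TNR)/2`; the rank-based score AUC
is kept as a diagnostic, since both readings of "ROC AUC" are defensible.
LOSO aggregates by pooling confusion counts across folds rather than
averaging per-fold metrics — ambulatory data routinely produce single-class
test subjects whose per-fold metrics are undefined, while pooling remains
well defined (per-fold breakdowns are retained). 0/0 divisions yield 0 with
a warning rather than dropping a fold. Cross-dataset evaluation fits the
identical leakage-safe stage chain once on the full training table and
scores the full test table.

## Synthetic generator

The generator encodes only the directional autonomic assumptions the
analysis needs — it is a statistical test-bed, not a cardiovascular model.
Beats follow `t[k+1] = t[k] + RR(t[k])` with two sinusoidal modulations
fixed at the LF/HF band centers (0.1 and 0.25 Hz, so simulated power lands
unambiguously in the right bands) plus Gaussian beat-to-beat noise; RR is
clipped strictly inside (0.3, 1.3) s so clean segments survive
preprocessing untouched. Per subject, the baseline RR is drawn
`Normal(0.85, 0.07)` clipped to [0.55, 1.2] s and the amplitudes/noise are
jittered ±20% around the defaults (`a_lf = 0.03`, `a_hf = 0.05`,
`noise_sd = 0.02`, relative). Stress multiplies `rr0` by 0.85 (faster heart
rate), `a_hf` by 0.4 (vagal withdrawal), `a_lf` by 1.2 and `noise_sd` by
0.7 — magnitudes chosen once to make the *direction* of the effects
(lower SDNN and HF power, higher LF/HF under stress) robustly testable, with
no claim of physiological calibration.

Corruption injects (a) Poisson-placed gaps deleting 2–8 consecutive beats,
extended if necessary until the resulting inter-beat gap exceeds 1.3 s, and
(b) ectopic beats replacing one RR value `x ≥ 0.55 s` with the premature
pair (0.25 s, x − 0.25 s), which the abnormal-beat rule later removes.
Rates are expected events per 5 minutes.

**Lab mode** emits one 45-minute record per subject (relaxation 900 s,
stress 1200 s, recovery 600 s; default 68 subjects, light corruption).
**Ambulatory mode** scales a multi-week wearable study down to a
configurable few hours per subject (default 3 h, 25 subjects, heavier
corruption) with stress episodes covering ~7% of the windows. Stress
episodes are placed as a contiguous run of blocks aligned to the 300 s
side-by-side window grid, with the expected run length equal to the
configured fraction of the subject's windows: unaligned short episodes
would lose a disproportionate share of *stress* windows to the
straddle-drop labelling rule and bias the realized imbalance well below the
configured value. A "shifted" ambulatory configuration (higher device
noise, weaker stressor multipliers) is provided for the cross-dataset
generalizability harness.

What the generator does **not** emulate: integral-pulse-frequency
modulation or any closed-loop cardiovascular dynamics, respiration
coupling, circadian rhythm, movement artifacts with realistic temporal
structure, or subject-specific stressor response heterogeneity beyond the
jittered multipliers. Consequently, passing tests demonstrate that the
pipeline's statistical machinery (quality control, features, leakage-safe
imbalanced learning, evaluation protocols) behaves correctly on data with
the assumed structure — they say nothing about classification accuracy on
real recordings, whose reported scores require the original datasets.

## Problem sizes and determinism

The test suite exercises the full chain at desk scale as the package's own
default study conditions: 12 lab subjects for LOSO parameter recovery (with
a label-permutation null), 8 lab subjects against 10-subject shifted
ambulatory corpora over 10 seeds for the cross-dataset harness, 1000
randomized windows for the missing-data oracle, and 100 random windows for
the feature cross-checks. All randomness flows through explicit integer
seeds (numpy `default_rng`); classifiers receive fixed `random_state`, so
every reported number is bit-reproducible.

## Known limitations

- The missing-beat count `floor(gap/meanRR)` overestimates by one beat per
  gap relative to the strict bridging count; kept verbatim (see above).
- The hard-label ROC AUC is a coarser statistic than the score-based AUC;
  both are reported, the hard-label form being canonical here.
- The LF/HF sentinel (largest finite float) for zero HF power keeps the
  feature finite but distorts scaling statistics when it occurs; it is rare
  on realistic tachograms and always logged.
- TINN's separable least-squares fit assumes the triangle's peak sits at
  the modal bin, the standard geometric convention; multimodal histograms
  make the fit, like the statistic itself, less meaningful.
- Tachogram resampling mildly attenuates power near the HF band's upper
  edge at slow heart rates (a sampling, not an implementation, effect);
  the single-tone acceptance checks quantify the retained fraction.
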
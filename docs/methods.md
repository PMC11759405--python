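# Methods

## Model

The intensity trace `y(t)` (knob-reported feeling, unit interval) is
modelled as a polynomial NARX process over physiological features: output
lags `y(t−1)…y(t−n_y)` enter linearly; each exogenous feature `u_m`
contributes `n_u_m + 1` lagged terms starting at its own delay `n_k_m`,
each with its square. The current input `u(t)` never enters (delays start
at 1), so the model is strictly causal with a minimum physiological lead
of one sample (0.39 s at 2.56 Hz).

The output map is `y = y₀ + (z − z̄)ᵀ P l + W(z) + S(z)`:

* `z̄` and the per-column standard deviations are training statistics;
  `P = diag(1/σ) V` combines standardisation with the principal axes `V`
  of the standardised regressors, retaining components explaining
  ≥ 1 − 10⁻⁶ of variance (rank-deficient directions are dropped, making
  the linear solve minimum-norm).
* `l` solves the projected least-squares problem in closed form (the
  projected columns are orthogonal).
* `W` is a sum of radial wavelet units ψ(ρ) = (d − ρ)·exp(−ρ/2) and `S` a
  sum of Gaussian scaling units φ(ρ) = exp(−ρ/2), where
  ρ = ‖a ⊙ (x − c)‖² on the projected coordinates `x` (dimension `d`).
  Candidate centres sit on a seeded subsample of training points (32 by
  default) at dyadic dilations (1, ½, ¼ of the per-dimension spread);
  units are added greedily by matching pursuit with joint amplitude
  refits, up to 8 units or until the relative residual-variance
  improvement falls below 10⁻⁴. On data with a purely polynomial
  generating process the unit stage contributes nothing and the model
  reduces to (projected) least squares — several tests rely on this.

Trials are pooled for fitting but regressors never cross a trial
boundary. Standardisation statistics always come from training folds
only.

## Evaluation modes

Free-run simulation (output lags fed back from the model's own
predictions, initialised with the first `max-lookback` ground-truth
samples) is the default objective both for reporting *and inside the lag
search*. One-step-ahead prediction is available but deliberately not the
default: with any autoregressive term, one-step correlations sit near
0.99 for every lag structure, which would make the Δr ≥ 0.01 forward-
selection rule vacuous and is inconsistent with the correlation levels
the procedure is meant to reproduce (roughly 0.4–0.9). A diverged free
run (|ŷ| > 10³) scores correlation 0, the same convention as a
zero-variance prediction; correlations are plain Pearson r with
zero-variance inputs mapping to 0.

When no wavelet units are active the prediction is affine in `z`, so the
exogenous contribution is precomputed as a series and only a scalar
autoregressive loop remains (JIT-compiled when numba is available); a
Gram-matrix formulation of the leave-one-out fits avoids restacking rows
per fold. Both fast paths are tested to be algebraically identical to the
reference fit.

## Search

* 1 feature (3 integer parameters in [1, 11]): exhaustive search over the
  1331-cell grid; ties break toward the lexicographically smallest
  (n_y, n_u, n_k).
* 2–3 features (5 or 7 parameters): integer genetic algorithm —
  tournament selection (size 3), uniform crossover (p = 0.8), random-reset
  mutation (p = 0.1 per gene), elitism (2) — population 50, capped at
  200 × (parameter count) generations, stopping early when the mean
  absolute change of the best fitness over 50 generations drops below
  10⁻⁶. Chromosome evaluations are memoised; everything is reproducible
  from (config, seed). The constraint-violation stop is vacuous under
  integer encoding and is retained only in the log.
* Sequential forward selection: stage 1 always accepts the best single
  feature; an extension is accepted only if it raises the mean LOOCV
  correlation by ≥ 0.01; at most 3 features for the NARX model, unlimited
  for the baseline; candidate ties break by the canonical 13-feature
  order. Greedy, no backtracking.

## Signal conditioning and features

GSR and pulse: 4th-order Butterworth low-pass at 30 Hz plus a Q = 30
notch at 50 Hz; respiration: 4th-order band-pass 0.1–30 Hz plus the same
notch — all zero-phase (forward–backward, reflect padding). The first 2 s
of every trial are discarded exactly once (enforced by a trim flag).
Features are extracted at the acquisition rate (256 Hz) and then
decimated by 100 to 2.56 Hz via zero-phase polyphase FIR resampling with
edge padding, keeping phase-0 samples; a 26 880-sample trimmed trial
yields ⌈26 880/100⌉ = 269 analysis samples.

The 13 features: filtered GSR, its derivative and running rate; filtered
(instantaneous) HR, its derivative and running rate; respiration rate,
its derivative and running rate; inspiration time, expiration time,
inhalation depth, exhalation depth.

* HR comes from systolic peaks (refractory 0.3 s) converted to
  beats/min, gated to [30, 200] bpm, linearly interpolated onto the
  uniform time base. Peak prominence uses 0.3 × (p98 − p2) of the pulse
  signal: an inter-quartile basis collapses on spiky beat trains (the IQR
  of a sharp pulse wave is a few percent of the beat amplitude, which
  admits noise bumps as beats).
* Breath cycles are trough–peak–trough triples from prominence-gated
  extrema (0.3 × IQR, minimum cycle 1.5 s, same-type runs collapsed to the
  most extreme event). Cycle features are sample-and-hold *causally*: a
  cycle's values become available at its end and hold until the next
  cycle's end. Both extremum detectors apply an absolute prominence floor
  of 0.05 signal units so that low-amplitude noise yields no events at
  all.
* Running rate of a series is (mean over a 5-s evaluation window − mean
  over a trailing 10-s reference window ending 5 s earlier) divided by
  (|reference mean| + 10⁻⁶), zero during warm-up. The window lengths are
  a documented surrogate for a proprietary toolbox feature and are
  configurable, not a claim of equivalence.

Features that cannot be computed (fewer than 3 beats or breath cycles)
are NaN with a cleared availability mask; masks propagate (the derivative
of an unavailable series is unavailable) and masked features are excluded
from a subject's candidate set, never imputed.

## Synthetic data

The protocol generator reproduces the study timeline: 24 trials (8 per
quality, first of each practice and excluded), each 2 s cue + 3 × 15 s
images + 30 s black + 30 s neutral = 107 s, ≈ 43 min total, acquisition at
256 Hz so that decimation by 100 lands on 2.56 Hz. Nominal image
intensities are drawn from {0.3, 0.6, 0.9}.

The biophysical layer generates: tonic skin conductance with drift plus
stimulus-locked bi-exponential SCRs (rise 0.75 s, decay 2.5 s, latency
1 s, amplitude proportional to nominal image intensity); a quasi-periodic
pulse wave exp(κ(cos φ − 1)) whose instantaneous rate follows a smoothed,
lagged stimulus drive; a respiration sinusoid with rate/depth modulation;
and a knob-style intensity trace that follows a saturating (tanh)
response to the nominal level through a pure lag and first-order
smoothing, clipped to [0, 1]. Gaussian measurement noise per channel.
What this layer does **not** emulate: picture-content effects,
habituation across images, motion artifacts, electrode drift beyond a
linear term, or heart-rate variability beyond the stimulus drive — so
green tests certify the pipeline's mechanics, not field performance on
real recordings.

The system-identification layer replaces the intensity by the output of a
known polynomial NARX process (`TrueNarxProcess`) driven by feature
series, with the innovation term as equation error; recursions that
exceed a configurable bound abort with a diagnostic. For recovery
experiments, feature series are first-order-smoothed standardised noise,
and the raw process output is mapped to [0, 1] by one affine map shared
across a subject's trials (a per-trial min–max would change the
generating coefficients from trial to trial).

## Ground-truth experiments (desk scale)

Problem sizes follow the study protocol (7 analysed trials of 269
samples per subject) while search budgets are reduced: genetic algorithm
with population 24, ≤ 30 generations, stall window 12; wavelet units
disabled (the generating processes are polynomial, already inside the
regressor span — the unit stage is exercised separately by unit and
property tests).

**Parameter recovery.** One subject per replicate, 3 candidate features,
2 of which drive the intensity with delays n_k = 2 and 1 and moderate
innovation noise (set so the free-run correlation of the true structure
on held-out folds is ≈ 0.88). A landscape analysis motivated the design:
the correlation objective identifies delays *from above* (a window that
misses a true lag loses 0.03–0.14 of r) but only weakly from below (any
window covering the true lags ties within ~2 × 10⁻⁴, an O(p/n)
estimation penalty), so informative ±1 delay recovery requires true
delays near the n_k ≥ 1 bound, where the covering plateau is itself
within ±1. Inputs are smoothed over 1 s only, so neighbouring lags
decorrelate at the resolution being tested. Over 10 seeded replicates the
selection recovers the exact feature pair and both delays within ±1, with
held-out free-run r ≈ 0.88.

**Population comparison.** 15 subjects, each with their own generating
process (random feature pair out of 6 candidates, random lags within
[1, 6], random stable coefficients); both model families run their full
subject-level pipeline and the per-subject best mean correlations enter a
paired two-sided Wilcoxon signed-rank test. The lag range is reduced to
[1, 6] here purely to keep the experiment at desk scale.

**Intersubject.** Random 14/7 participant splits (98/49 trials), 10
repeats, one model per split. Two objective modes are implemented and
recorded in every result: *literal* (the genetic search maximises the
mean correlation over the test trials themselves — the historical
protocol, which leaks test data into the search and triggers an explicit
warning) and *holdout* (maximises on a validation split of the training
subjects, reports on the untouched test set — the honest default for new
work).

## Statistics

* Median and **unscaled** MAD (median absolute deviation about the
  median) summarise per-subject best correlations.
* Wilcoxon signed-rank: two-sided, zero differences dropped, exact null
  for n ≤ 25 without ties, normal approximation otherwise.
* Feature ranking counts a feature once per subject if it appears
  anywhere in that subject's final optimal set.
* Apriori: level-wise candidate generation with subset pruning; support =
  number of subjects whose optimal set contains the itemset; threshold 6
  subjects, itemsets up to size 3. Verified against brute-force
  enumeration.

## Reference tables

The published per-participant tables are shipped as TSV (stage-wise
optimal features and correlations per participant, model family and
quality; intersubject repeats with their optimised lag vectors). The
stage-wise lag parameters of the intrasubject tables were printed in a
concatenated form that is ambiguous to de-concatenate for values in
1–11, so the intrasubject fixtures carry features and correlations only;
the intersubject lag vectors are unambiguous and carried in full.
Regression tests assert that this package's own summary operations
reproduce the published medians, MADs, occurrence counts and the
no-frequent-pair Apriori outcome from those tables exactly.

## Known limitations

* The wavelet-network estimator reproduces the published functional form,
  but the original study's exact estimator is undocumented; unit shapes,
  candidate layout and the greedy fit are this package's own choices.
* Free-run vs one-step evaluation is resolved by internal consistency
  (see above), not by an explicit statement in the source analysis.
* Input delays are not identifiable from below under the correlation
  objective (covering-window plateau); reported n_k values should be read
  as "no later than", which also applies to the original analysis.
* The intersubject *literal* mode reproduces a protocol with test-set
  leakage; results from it are labelled and should not be compared
  against honest holdout numbers.
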
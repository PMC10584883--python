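# Methods

This document records what the pipeline computes, the parameter choices and
their rationale, and the known limitations. Notation: one *epoch* is 30 s;
stages are WK (wake), REM, N1, N2, N3 and LV ("out of bed", all channels
absent).

## 1. Synthetic signal model

A 6-state Markov chain over 30 s epochs produces the hypnogram (the chain
starts awake). Each scored stage carries a `StageProfile` of
stage-conditional statistics; the LV stage zeroes every channel and contains
no beats.

Beat-to-beat RR intervals are generated as

```
RRI(ms) = 60000 / HR(t) + A_RSA · sin(φ_resp(t) + θ(t))
```

where `HR(t)` is the stage mean plus a slow AR(1) wander (coefficient 0.999
per beat), `φ_resp` is the respiratory phase, and `θ(t)` is an
Ornstein–Uhlenbeck phase offset with a 3 s correlation time whose stationary
SD (`phase_jitter_sd`) sets the ground-truth coherence: 0 rad gives λ → 1,
larger values lower λ. The RSA term is evaluated at the interval midpoint by
a predictor–corrector step; evaluating it at the interval start would bias
the mean RRI by several milliseconds (sampling the positive half-wave more
densely in time). The respiratory frequency itself drifts as an OU process
clipped to the 0.05–0.6 Hz band; each record's *realized* mean HR and mean
respiratory frequency are stored in `bundle.meta`, and recovery is judged
against those realized values, not the nominal profile means — a single
night's realized mean legitimately deviates from the nominal because of the
wander.

EMG is unit-variance Gaussian baseline plus Poisson-timed movement bursts
(stage-dependent rate and amplitude). Movements are most frequent in wake,
rare in N3.

The default transition matrix is heavily self-persistent with physiological
structure (wake enters sleep through N1; N3 through N2; LV only from WK).
`balanced_transition_matrix()` is an alternative study condition whose 5×5
sleep block is doubly stochastic, giving a *uniform* stationary stage
distribution; see §4 for why chance-controlled experiments need it.

Defaults are study conditions, not physiological claims. They were chosen for
a qualitative stage ordering (coherence N3 ≈ N2 > N1 > WK > REM; movement
WK ≫ sleep; HR WK > REM > N1 > N2 > N3) with enough separation that the
features are learnable at desk scale.

## 2. Feature extraction (per 30 s epoch)

All four features are computed on 10 s windows sliding by 5 s (window *j*
centred at 5(j+1) s), median-filtered over the 6 window points spanning each
epoch (shrinking windows at the record edges), then averaged per epoch.

1. **RR-interval conditioning.** Intervals outside [300, 2000] ms, or
   jumping by more than 30% of the running median of the last 5 accepted
   intervals, are discarded. The cleaned tachogram is resampled to a uniform
   10 Hz grid by cubic-spline interpolation (values clipped to [200, 3000] ms
   as a spline-overshoot guard).
2. **HR** = mean of 60000/RRI(ms) over the window.
3. **Respiratory rate.** Respiration is band-passed 0.05–0.6 Hz
   (2nd-order Butterworth, zero-phase `filtfilt`), then a complex Morlet CWT
   (`cmor1.5-1.0`, 160 log-spaced frequencies across the band) is computed
   once for the record; each window's dominant frequency f_R is the peak of
   the wavelet power averaged over a 20 s span centred on the window
   (lowest-frequency peak on ties). Windows with no signal (e.g. LV) yield
   NaN and the last valid f_R is carried forward (starting value: the band
   centre, 0.325 Hz).
4. **Phase coherence λ.** The RSA waveform is the resampled tachogram
   band-passed to f_med ± 50%, where f_med is the record's global median
   f_R (a record-level band keeps the RSA filter stable across windows).
   With ψ = wrapped difference of the Hilbert instantaneous phases of RSA
   and filtered respiration,

   ```
   λ(t_k) = | (1/N) Σ_{i=k-N+1..k} exp(i ψ_i) |²,   N = 100 samples (10 s)
   ```

   evaluated at the window-end grid index. λ = 1 for perfect phase locking;
   E[λ] = 1/N for independent phases.
5. **Body-movement frequency (BMF).** EMG is band-passed 1–30 Hz, converted
   to a 0.5 s RMS envelope, and compared against 3× the median envelope of
   the baseline (excluding LV samples when a mask is available). A window is
   flagged if any envelope sample exceeds the threshold; BMF = flagged
   windows per second of epoch (flagged count / 30). The envelope form is
   deliberate: thresholding *raw samples* at 3× the baseline SD flags
   essentially every 10 s window of pure Gaussian noise
   (P(max of ~1280 samples > 3σ) ≈ 1), destroying the detector's
   specificity; the envelope rule keeps the same "3× baseline" spirit with
   zero false positives on noise. `count_movement_events` counts distinct
   envelope-exceedance runs (runs separated by < 1 s merge into one event)
   and recovers Poisson burst counts within 3σ.

LV epochs have all four features set to 0. `pad_lv` prepends and appends
exactly 4 zero-feature LV epochs per record so the network sees an explicit
"in bed starts/ends here" token.

## 3. Sequence classifier and training protocol

A bidirectional LSTM maps the per-epoch 4-vector sequence to 6 class
probabilities per epoch (softmax over WK, REM, N1, N2, N3, LV; LV is merged
into WK *after* prediction, at scoring time). Full-scale configuration:
3 biLSTM layers × 128 hidden units, inter-layer dropout 0.2. Training:
Adam, initial learning rate 1e-2 multiplied by 0.01 every 50 epochs, L2
regularization 0.1 on weight matrices, global L2 gradient-norm clipping at
2, one minibatch containing all training sequences (sorted by length, padded
to the longest, masked loss), at most 5000 epochs with early stopping when
the validation loss has not improved by 1e-5 for 50 epochs. Features are
z-scored with statistics from the training subjects only. The loss is the
mean cross-entropy over valid epochs, computed over all 6 outputs.

The implementation is pure NumPy (forward and backward passes verified
against numerical gradients to ≤ 5e-6 relative error); no deep-learning
framework is required. `StagerConfig.fast()` (1 layer, 32 units, ≤ 200
epochs) is the desk-scale profile used in the tests.

Leave-one-subject-out cross-validation trains one model per held-out
subject. The held-out subject also serves as the early-stopping validation
set — this mirrors a per-subject stopping protocol but is optimistic, since
the stopping criterion sees the evaluation subject; results should be read
as upper bounds. Fold seeds are derived from the subject id, and training
subjects are processed in canonical id order, so results are invariant to
cohort ordering.

## 4. Agreement metrics

Before scoring, LV is merged into WK and stages are encoded N3=1, N2=2,
N1=3, REM=4, WK=5. From the 5×5 confusion matrix, one-vs-rest tallies are
pooled over classes: S = ΣTP/(ΣTP+ΣFN), P = ΣTN/(ΣFP+ΣTN), and the three
headline scores are

```
balanced accuracy = (S + P) / 2
kappa             = S + P − 1
F1                = 2S / (2 + S − P)
```

These printed formulas are canonical here. Two caveats are intentional and
preserved: this "kappa" is the pooled Youden J, *not* the conventional
chance-corrected Cohen κ (which is exposed separately as `kappa_cohen`,
along with a conventional `f1_macro`); and under independent labels the
pooled kappa equals (5·Σ_c p_c q_c − 1)/4 for true/predicted marginals p, q
— it is zero for any q only when p is uniform. Chance-controlled
experiments (the shuffled-label control in the acceptance suite and
`scripts/acceptance.py`) therefore use the balanced transition matrix of §1.
Per-class scores apply the same three formulas to a single class's tallies;
empty tallies yield NaN with a warning rather than a silent 0.

## 5. Sleep parameters and method comparison

Per night (LV→WK, optionally dropping the 4+4 padded epochs): TIB = record
duration; TST = time in non-wake stages; SL = bedtime to first non-wake
epoch; WASO = TIB − SL − TST; REM% = REM time / TST (NREM% its complement);
SE = 100·TST/TIB. A night with no sleep yields TST 0, SL = TIB and NaN
REM%/NREM% with a warning.

Predicted-vs-reference agreement per parameter: Deming errors-in-variables
regression (closed-form sample-moment solution; `variance_ratio` → ∞
recovers ordinary least squares), Bland–Altman bias with 1.96·SD limits of
agreement, a Spearman rank test of difference vs mean for proportional bias,
and a paired t statistic as a descriptive. Parameters with fewer than 3
nights of defined values produce a NaN row with a warning instead of
aborting the table.

## 6. Numerical and design choices

- CWT via PyWavelets `cmor1.5-1.0`; the full-record transform with 20 s
  span-averaging is equivalent to windowed transforms but avoids per-window
  edge artefacts.
- Hilbert transforms and Butterworth filtering via SciPy; zero-phase
  filtering throughout so phases are not distorted.
- λ is computed by cumulative sums (O(n)); values are clipped to ≤ 1 against
  round-off.
- The biLSTM backward direction reverses each sequence *within its true
  length*, so padding never leaks into the recurrence.
- LSTM forget-gate biases initialize to 1 (standard recipe for gradient flow
  at the start of training).
- Argmax ties in prediction resolve to the lower class index,
  deterministically.
- All randomness flows from explicit integer seeds; derived seeds stay below
  2³¹. Cohort serialization is byte-stable for a fixed configuration.

## 7. Scope and limitations

- The generator is a test bench, not a physiological simulator: it encodes
  the qualitative stage structure the features assume and nothing more
  (no apnea events, no arousal microstructure, no ECG morphology — R-peak
  detection is out of scope and beats enter as interval lists).
- Headline numbers from the synthetic experiments characterize the
  *pipeline*, not clinical performance; they are reproducible at fixed seeds
  and stochastic across seeds.
- Early stopping on the held-out subject (§3) makes LOOCV scores optimistic.
- The EDF reader is optional and minimal (respiration + EMG channels plus a
  sidecar beats CSV); the CSV cohort layout is the canonical input path.
- Runtime targets one CPU at desk scale: feature extraction ≈ 1–2 s per
  subject-hour; the 12-subject × 2 h LOOCV experiment ≈ 2 minutes.
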
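# cardiostage

Five-class sleep staging (WK, REM, N1, N2, N3, per 30 s epoch) from four
cardiorespiratory parameters — heart rate, respiratory rate, cardiorespiratory
phase coherence and body-movement frequency — using a bidirectional LSTM
sequence classifier, plus the agreement statistics used to compare the
predicted hypnograms against a reference.

Clinical overnight recordings are not distributable, so the package ships a
synthetic signal generator with known ground truth (a Markov hypnogram driving
stage-conditional beat intervals, respiratory flow and leg EMG). The generator
is the test bench for the whole pipeline: every processing stage is validated
against the ground truth it was generated from.

## What's inside

| Module | Purpose |
|---|---|
| `cardiostage.synthetic` | Stage-labelled synthetic nights: Markov hypnogram, RR intervals with respiratory sinus arrhythmia (RSA), respiration, EMG bursts, "out of bed" (LV) gaps |
| `cardiostage.features` | Per-epoch features: HR, respiratory rate via complex-Morlet CWT, phase coherence λ between RSA and respiration (Hilbert phases, 100-sample windows), body-movement frequency from EMG |
| `cardiostage.stager` | Bidirectional LSTM classifier (pure NumPy: Adam, gradient clipping, stepped learning rate, early stopping), leave-one-subject-out cross-validation |
| `cardiostage.metrics` | Epoch-by-epoch agreement: pooled one-vs-rest accuracy/κ/F1, conventional Cohen κ and macro-F1 as diagnostics, per-class scores, cohort summaries |
| `cardiostage.sleepstats` | Per-night sleep parameters (TST, SL, WASO, REM%, NREM%, SE) and method agreement: Deming regression, Bland–Altman limits of agreement |
| `cardiostage.io` / `cardiostage.cli` | CSV/JSON/YAML formats, run manifests, optional EDF input, and the `cardiostage` command-line pipeline |

See `docs/methods.md` for the model equations, parameter choices and known
limitations.

## Quick start (command line)

Run the whole pipeline — simulate a cohort, extract features, leave-one-out
train/predict, score — with one command:

```bash
cardiostage all --seed 11 --out scratch/demo
```

This writes `metrics.json` (pooled and per-subject agreement),
`sleep_params.csv` and `agreement.json` under `scratch/demo/`. Individual
stages (`simulate`, `features`, `train`, `predict`, `loocv`, `evaluate`,
`sleep-params`, `agreement`) are also available; `cardiostage --help` lists
them. A YAML file passed via `--config` controls cohort size, stager
hyperparameters and seeds; unknown keys are rejected (exit code 2).

## Quick start (library)

```python
from cardiostage import (CohortConfig, simulate_cohort, compute_feature_epochs,
                         pad_lv, confusion_matrix, overall_metrics)
from cardiostage.features import feature_matrix
from cardiostage.stager import StagerConfig, loocv

cfg = CohortConfig(n_subjects=6, record_minutes=60, seed=7)
records = simulate_cohort(cfg)

feats, labels = [], []
for bundle, hyp in records:
    df = compute_feature_epochs(bundle, hyp)   # epoch, hr_bpm, rr_brpm, lambda, bmf_per_s
    padded, padded_hyp = pad_lv(df, hyp)       # 4 zeroed LV epochs each end
    feats.append(feature_matrix(padded))
    labels.append(padded_hyp)

pairs = loocv(feats, labels, StagerConfig.fast(seed=1))
true = [l for t, _ in pairs for l in t.labels]
pred = [l for _, p in pairs for l in p.labels]
print(overall_metrics(confusion_matrix(true, pred)))
```

`StagerConfig()` holds the full-scale training protocol (3 biLSTM layers,
128 hidden units, up to 5000 epochs); `StagerConfig.fast()` is the desk-scale
profile used throughout the tests.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds one test per release criterion (coherence
limits, ground-truth recovery, metric-formula oracles, cross-entropy closed
forms, end-to-end learning with a shuffled-label control, sleep-parameter
identities, agreement oracles, training-protocol traces). The full suite
takes a few minutes; the end-to-end fixture (12 subjects × 2 h, shared
session-wide) dominates the runtime.
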
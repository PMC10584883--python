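"""Synthetic overnight cardiorespiratory recordings with known sleep stages.

Generates stage-labelled nights (hypnogram + beat intervals + respiratory
flow + leg EMG) whose stage-conditional statistics follow the qualitative
structure the downstream analysis assumes: as non-REM sleep deepens, heart
rate and respiratory rate stabilise, cardiorespiratory phase locking
strengthens, and body movements become rare; in REM both rates fluctuate and
phase locking drops; wake shows the most movement.  "Getting out of bed"
(LV) periods zero every channel and contain no beats.

The generator is the ground truth for the whole test pyramid: single-stage
records verify feature recovery, jitter sweeps verify the coherence index,
and multi-subject cohorts train and validate the sequence classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, STAGES

_SLEEP_STAGES = ("WK", "REM", "N1", "N2", "N3")  # stages that carry a profile


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class StageProfile:
    """Stage-conditional signal statistics for one sleep stage.

    Parameters
    ----------
    mean_hr : beats/min.
    hr_wander_sd : beats/min — stationary SD of a slow AR(1) heart-rate
        drift (coefficient 0.999 at beat resolution).
    resp_freq : Hz — central respiratory frequency; must stay inside the
        0.05–0.6 Hz analysis band.
    resp_freq_jitter : Hz — stationary SD of a slow Ornstein–Uhlenbeck
        drift of the respiratory frequency, clipped to the band.
    rsa_amplitude : ms — peak respiratory modulation of the beat interval
        (respiratory sinus arrhythmia).
    phase_jitter_sd : rad — stationary SD of the slow RSA-vs-respiration
        phase-offset noise; 0 gives perfect phase locking (lambda → 1) and
        larger values lower the ground-truth coherence.
    movement_rate : events/min — Poisson rate of EMG movement bursts.
    movement_amp : multiples of the unit baseline EMG SD.
    """

    stage: str
    mean_hr: float
    hr_wander_sd: float
    resp_freq: float
    resp_freq_jitter: float
    rsa_amplitude: float
    phase_jitter_sd: float
    movement_rate: float
    movement_amp: float

    def __post_init__(self):
        if self.stage not in _SLEEP_STAGES:
            raise ConfigurationError(f"no profile allowed for stage {self.stage!r}")
        if not self.mean_hr > 0:
            raise ConfigurationError(f"{self.stage}: mean_hr must be > 0")
        if not (0.05 <= self.resp_freq <= 0.6):
            raise ConfigurationError(
                f"{self.stage}: resp_freq {self.resp_freq} outside the "
                "0.05-0.6 Hz respiration band"
            )
        if self.phase_jitter_sd < 0:
            raise ConfigurationError(f"{self.stage}: phase_jitter_sd must be >= 0")
        if self.movement_rate < 0:
            raise ConfigurationError(f"{self.stage}: movement_rate must be >= 0")


def default_profiles() -> dict[str, StageProfile]:
    """Stage profiles encoding the qualitative stage ordering.

    Coherence (via phase jitter): N3 ~ N2 > N1 > WK > REM; movement rate
    highest in WK; heart-rate wander highest in REM.  The numbers are
    configuration, not physiological claims.
    """
    return {
        "WK": StageProfile("WK", 70.0, 3.0, 0.27, 0.050, 20.0, 1.0, 3.0, 8.0),
        "REM": StageProfile("REM", 68.0, 4.0, 0.30, 0.060, 25.0, 1.5, 0.5, 6.0),
        "N1": StageProfile("N1", 64.0, 2.0, 0.28, 0.030, 30.0, 0.8, 1.0, 6.0),
        "N2": StageProfile("N2", 60.0, 1.0, 0.25, 0.015, 40.0, 0.3, 0.2, 5.0),
        "N3": StageProfile("N3", 56.0, 0.5, 0.23, 0.008, 50.0, 0.1, 0.05, 5.0),
    }


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic 30 s transition matrix over (WK, REM, N1, N2, N3, LV).

    Heavily self-persistent, wake enters sleep through N1, N3 is reached
    through N2, and LV (out of bed) is rare and entered only from WK.
    """
    return np.array(
        [
            #  WK    REM   N1    N2    N3    LV
            [0.92, 0.00, 0.06, 0.01, 0.00, 0.01],  # WK
            [0.03, 0.90, 0.04, 0.03, 0.00, 0.00],  # REM
            [0.05, 0.02, 0.80, 0.13, 0.00, 0.00],  # N1
            [0.02, 0.03, 0.03, 0.88, 0.04, 0.00],  # N2
            [0.01, 0.00, 0.00, 0.09, 0.90, 0.00],  # N3
            [0.15, 0.00, 0.00, 0.00, 0.00, 0.85],  # LV
        ]
    )


def balanced_transition_matrix() -> np.ndarray:
    """Row-stochastic matrix with a uniform stationary distribution over the
    five scored stages (LV is never entered).

    The 5x5 sleep-stage block is doubly stochastic (0.85 self-transition,
    the rest spread evenly), so each scored stage occupies ~20% of a long
    record.  Use this for chance-controlled evaluation experiments: the
    pipeline's pooled kappa equals (5 * sum_c p_c q_c - 1) / 4 under
    independent labels, which is exactly 0 for any prediction marginal q
    only when the true marginal p is uniform.
    """
    tm = np.zeros((6, 6))
    block = np.full((5, 5), 0.15 / 4) + (0.85 - 0.15 / 4) * np.eye(5)
    tm[:5, :5] = block
    tm[5, 0] = 1.0  # LV (never entered) returns to WK
    return tm


@dataclass
class CohortConfig:
    """Configuration for a synthetic cohort of overnight recordings."""

    n_subjects: int = 12
    record_minutes: float = 120.0
    epoch_seconds: int = 30
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    profiles: dict[str, StageProfile] = field(default_factory=default_profiles)
    emg_sampling_hz: float = 128.0
    resp_sampling_hz: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (6, 6):
            raise ConfigurationError("transition_matrix must be 6x6 over "
                                     f"{STAGES}")
        rowsum = self.transition_matrix.sum(axis=1)
        bad = np.nonzero(np.abs(rowsum - 1.0) > 1e-12)[0]
        if bad.size or (self.transition_matrix < 0).any():
            i = int(bad[0]) if bad.size else int(np.argmin(self.transition_matrix))
            raise ConfigurationError(
                f"transition_matrix row {i} ({STAGES[i]}) is not a "
                f"probability distribution (sum={rowsum[i]!r})"
            )
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.record_minutes < 2:
            raise ConfigurationError("record_minutes must be >= 2")
        if (self.record_minutes * 60) % self.epoch_seconds != 0:
            raise ConfigurationError("record duration must be a whole number of epochs")
        for s in _SLEEP_STAGES:
            if s not in self.profiles:
                raise ConfigurationError(f"missing StageProfile for stage {s}")


@dataclass
class SignalBundle:
    """Raw channels for one subject.

    ``rri[i]`` is the interval (ms) between ``beat_times[i]`` and
    ``beat_times[i+1]``.  ``lv_mask`` / ``lv_mask_emg`` flag samples inside
    LV epochs (all channels zero there, and no beats fall inside).
    """

    beat_times: np.ndarray          # s, strictly increasing
    rri: np.ndarray                 # ms, len == len(beat_times) - 1
    respiration: np.ndarray         # a.u. at resp_sampling_hz
    emg: np.ndarray                 # a.u. at emg_sampling_hz
    resp_sampling_hz: float
    emg_sampling_hz: float
    lv_mask: np.ndarray             # bool per respiration sample
    lv_mask_emg: np.ndarray         # bool per EMG sample
    meta: dict = field(default_factory=dict)


_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def simulate_hypnogram(config: CohortConfig, seed: int) -> Hypnogram:
    """Draw a Markov-chain stage sequence, one state per 30 s epoch.

    The chain starts in WK (lights off, subject awake) and is deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_epochs = int(round(config.record_minutes * 60 / config.epoch_seconds))
    P = config.transition_matrix
    states = np.empty(n_epochs, dtype=int)
    state = _STAGE_INDEX["WK"]
    for k in range(n_epochs):
        states[k] = state
        state = rng.choice(6, p=P[state])
    return Hypnogram(STAGES[s] for s in states)


def _ou_series(rng, n, sd, corr_samples):
    """Zero-mean Ornstein-Uhlenbeck path with stationary SD and correlation
    length in samples; returns zeros when sd == 0."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / max(corr_samples, 1e-9))
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - a * a)
    out = np.empty(n)
    x = rng.standard_normal() * sd
    for i in range(n):
        x = a * x + innov[i]
        out[i] = x
    return out


def simulate_signals(hypnogram: Hypnogram, config: CohortConfig, seed: int) -> SignalBundle:
    """Generate beat intervals, respiration and EMG for one hypnogram.

    The instantaneous beat interval is
    ``60000/mean_hr + slow AR(1) wander + rsa_amplitude * sin(resp phase +
    slow phase noise)``; respiration is a narrowband oscillation at the
    stage's frequency with slow drift; EMG is unit-SD Gaussian baseline plus
    Poisson-placed bursts.  Every channel is zero, and no beat falls, inside
    LV epochs.
    """
    rng = np.random.default_rng(seed)
    n_epochs = len(hypnogram)
    epoch_s = hypnogram.epoch_seconds
    duration = n_epochs * epoch_s
    profiles = config.profiles
    for lbl in set(hypnogram.labels) - {"LV"}:
        if lbl not in profiles:
            raise ConfigurationError(f"missing StageProfile for stage {lbl}")

    stage_of_epoch = list(hypnogram.labels)
    lv_epoch = np.array([s == "LV" for s in stage_of_epoch])

    # --- respiration at resp_sampling_hz ---------------------------------
    fs_r = config.resp_sampling_hz
    n_r = int(round(duration * fs_r))
    t_r = np.arange(n_r) / fs_r
    ep_r = np.minimum((t_r // epoch_s).astype(int), n_epochs - 1)
    f_base = np.array(
        [0.0 if lv_epoch[e] else profiles[stage_of_epoch[e]].resp_freq for e in range(n_epochs)]
    )[ep_r]
    jit_sd = np.array(
        [0.0 if lv_epoch[e] else profiles[stage_of_epoch[e]].resp_freq_jitter
         for e in range(n_epochs)]
    )[ep_r]
    # slow (20 s correlation) frequency drift, modulated per-sample by the
    # stage's jitter SD, clipped to the analysis band
    drift = _ou_series(rng, n_r, 1.0, 20.0 * fs_r)
    f_inst = np.clip(f_base + drift * jit_sd, 0.05, 0.6)
    phase_r = np.cumsum(2 * np.pi * f_inst / fs_r)
    respiration = np.sin(phase_r)
    lv_mask_r = lv_epoch[ep_r]
    respiration[lv_mask_r] = 0.0

    # --- beats ------------------------------------------------------------
    beat_times: list[float] = []
    # slow processes advanced per beat
    wander_ms = 0.0
    phase_off = 0.0
    a_w = 0.999
    t = float(rng.uniform(0, 0.5))  # first beat shortly after record start
    while t < duration:
        e = min(int(t // epoch_s), n_epochs - 1)
        if lv_epoch[e]:
            # skip to the end of the LV run; no beats while out of bed
            while e < n_epochs and lv_epoch[e]:
                e += 1
            if e >= n_epochs:
                break
            t = e * epoch_s + float(rng.uniform(0, 0.2))
            continue
        beat_times.append(t)
        p = profiles[stage_of_epoch[e]]
        rri_base = 60000.0 / p.mean_hr
        # convert the HR wander SD (bpm) to an RRI SD (ms) at this rate
        wander_sd_ms = 60000.0 * p.hr_wander_sd / p.mean_hr**2
        wander_ms = a_w * wander_ms + np.sqrt(1 - a_w * a_w) * wander_sd_ms * rng.standard_normal()
        # phase-offset noise decorrelating over ~3 s, i.e. within one 10 s
        # coherence window, so its SD sets the ground-truth lambda level
        rri_s_guess = rri_base / 1000.0
        a_p = np.exp(-rri_s_guess / 3.0)
        phase_off = a_p * phase_off + np.sqrt(max(1 - a_p * a_p, 0.0)) * p.phase_jitter_sd * rng.standard_normal()
        # evaluate the respiratory modulation at the interval midpoint
        # (predictor-corrector) so long intervals do not oversample the
        # positive half-wave and bias the mean interval
        guess = rri_base + wander_ms
        resp_phase_mid = np.interp(t + guess / 2000.0, t_r, phase_r)
        rri_ms = rri_base + wander_ms + p.rsa_amplitude * np.sin(resp_phase_mid + phase_off)
        rri_ms = max(rri_ms, 300.0)
        t = t + rri_ms / 1000.0
    beat_times_arr = np.asarray(beat_times)
    rri = np.diff(beat_times_arr) * 1000.0
    realized_hr = float(np.mean(60000.0 / rri)) if rri.size else float("nan")
    in_bed = ~lv_mask_r
    realized_f = float(np.mean(f_inst[in_bed])) if in_bed.any() else float("nan")

    # --- EMG --------------------------------------------------------------
    fs_e = config.emg_sampling_hz
    n_e = int(round(duration * fs_e))
    emg = rng.standard_normal(n_e)
    for e in range(n_epochs):
        if lv_epoch[e]:
            continue
        p = profiles[stage_of_epoch[e]]
        n_bursts = rng.poisson(p.movement_rate * epoch_s / 60.0)
        for _ in range(n_bursts):
            start = e * epoch_s + rng.uniform(0, epoch_s)
            dur = rng.uniform(0.5, 1.5)
            i0 = int(start * fs_e)
            i1 = min(int((start + dur) * fs_e), n_e)
            if i1 > i0:
                emg[i0:i1] += p.movement_amp * rng.standard_normal(i1 - i0)
    t_e = np.arange(n_e) / fs_e
    ep_e = np.minimum((t_e // epoch_s).astype(int), n_epochs - 1)
    lv_mask_e = lv_epoch[ep_e]
    emg[lv_mask_e] = 0.0

    return SignalBundle(
        beat_times=beat_times_arr,
        rri=rri,
        respiration=respiration,
        emg=emg,
        resp_sampling_hz=fs_r,
        emg_sampling_hz=fs_e,
        lv_mask=lv_mask_r,
        lv_mask_emg=lv_mask_e,
        meta={
            "seed": int(seed),
            # realized (path-level) ground truth for feature-recovery checks
            "realized_mean_hr_bpm": realized_hr,
            "realized_mean_resp_freq_hz": realized_f,
        },
    )


def _subject_seed(base_seed: int, subject_id: int) -> int:
    return int((base_seed * 1_000_003 + 2 * subject_id + 1) % (2**31))


def simulate_cohort(config: CohortConfig) -> list[tuple[SignalBundle, Hypnogram]]:
    """Simulate ``n_subjects`` independent nights.

    Per-subject seeds derive deterministically from ``config.seed``; each
    subject's metadata carries a synthetic apnea-severity scalar (an
    AHI-like covariate label, never used by the signal model).
    """
    records = []
    for s in range(config.n_subjects):
        seed = _subject_seed(config.seed, s)
        hyp = simulate_hypnogram(config, seed)
        bundle = simulate_signals(hyp, config, seed + 1)
        sev_rng = np.random.default_rng(seed + 2)
        bundle.meta.update(
            subject_id=s,
            seed=seed,
            ahi_like_severity=float(np.round(sev_rng.lognormal(np.log(20.0), 0.8), 2)),
        )
        records.append((bundle, hyp))
    return records


# --------------------------------------------------------------------------
# on-disk layout: one directory per subject + cohort manifest
# --------------------------------------------------------------------------

def write_subject(bundle: SignalBundle, hypnogram: Hypnogram, outdir: str | Path) -> None:
    """Write one subject as beats.csv / resp.csv / emg.csv / hypnogram.txt /
    meta.json. ``beats.csv`` rows are (time_s of the interval-ending beat,
    rri_ms)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": bundle.beat_times[1:], "rri_ms": bundle.rri}).to_csv(
        outdir / "beats.csv", index=False
    )
    pd.DataFrame({"value": bundle.respiration}).to_csv(outdir / "resp.csv", index=False)
    pd.DataFrame({"value": bundle.emg}).to_csv(outdir / "emg.csv", index=False)
    from .hypnogram import write_hypnogram

    write_hypnogram(hypnogram, outdir / "hypnogram.txt")
    meta = dict(bundle.meta)
    meta.update(
        resp_sampling_hz=bundle.resp_sampling_hz,
        emg_sampling_hz=bundle.emg_sampling_hz,
        n_epochs=len(hypnogram),
    )
    with open(outdir / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_subject(subjdir: str | Path) -> tuple[SignalBundle, Hypnogram]:
    """Read one subject directory written by :func:`write_subject`."""
    from .hypnogram import read_hypnogram

    subjdir = Path(subjdir)
    beats = pd.read_csv(subjdir / "beats.csv")
    with open(subjdir / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    rri = beats["rri_ms"].to_numpy()
    end_times = beats["time_s"].to_numpy()
    beat_times = np.concatenate([[end_times[0] - rri[0] / 1000.0], end_times])
    resp = pd.read_csv(subjdir / "resp.csv")["value"].to_numpy()
    emg = pd.read_csv(subjdir / "emg.csv")["value"].to_numpy()
    hyp = read_hypnogram(subjdir / "hypnogram.txt")
    lv_epoch = np.array([s == "LV" for s in hyp.labels])
    fs_r = float(meta["resp_sampling_hz"])
    fs_e = float(meta["emg_sampling_hz"])
    ep_r = np.minimum((np.arange(len(resp)) / fs_r // hyp.epoch_seconds).astype(int), len(hyp) - 1)
    ep_e = np.minimum((np.arange(len(emg)) / fs_e // hyp.epoch_seconds).astype(int), len(hyp) - 1)
    bundle = SignalBundle(
        beat_times=beat_times,
        rri=rri,
        respiration=resp,
        emg=emg,
        resp_sampling_hz=fs_r,
        emg_sampling_hz=fs_e,
        lv_mask=lv_epoch[ep_r],
        lv_mask_emg=lv_epoch[ep_e],
        meta=meta,
    )
    return bundle, hyp


def write_cohort(records, outdir: str | Path) -> None:
    """Write a cohort as subject_000/, subject_001/, ... plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (bundle, hyp) in enumerate(records):
        name = f"subject_{i:03d}"
        write_subject(bundle, hyp, outdir / name)
        names.append(name)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"subjects": names}, fh, indent=1)
        fh.write("\n")


def read_cohort(cohort_dir: str | Path) -> list[tuple[SignalBundle, Hypnogram]]:
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return [read_subject(cohort_dir / name) for name in manifest["subjects"]]
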
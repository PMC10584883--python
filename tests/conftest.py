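"""Shared fixtures: synthetic study conditions reused across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from cardiostage import (
    CohortConfig,
    StageProfile,
    default_profiles,
    simulate_cohort,
    simulate_hypnogram,
    simulate_signals,
    compute_feature_epochs,
    pad_lv,
)
from cardiostage.features import feature_matrix
from cardiostage.hypnogram import STAGES
from cardiostage.stager import StagerConfig, loocv
from cardiostage.synthetic import SignalBundle, balanced_transition_matrix

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def absorbing_matrix(stage: str) -> np.ndarray:
    """Transition matrix that jumps to ``stage`` and stays there."""
    tm = np.zeros((6, 6))
    tm[:, STAGE_INDEX[stage]] = 1.0
    return tm


def single_stage_config(stage: str, minutes: float = 30.0, seed: int = 5,
                        **profile_overrides) -> CohortConfig:
    """Single-stage record config (first epoch is WK: the chain starts awake)."""
    profiles = default_profiles()
    if profile_overrides:
        profiles[stage] = dataclasses.replace(profiles[stage], **profile_overrides)
    return CohortConfig(
        n_subjects=1, record_minutes=minutes,
        transition_matrix=absorbing_matrix(stage),
        profiles=profiles, seed=seed,
    )


def simulate_single_stage(stage: str, minutes: float = 30.0, seed: int = 5,
                          **profile_overrides):
    cfg = single_stage_config(stage, minutes=minutes, seed=seed, **profile_overrides)
    hyp = simulate_hypnogram(cfg, seed)
    bundle = simulate_signals(hyp, cfg, seed + 1)
    return bundle, hyp


def make_bundle(rri_ms: np.ndarray, resp: np.ndarray, emg: np.ndarray,
                fs_resp: float = 10.0, fs_emg: float = 128.0,
                t0: float = 0.3) -> SignalBundle:
    """Hand-built bundle from explicit channel arrays (no LV anywhere)."""
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(rri_ms) / 1000.0])
    return SignalBundle(
        beat_times=beat_times, rri=np.asarray(rri_ms, dtype=float),
        respiration=np.asarray(resp, dtype=float), emg=np.asarray(emg, dtype=float),
        resp_sampling_hz=fs_resp, emg_sampling_hz=fs_emg,
        lv_mask=np.zeros(len(resp), dtype=bool),
        lv_mask_emg=np.zeros(len(emg), dtype=bool),
    )


@pytest.fixture(scope="session")
def loocv_experiment():
    """Scaled-down end-to-end study: 12 synthetic subjects of 2 h each,
    default stage profiles, desk-scale stager, leave-one-subject-out.

    Uses the balanced (uniform-stationary) transition matrix so the pooled
    kappa of any label-shuffled control is chance-centred at 0 — the pooled
    formula is only chance-corrected under a uniform true-stage marginal.

    Computed once per session; returns the padded feature/label cohort and
    the per-subject (true, predicted) hypnogram pairs.
    """
    cfg = CohortConfig(n_subjects=12, record_minutes=120.0, seed=20,
                       transition_matrix=balanced_transition_matrix())
    records = simulate_cohort(cfg)
    feats, labels = [], []
    for bundle, hyp in records:
        df = compute_feature_epochs(bundle, hyp)
        padded, padded_hyp = pad_lv(df, hyp)
        feats.append(feature_matrix(padded))
        labels.append(padded_hyp)
    pairs = loocv(feats, labels, StagerConfig.fast(seed=1))
    return {"features": feats, "labels": labels, "pairs": pairs,
            "records": records}
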
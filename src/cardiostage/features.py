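"""Epoch-aligned physiological features: HR, RR, phase coherence, movement.

Processing chain, per overnight record:

1.  Beat intervals are screened for artifacts, cubic-spline resampled onto a
    uniform 10 Hz grid, and converted to heart rate (HR = 60000/RRI).
2.  Respiration is band-passed 0.05-0.6 Hz (2nd-order Butterworth, applied
    forward and backward for zero phase).  The respiratory frequency f_R of
    each window is the dominant peak of a complex-Morlet wavelet power
    spectrum averaged over a 20 s span; RR = 60 f_R.
3.  Respiratory sinus arrhythmia (RSA) is the 10 Hz RRI series band-passed
    to +/-50 % of the dominant respiratory frequency.  Instantaneous phases
    of RSA and respiration come from the analytic (Hilbert) signal, and the
    phase-coherence index

        lambda(t_k) = | (1/N) sum_{j} exp(i psi_j) |^2,

    with psi the wrapped RSA-respiration phase difference and N = 100
    trailing samples (10 s at 10 Hz), measures how invariant the phase
    relation is: 1 for perfect locking, ~1/N for independent phases.
4.  Leg EMG is band-passed 1-30 Hz and normalised by a robust baseline
    scale; a 10 s window counts as one body movement when its short-time
    amplitude exceeds 3x baseline.

All four parameters are computed on 10 s windows sliding by 5 s, smoothed
with a 30 s (6-point) median filter, and aggregated to one row per 30 s
epoch (mean of the six 5 s points; movement windows per epoch / 30 s for
BMF).  LV ("out of bed") epochs yield all-zero feature rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, hilbert

from .hypnogram import Hypnogram
from .synthetic import SignalBundle

#: canonical feature-table column order
FEATURE_COLUMNS = ("epoch", "hr_bpm", "rr_brpm", "lambda", "bmf_per_s")

RESP_BAND = (0.05, 0.6)          # Hz, respiration analysis band
GRID_HZ = 10.0                   # uniform RRI/respiration grid
LAMBDA_WINDOW = 100              # samples: 10 s at 10 Hz
WINDOW_S = 10.0                  # parameter window
SLIDE_S = 5.0                    # window slide
EPOCH_S = 30.0
_BAND_CENTER = 0.5 * (RESP_BAND[0] + RESP_BAND[1])  # fallback f_R


# -------------------------------------------------------------------------
# beat intervals
# -------------------------------------------------------------------------

def clean_rri(beat_times: np.ndarray, rri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Automated artifact screen replacing manual outlier inspection.

    An interval is rejected when it lies outside the physiological range
    [300, 2000] ms or deviates more than 30 % from the median of the five
    previously accepted intervals.  ``beat_times`` are the interval-ending
    beat times (one per interval), returned filtered alongside the
    surviving intervals.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rri = np.asarray(rri, dtype=float)
    if beat_times.shape != rri.shape:
        raise ValueError("beat_times and rri must have equal length (one time per interval)")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    keep = np.zeros(rri.size, dtype=bool)
    accepted: list[float] = []
    for i, r in enumerate(rri):
        if not (300.0 <= r <= 2000.0):
            continue
        if len(accepted) >= 1:
            ref = float(np.median(accepted[-5:]))
            if abs(r - ref) > 0.30 * ref:
                continue
        keep[i] = True
        accepted.append(r)
    if keep.sum() < 2:
        raise ValueError("insufficient beats after artifact screening")
    return beat_times[keep], rri[keep]


def resample_rri(beat_times: np.ndarray, rri: np.ndarray,
                 t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cubic-spline resample the beat-interval series onto a 10 Hz grid.

    Knots are (interval-ending beat time, interval).  By default the grid
    spans [first, last] knot; a caller-supplied grid (e.g. the whole-record
    grid) is evaluated with spline extrapolation at the edges.  Returns a
    frame with columns t, rri (ms) and hr (= 60000/rri, beats/min).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rri = np.asarray(rri, dtype=float)
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if beat_times.size < 4:
        raise ValueError("need >= 4 beats for cubic-spline resampling")
    spline = CubicSpline(beat_times, rri, extrapolate=True)
    if t_grid is None:
        n = int(np.floor((beat_times[-1] - beat_times[0]) * GRID_HZ)) + 1
        t_grid = beat_times[0] + np.arange(n) / GRID_HZ
    vals = spline(t_grid)
    vals = np.clip(vals, 200.0, 3000.0)  # guard spline overshoot at edges
    return pd.DataFrame({"t": t_grid, "rri": vals, "hr": 60000.0 / vals})


# -------------------------------------------------------------------------
# respiration
# -------------------------------------------------------------------------

def _bandpass(x, fs, lo, hi, order=2):
    b, a = butter(order, [lo, hi], btype="bandpass", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"signal too short for filtering (need > {padlen} samples)")
    return filtfilt(b, a, x)


def filter_respiration(resp: np.ndarray, fs: float) -> np.ndarray:
    """2nd-order Butterworth band-pass 0.05-0.6 Hz, forward-backward
    (zero net phase shift)."""
    if fs < 2.0:
        raise ValueError("respiration sampling rate must be >= 2 Hz")
    return _bandpass(np.asarray(resp, dtype=float), fs, *RESP_BAND)


_CWT_WAVELET = "cmor1.5-1.0"     # complex Morlet, bandwidth 1.5, center 1.0
_N_CWT_FREQS = 160


def _cwt_frequencies() -> np.ndarray:
    return np.geomspace(RESP_BAND[0], RESP_BAND[1], _N_CWT_FREQS)


def _cwt_power(resp_filtered: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Complex-Morlet wavelet power |W(f, t)|^2 on a log frequency grid
    spanning the respiration band.  Returns (freqs, power[freq, time])."""
    freqs = _cwt_frequencies()
    fc = pywt.central_frequency(_CWT_WAVELET)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(resp_filtered, scales, _CWT_WAVELET,
                       sampling_period=1.0 / fs, method="fft")
    return freqs, np.abs(coef) ** 2


def estimate_resp_frequency(resp_window: np.ndarray, fs: float) -> float:
    """Dominant respiratory frequency of one (nominally 20 s) window.

    The wavelet power spectrum is averaged over time and the frequency of
    its maximum returned (ties broken toward the lowest frequency).  An
    all-zero window has no spectral peak and returns NaN (flagged missing).
    """
    resp_window = np.asarray(resp_window, dtype=float)
    if not np.any(resp_window):
        return float("nan")
    freqs, power = _cwt_power(resp_window, fs)
    mean_power = power.mean(axis=1)
    return float(freqs[int(np.argmax(mean_power))])  # argmax: first (lowest) max


# -------------------------------------------------------------------------
# RSA and phase coherence
# -------------------------------------------------------------------------

def extract_rsa(rri_resampled: pd.DataFrame, f_r: float) -> np.ndarray:
    """Band-pass the 10 Hz RRI series to +/-50 % of the respiratory
    frequency, isolating the respiratory sinus arrhythmia."""
    if not f_r > 0:
        raise ValueError("respiratory frequency must be positive")
    lo, hi = 0.5 * f_r, 1.5 * f_r
    if hi >= GRID_HZ / 2:
        raise ValueError("RSA band reaches the 5 Hz Nyquist limit")
    return _bandpass(rri_resampled["rri"].to_numpy(), GRID_HZ, lo, hi)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a zero-mean narrowband signal via the
    analytic signal (signal + i * Hilbert transform), wrapped to (-pi, pi]."""
    return np.angle(hilbert(np.asarray(x, dtype=float)))


def wrap_phase(psi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(psi), 2 * np.pi)


def phase_coherence(psi: np.ndarray, n_window: int = LAMBDA_WINDOW) -> np.ndarray:
    """Trailing-window phase-coherence index lambda.

    ``lambda[k] = |mean(exp(i psi[k-N+1 .. k]))|^2`` over the trailing N
    samples; entries before the first full window are NaN.  Always in
    [0, 1]: 1 for a constant phase difference, ~1/N for independent phases.
    """
    psi = np.asarray(psi, dtype=float)
    if n_window < 2:
        raise ValueError("n_window must be >= 2")
    if n_window > psi.size:
        raise ValueError("window longer than the phase series")
    z = np.exp(1j * psi)
    csum = np.concatenate([[0.0 + 0.0j], np.cumsum(z)])
    means = (csum[n_window:] - csum[:-n_window]) / n_window
    lam = np.full(psi.size, np.nan)
    lam[n_window - 1:] = np.minimum(np.abs(means) ** 2, 1.0)
    return lam


# -------------------------------------------------------------------------
# EMG body movements
# -------------------------------------------------------------------------

EMG_BAND = (1.0, 30.0)
_MOVEMENT_THRESHOLD = 3.0
_ENVELOPE_S = 0.5                # short-time RMS length


def _emg_envelope(emg: np.ndarray, fs: float) -> np.ndarray:
    filtered = _bandpass(np.asarray(emg, dtype=float), fs, *EMG_BAND)
    w = max(int(round(_ENVELOPE_S * fs)), 1)
    kernel = np.ones(w) / w
    return np.sqrt(np.convolve(filtered**2, kernel, mode="same"))


def detect_body_movements(emg: np.ndarray, fs: float,
                          n_windows: int | None = None,
                          baseline_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-10 s-window (5 s slide) binary movement indicator.

    The EMG is band-passed 1-30 Hz and reduced to a 0.5 s short-time RMS
    amplitude.  The baseline amplitude scale is estimated robustly as the
    median envelope (optionally excluding masked, e.g. out-of-bed, samples)
    — insensitive to sparse bursts.  A window scores 1 when any amplitude
    sample inside it exceeds 3x that baseline, else 0.
    """
    if fs <= 60.0:
        raise ValueError("EMG sampling rate must exceed 60 Hz (30 Hz band edge)")
    env = _emg_envelope(emg, fs)
    base = env if baseline_mask is None else env[~np.asarray(baseline_mask, bool)]
    base = base[base > 0]
    scale = float(np.median(base)) if base.size else 1.0
    if scale <= 0:
        scale = 1.0
    exceeded = env > _MOVEMENT_THRESHOLD * scale
    duration = len(emg) / fs
    if n_windows is None:
        n_windows = max(int(np.floor(duration / SLIDE_S)) - 1, 0)
    out = np.zeros(n_windows, dtype=int)
    for j in range(n_windows):
        c = SLIDE_S * (j + 1)
        i0 = max(int((c - WINDOW_S / 2) * fs), 0)
        i1 = min(int((c + WINDOW_S / 2) * fs), len(emg))
        if i1 > i0 and np.any(exceeded[i0:i1]):
            out[j] = 1
    return out


def count_movement_events(emg: np.ndarray, fs: float,
                          baseline_mask: np.ndarray | None = None,
                          merge_gap_s: float = 1.0) -> int:
    """Number of distinct movement events in an EMG trace.

    Uses the same envelope-threshold rule as :func:`detect_body_movements`
    but counts sample-level exceedance runs, merging runs separated by less
    than ``merge_gap_s`` (a burst briefly dipping under threshold is one
    movement, not two).
    """
    if fs <= 60.0:
        raise ValueError("EMG sampling rate must exceed 60 Hz (30 Hz band edge)")
    env = _emg_envelope(emg, fs)
    base = env if baseline_mask is None else env[~np.asarray(baseline_mask, bool)]
    base = base[base > 0]
    scale = float(np.median(base)) if base.size else 1.0
    exceeded = env > _MOVEMENT_THRESHOLD * max(scale, 1e-12)
    if not exceeded.any():
        return 0
    idx = np.nonzero(exceeded)[0]
    gaps = np.diff(idx) > merge_gap_s * fs
    return int(1 + gaps.sum())


# -------------------------------------------------------------------------
# epoch alignment
# -------------------------------------------------------------------------

def _median_filter_shrink(x: np.ndarray, size: int = 6) -> np.ndarray:
    """Running median with a 6-point window centered as [i-2, i+3), the
    window shrinking at the series edges."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    n = x.size
    for i in range(n):
        lo = max(i - (size // 2 - 1), 0)
        hi = min(i + size // 2 + 1, n)
        seg = x[lo:hi]
        valid = seg[np.isfinite(seg)]
        out[i] = np.median(valid) if valid.size else np.nan
    return out


def compute_feature_epochs(bundle: SignalBundle,
                           hypnogram: Hypnogram | None = None) -> pd.DataFrame:
    """Full feature chain: one row (HR, RR, lambda, BMF) per 30 s epoch.

    Windows are 10 s sliding by 5 s (centers at 5k+5 s); HR/RR/lambda window
    series are median-filtered over 30 s (6 points) and averaged within each
    epoch's six points; BMF is the epoch's movement-window count / 30 s.
    When a hypnogram is supplied its length fixes the epoch count and LV
    epochs are zeroed; the RSA band uses the median respiratory frequency
    over in-bed windows.
    """
    fs_r = bundle.resp_sampling_hz
    if hypnogram is not None:
        n_epochs = len(hypnogram)
    else:
        n_epochs = int(np.floor(len(bundle.respiration) / fs_r / EPOCH_S))
    duration = n_epochs * EPOCH_S
    if len(bundle.respiration) / fs_r < duration - 1e-9:
        raise ValueError(
            f"respiration covers {len(bundle.respiration) / fs_r:.1f} s but the "
            f"hypnogram spans {duration:.1f} s"
        )
    n_windows = 6 * n_epochs
    centers = SLIDE_S * (np.arange(n_windows) + 1)

    lv_epochs = (np.array([s == "LV" for s in hypnogram.labels])
                 if hypnogram is not None else np.zeros(n_epochs, dtype=bool))

    # ---- HR on the record-wide 10 Hz grid --------------------------------
    bt, rr_ms = clean_rri(bundle.beat_times[1:], bundle.rri)
    t_grid = np.arange(int(round(duration * GRID_HZ))) / GRID_HZ
    res = resample_rri(bt, rr_ms, t_grid=t_grid)
    hr_series = res["hr"].to_numpy()

    # ---- respiration: filter once, wavelet power once --------------------
    resp = np.asarray(bundle.respiration, dtype=float)[: int(round(duration * fs_r))]
    resp_f = filter_respiration(resp, fs_r)
    freqs, power = _cwt_power(resp_f, fs_r)

    window_lv = np.repeat(lv_epochs, 6)

    f_r = np.full(n_windows, np.nan)
    hr_win = np.full(n_windows, np.nan)
    for j, c in enumerate(centers):
        # 20 s wavelet-analysis span centered on the 10 s parameter window
        a0 = max(int((c - WINDOW_S) * fs_r), 0)
        a1 = min(int((c + WINDOW_S) * fs_r), power.shape[1])
        raw0 = max(int((c - WINDOW_S) * fs_r), 0)
        if a1 > a0 and np.any(resp[raw0:a1]):
            mp = power[:, a0:a1].mean(axis=1)
            f_r[j] = freqs[int(np.argmax(mp))]
        i0 = max(int((c - WINDOW_S / 2) * GRID_HZ), 0)
        i1 = min(int((c + WINDOW_S / 2) * GRID_HZ), hr_series.size)
        hr_win[j] = hr_series[i0:i1].mean() if i1 > i0 else np.nan

    # carry-forward for missing (flat-window) respiratory rates
    last = _BAND_CENTER
    f_r_filled = np.empty(n_windows)
    for j in range(n_windows):
        if np.isfinite(f_r[j]):
            last = f_r[j]
        f_r_filled[j] = last
    rr_win = 60.0 * f_r_filled

    # ---- RSA + phase coherence ------------------------------------------
    valid_fr = f_r[np.isfinite(f_r) & ~window_lv]
    f_dom = float(np.median(valid_fr)) if valid_fr.size else _BAND_CENTER
    rsa = extract_rsa(res, f_dom)
    if fs_r != GRID_HZ:
        # bring respiration onto the common 10 Hz grid for the phase pair
        t_resp = np.arange(resp_f.size) / fs_r
        resp_10 = np.interp(t_grid, t_resp, resp_f)
    else:
        resp_10 = resp_f[: t_grid.size]
    psi = wrap_phase(instantaneous_phase(rsa) - instantaneous_phase(resp_10))
    lam_series = phase_coherence(psi, LAMBDA_WINDOW)
    lam_win = np.full(n_windows, np.nan)
    for j, c in enumerate(centers):
        k = min(int((c + WINDOW_S / 2) * GRID_HZ) - 1, lam_series.size - 1)
        if k >= LAMBDA_WINDOW - 1:
            lam_win[j] = lam_series[k]
        else:
            lam_win[j] = lam_series[LAMBDA_WINDOW - 1]

    # ---- EMG movements ---------------------------------------------------
    emg = np.asarray(bundle.emg, dtype=float)[: int(round(duration * bundle.emg_sampling_hz))]
    moves = detect_body_movements(
        emg, bundle.emg_sampling_hz, n_windows=n_windows,
        baseline_mask=bundle.lv_mask_emg[: emg.size] if bundle.lv_mask_emg is not None else None,
    )

    # ---- 30 s median smoothing + epoch aggregation ----------------------
    hr_s = _median_filter_shrink(hr_win)
    rr_s = _median_filter_shrink(rr_win)
    lam_s = _median_filter_shrink(lam_win)

    rows = []
    for k in range(n_epochs):
        sl = slice(6 * k, 6 * k + 6)
        if lv_epochs[k]:
            rows.append((k, 0.0, 0.0, 0.0, 0.0))
            continue
        rows.append((
            k,
            float(np.nanmean(hr_s[sl])),
            float(np.nanmean(rr_s[sl])),
            float(np.nanmean(lam_s[sl])),
            float(np.sum(moves[sl]) / EPOCH_S),
        ))
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    if hypnogram is not None:
        df["stage"] = list(hypnogram.labels)
    if len(df) != n_epochs:
        raise RuntimeError(f"alignment failure: expected {n_epochs} rows, got {len(df)}")
    return df


def pad_lv(features: pd.DataFrame, labels: Hypnogram) -> tuple[pd.DataFrame, Hypnogram]:
    """Prepend and append four all-zero LV epochs to features and labels.

    Gives the sequence model explicit examples of the minority "out of bed"
    class at both record ends; the added rows carry zero features.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must be aligned before padding")
    pad = pd.DataFrame(0.0, index=range(4), columns=[c for c in features.columns if c != "stage"])
    if "stage" in features.columns:
        pad["stage"] = "LV"
    out = pd.concat([pad, features, pad], ignore_index=True)
    out["epoch"] = np.arange(len(out))
    new_labels = Hypnogram(("LV",) * 4 + tuple(labels.labels) + ("LV",) * 4,
                           labels.epoch_seconds)
    return out, new_labels


def feature_matrix(features: pd.DataFrame) -> np.ndarray:
    """(n_epochs, 4) float array in the canonical order HR, RR, lambda, BMF."""
    return features[["hr_bpm", "rr_brpm", "lambda", "bmf_per_s"]].to_numpy(dtype=float)
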
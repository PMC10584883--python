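"""Sleep parameters from hypnograms and method-agreement statistics.

Sleep parameters per night (30 s epochs, LV merged into WK, optional
removal of the 4+4 padded LV epochs):

    TIB   time in bed                = record duration
    TST   total sleep time           = time in any non-wake stage
    SL    sleep latency              = bedtime to first non-wake epoch
    WASO  wake after sleep onset     = TIB - SL - TST
    REM%  REM time as % of TST, NREM% its complement
    SE    sleep efficiency           = 100 * TST / TIB

Agreement between predicted and reference parameters uses Deming
(errors-in-variables) regression, Bland-Altman bias with 1.96-SD limits of
agreement, and a Spearman rank test of difference vs mean for proportional
bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram import Hypnogram


@dataclass(frozen=True)
class SleepParameters:
    tib: float        # min
    tst: float        # min
    sl: float         # min
    waso: float       # min
    rem_pct: float    # % of TST
    nrem_pct: float   # % of TST
    se: float         # %

    def as_dict(self) -> dict[str, float]:
        return {"tib": self.tib, "tst": self.tst, "sl": self.sl,
                "waso": self.waso, "rem_pct": self.rem_pct,
                "nrem_pct": self.nrem_pct, "se": self.se}


@dataclass(frozen=True)
class AgreementResult:
    deming_slope: float
    deming_intercept: float
    pearson_r: float
    bias: float           # mean(predicted - reference)
    loa_lower: float      # bias - 1.96 SD
    loa_upper: float      # bias + 1.96 SD
    spearman_rho: float
    spearman_p: float


PARAMETER_NAMES = ("tst", "sl", "waso", "rem_pct", "nrem_pct", "se")


def sleep_parameters(hypnogram: Hypnogram, strip_padding: bool = False) -> SleepParameters:
    """Derive the six sleep parameters from one hypnogram.

    ``strip_padding`` removes the four LV epochs added at each record end
    before scoring.  Bedtime is the first remaining epoch; sleep onset is
    the first epoch scored as any non-wake stage.  A night with no sleep at
    all yields TST 0, SL = TIB and undefined REM%/NREM% (NaN).
    """
    labels = list(hypnogram.labels)
    if strip_padding:
        if len(labels) <= 8:
            raise ValueError("hypnogram empty after removing 4+4 padded epochs")
        labels = labels[4:-4]
    if not labels:
        raise ValueError("empty hypnogram")
    labels = ["WK" if l == "LV" else l for l in labels]
    ep_min = hypnogram.epoch_seconds / 60.0

    n = len(labels)
    tib = n * ep_min
    sleep = [l != "WK" for l in labels]
    n_sleep = sum(sleep)
    tst = n_sleep * ep_min
    if n_sleep == 0:
        warnings.warn("no sleep epochs: REM%/NREM% undefined", stacklevel=2)
        return SleepParameters(tib=tib, tst=0.0, sl=tib, waso=0.0,
                               rem_pct=float("nan"), nrem_pct=float("nan"), se=0.0)
    onset = sleep.index(True)
    sl = onset * ep_min
    waso = tib - sl - tst
    n_rem = sum(1 for l in labels if l == "REM")
    rem_pct = 100.0 * n_rem / n_sleep
    return SleepParameters(
        tib=tib, tst=tst, sl=sl, waso=waso,
        rem_pct=rem_pct, nrem_pct=100.0 - rem_pct,
        se=100.0 * tst / tib,
    )


def deming_regression(x, y, variance_ratio: float = 1.0) -> tuple[float, float]:
    """Errors-in-variables straight-line fit of y on x.

    ``variance_ratio`` = var(y errors) / var(x errors); 1 gives orthogonal
    regression, and the limit -> infinity recovers ordinary least squares.
    Returns (slope, intercept) from the closed-form sample-moment solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        if syy == variance_ratio * sxx:
            raise ValueError("Deming slope undefined: zero covariance with "
                             "equal (scaled) variances")
        # degenerate: the line is vertical or horizontal; report slope 0/inf
        if syy < variance_ratio * sxx:
            return 0.0, float(np.mean(y))
        raise ValueError("Deming slope undefined (vertical line)")
    d = variance_ratio
    slope = (syy - d * sxx + np.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of y (predicted) against x (reference).

    bias = mean(y - x); limits of agreement = bias +/- 1.96 * sample SD of
    the differences; the Spearman rank correlation of difference vs mean
    tests for proportional bias.  Deming/Pearson fields are filled too so
    one call yields the complete agreement panel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    diff = y - x
    mean_xy = 0.5 * (x + y)
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.ptp(diff) == 0 or np.ptp(mean_xy) == 0:
        warnings.warn("constant differences or means: proportional-bias "
                      "test undefined", stacklevel=2)
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(mean_xy, diff)
    try:
        slope, intercept = deming_regression(x, y)
    except ValueError:
        slope, intercept = float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y)[0])
    return AgreementResult(
        deming_slope=slope, deming_intercept=intercept, pearson_r=r,
        bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        spearman_rho=float(rho), spearman_p=float(pval),
    )


def compare_sleep_parameters(pairs, strip_padding: bool = False) -> pd.DataFrame:
    """Per-parameter agreement table between reference and predicted nights.

    ``pairs``: list of (reference Hypnogram, predicted Hypnogram).  For each
    of TST, SL, WASO, REM%, NREM% and SE the table reports the reference and
    predicted mean +/- SD, the paired t statistic and two-sided p value
    (descriptive), and the Deming / Bland-Altman agreement panel.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 subjects for agreement analysis")
    ref_rows, pred_rows = [], []
    for ref, pred in pairs:
        ref_rows.append(sleep_parameters(ref, strip_padding=strip_padding).as_dict())
        pred_rows.append(sleep_parameters(pred, strip_padding=strip_padding).as_dict())
    ref_df = pd.DataFrame(ref_rows)
    pred_df = pd.DataFrame(pred_rows)
    rows = []
    for name in PARAMETER_NAMES:
        x = ref_df[name].to_numpy()
        y = pred_df[name].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if ok.sum() < 3:
            warnings.warn(f"{name}: fewer than 3 nights with a defined value; "
                          "agreement reported as NaN", stacklevel=2)
            nan = float("nan")
            rows.append({"parameter": name, "n": int(ok.sum()),
                         "reference_mean": nan, "reference_sd": nan,
                         "predicted_mean": nan, "predicted_sd": nan,
                         "t": nan, "p": nan,
                         "deming_slope": nan, "deming_intercept": nan,
                         "pearson_r": nan, "bias": nan,
                         "loa_lower": nan, "loa_upper": nan,
                         "spearman_rho": nan, "spearman_p": nan})
            continue
        agr = bland_altman(x, y)
        if np.ptp(y - x) == 0:
            t, p = (float("nan"), float("nan")) if np.allclose(y, x) else stats.ttest_rel(y, x)[:2]
        else:
            t, p = stats.ttest_rel(y, x)[:2]
        rows.append({
            "parameter": name,
            "n": int(ok.sum()),
            "reference_mean": float(np.mean(x)), "reference_sd": float(np.std(x, ddof=1)),
            "predicted_mean": float(np.mean(y)), "predicted_sd": float(np.std(y, ddof=1)),
            "t": float(t), "p": float(p),
            "deming_slope": agr.deming_slope, "deming_intercept": agr.deming_intercept,
            "pearson_r": agr.pearson_r,
            "bias": agr.bias, "loa_lower": agr.loa_lower, "loa_upper": agr.loa_upper,
            "spearman_rho": agr.spearman_rho, "spearman_p": agr.spearman_p,
        })
    return pd.DataFrame(rows)
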
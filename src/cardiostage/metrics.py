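"""Epoch-by-epoch agreement metrics for five-class sleep staging.

Before scoring, LV ("out of bed") is merged into WK and the stages are
mapped to ordinal values N3=1, N2=2, N1=3, REM=4, WK=5.  From the 5x5
confusion matrix, pooled one-vs-rest tallies give a pooled sensitivity
S = sum TP_c / (sum TP_c + sum FN_c) and pooled specificity
P = sum TN_c / (sum FP_c + sum TN_c), and the three headline scores are

    balanced accuracy = (S + P) / 2
    kappa             = S + P - 1
    F1                = 2 S / (2 + S - P)

These printed formulas are the canonical scores here (the kappa is the
pooled Youden J rather than the conventional chance-corrected Cohen kappa,
and the F1 denominator is as printed); the conventional Cohen kappa and
macro-F1 are exposed as separate diagnostics and never substituted.
Per-class scores apply the same three formulas to a single class's
one-vs-rest tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram

#: ordinal encoding after merging LV into WK
ORDINAL: dict[str, int] = {"N3": 1, "N2": 2, "N1": 3, "REM": 4, "WK": 5, "LV": 5}
ORDINAL_NAMES: tuple[str, ...] = ("N3", "N2", "N1", "REM", "WK")


def merge_and_encode(hypnogram) -> np.ndarray:
    """Map a 6-stage label sequence to ordinal classes 1..5 (LV -> WK=5)."""
    labels = hypnogram.labels if isinstance(hypnogram, Hypnogram) else hypnogram
    out = np.empty(len(labels), dtype=int)
    for i, l in enumerate(labels):
        key = str(l).upper()
        if key not in ORDINAL:
            raise ValueError(f"unknown stage label {l!r} at epoch {i}")
        out[i] = ORDINAL[key]
    return out


@dataclass
class ConfusionMatrix5:
    """5x5 epoch-count table; rows = true ordinal class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 5x5 table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_tallies(self, c: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for ordinal class c in 1..5."""
        i = c - 1
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def pooled_tallies(self) -> tuple[int, int, int, int]:
        """(sum TP_c, sum TN_c, sum FP_c, sum FN_c) over the five classes.

        Each correct epoch contributes one TP; an epoch contributes to TN
        for every class not involved in it (up to four times).
        """
        tp = tn = fp = fn = 0
        for c in range(1, 6):
            a, b, d, e = self.class_tallies(c)
            tp += a
            tn += b
            fp += d
            fn += e
        return tp, tn, fp, fn


@dataclass
class MetricsReport:
    accuracy: float
    kappa: float
    f1: float
    kappa_cohen: float = float("nan")
    f1_macro: float = float("nan")
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def confusion_matrix(true_seq, pred_seq) -> ConfusionMatrix5:
    """Tally a 5x5 confusion matrix from two aligned sequences.

    Inputs may be hypnograms/label sequences (merged and encoded first) or
    already-ordinal integer sequences in 1..5.
    """
    def encode(x):
        arr = np.asarray(x)
        if arr.dtype.kind in "iu":
            if arr.size and (arr.min() < 1 or arr.max() > 5):
                raise ValueError("ordinal classes must lie in 1..5")
            return arr.astype(int)
        return merge_and_encode(x)

    t = encode(true_seq)
    p = encode(pred_seq)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted epochs")
    if len(t) == 0:
        raise ValueError("empty sequences")
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix5(counts)


def _three_scores(tp, tn, fp, fn) -> tuple[float, float, float]:
    """(balanced accuracy, kappa, F1) from the printed formulas; NaN with a
    warning when a denominator vanishes."""
    with np.errstate(invalid="ignore", divide="ignore"):
        s = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        p = tn / (fp + tn) if (fp + tn) > 0 else np.nan
    if not np.isfinite(s) or not np.isfinite(p):
        warnings.warn("undefined sensitivity or specificity (empty tally); "
                      "metrics reported as NaN", stacklevel=3)
    acc = 0.5 * (s + p)
    kappa = s + p - 1.0
    f1 = 2.0 * s / (2.0 + s - p)
    return float(acc), float(kappa), float(f1)


def _cohen_kappa(cm: ConfusionMatrix5) -> float:
    """Conventional chance-corrected Cohen kappa (diagnostic only)."""
    n = cm.total
    po = np.trace(cm.counts) / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        return float("nan")
    return float((po - pe) / (1 - pe))


def _macro_f1(cm: ConfusionMatrix5) -> float:
    """Conventional macro-averaged F1 (diagnostic only)."""
    vals = []
    for c in range(1, 6):
        tp, tn, fp, fn = cm.class_tallies(c)
        denom = 2 * tp + fp + fn
        if denom > 0:
            vals.append(2 * tp / denom)
    return float(np.mean(vals)) if vals else float("nan")


def per_class_metrics(cm: ConfusionMatrix5) -> dict[str, dict[str, float]]:
    """The three scores per class from that class's one-vs-rest tallies."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out = {}
    for c, name in enumerate(ORDINAL_NAMES, start=1):
        acc, kappa, f1 = _three_scores(*cm.class_tallies(c))
        out[name] = {"accuracy": acc, "kappa": kappa, "f1": f1}
    return out


def overall_metrics(cm: ConfusionMatrix5) -> MetricsReport:
    """Pooled three scores (plus conventional diagnostics and per-class)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc, kappa, f1 = _three_scores(*cm.pooled_tallies())
    return MetricsReport(
        accuracy=acc, kappa=kappa, f1=f1,
        kappa_cohen=_cohen_kappa(cm), f1_macro=_macro_f1(cm),
        per_class=per_class_metrics(cm),
    )


def cohort_summary(pairs, covariates: dict[str, np.ndarray] | None = None) -> dict:
    """Per-subject metrics with cohort mean +/- sample SD.

    ``pairs`` is a list of (true, predicted) hypnograms; ``covariates`` maps
    a name (e.g. apnea severity, age, sleep efficiency) to one value per
    subject and yields Pearson correlations against each overall metric.
    """
    if len(pairs) == 0:
        raise ValueError("no subjects")
    per_subject = []
    for true, pred in pairs:
        cm = confusion_matrix(true, pred)
        r = overall_metrics(cm)
        per_subject.append({"accuracy": r.accuracy, "kappa": r.kappa, "f1": r.f1})
    table = pd.DataFrame(per_subject)
    summary = {
        "per_subject": per_subject,
        "mean": table.mean().to_dict(),
        "sd": (table.std(ddof=1).to_dict() if len(table) > 1
               else {k: float("nan") for k in table.columns}),
    }
    if covariates:
        from scipy.stats import pearsonr

        cors = {}
        for name, values in covariates.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(pairs):
                raise ValueError(f"covariate {name!r} has {len(values)} values "
                                 f"for {len(pairs)} subjects")
            cors[name] = {}
            for metric in table.columns:
                r, p = pearsonr(values, table[metric].to_numpy())
                cors[name][metric] = {"r": float(r), "p": float(p)}
        summary["covariate_correlations"] = cors
    return summary
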
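"""ROC analysis, balanced confusion metrics and trajectory summaries.

Classification convention throughout: a sample is called an *event* when its
score is greater than or equal to the threshold.  AUC is trapezoidal over
the full ROC curve, which equals the concordant-pair (Mann-Whitney)
statistic with ties counted one half.

Because the control window is much wider than short horizons, event/control
counts are heavily imbalanced; PPV, NPV and accuracy are therefore reported
after oversampling the minority class to prevalence 0.5, which makes them
interpretable and ties them to sensitivity/specificity through closed-form
identities (see :func:`implied_balanced_metrics`).  AUC is rank-based and
never needs resampling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "EvaluationResult",
    "roc_points",
    "auc_trapezoid",
    "youden_cutoff",
    "confusion_metrics",
    "implied_balanced_metrics",
    "stratified_auc",
    "trajectory_bins",
    "as_event_indicator",
    "derive_seed",
]


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve points: one per distinct score threshold plus endpoints.

    ``thresholds`` is descending; its leading entry is +inf (the all-control
    corner (0, 0)).  ``fpr``/``tpr`` are non-decreasing and end at (1, 1).
    """
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class EvaluationResult:
    """AUC plus balanced confusion metrics for one model on one dataset."""
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    n_samples: int
    n_patients: int = 0

    def rounded(self, ndigits: int = 3) -> "EvaluationResult":
        """Reporting-time rounding; internal arithmetic stays full precision."""
        return EvaluationResult(
            *(round(getattr(self, f), ndigits) for f in
              ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")),
            n_samples=self.n_samples, n_patients=self.n_patients)


def as_event_indicator(labels) -> np.ndarray:
    """Coerce labels (bool/0-1 ints or 'event'/'control' strings) to bool."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "bifu":
        return arr.astype(bool)
    out = arr == "event"
    if not np.all(out | (arr == "control")):
        raise ValueError("labels must be 'event'/'control' or binary")
    return out


def derive_seed(*parts) -> int:
    """Stable sub-stream seed (< 2^31) from heterogeneous parts."""
    return zlib.crc32("|".join(map(str, parts)).encode()) & 0x7FFFFFFF


def roc_points(scores, labels) -> ROCCurve:
    """ROC curve under the score-``>=``-threshold event-calling rule."""
    y = as_event_indicator(labels)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing Youden's J = tpr - fpr; ties go to the smallest.

    Only observed score thresholds compete (the synthetic +inf corner is
    excluded), so degenerate all-tied scores return the single observed
    score.
    """
    j = curve.tpr[1:] - curve.fpr[1:]
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = smallest
    return float(curve.thresholds[1:][best])


def oversampled_indices(labels, seed: int = 0) -> np.ndarray:
    """Class-balancing index list: originals plus minority redraws.

    Every original sample is kept once; the minority class is then topped up
    with uniform draws with replacement until the class counts are equal
    (output prevalence exactly 0.5).  Re-exported by the model-search module
    as ``oversample_balance``.
    """
    y = as_event_indicator(labels)
    n = y.size
    n_event = int(y.sum())
    n_control = n - n_event
    if n_event == 0 or n_control == 0:
        raise ValueError("both classes must be present to balance")
    idx = np.arange(n)
    if n_event == n_control:
        return idx
    minority = idx[y] if n_event < n_control else idx[~y]
    extra = np.random.default_rng(seed).choice(
        minority, size=abs(n_control - n_event), replace=True)
    return np.concatenate([idx, extra])


def confusion_metrics(scores, labels, cutoff: float, balance: bool = True,
                      seed: int = 0, n_patients: int = 0) -> EvaluationResult:
    """Confusion-matrix metrics at a cutoff, plus AUC.

    With ``balance`` on, scores/labels are resampled to prevalence 0.5
    (minority oversampling) before counting TP/FP/TN/FN, so PPV/NPV/accuracy
    are comparable across horizons with different event rates.  AUC is
    always computed on the original, unresampled scores.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    y = as_event_indicator(labels)
    s = np.asarray(scores, dtype=float)
    auc = auc_trapezoid(roc_points(s, y))
    if balance:
        idx = oversampled_indices(y, seed=seed)
        yb, sb = y[idx], s[idx]
    else:
        yb, sb = y, s
    pred = sb >= cutoff
    tp = int(np.sum(pred & yb))
    fp = int(np.sum(pred & ~yb))
    fn = int(np.sum(~pred & yb))
    tn = int(np.sum(~pred & ~yb))

    def _ratio(a, b):
        return a / b if b else float("nan")

    return EvaluationResult(
        auc=auc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        n_samples=int(y.size),
        n_patients=n_patients,
    )


def implied_balanced_metrics(sensitivity: float,
                             specificity: float) -> tuple[float, float, float]:
    """Closed-form PPV, NPV and accuracy at prevalence 0.5.

    At a balanced prevalence the confusion matrix is determined by
    sensitivity and specificity alone::

        ppv = sens / (sens + 1 - spec)
        npv = spec / (spec + 1 - sens)
        accuracy = (sens + spec) / 2

    Degenerate zero denominators yield NaN rather than raising.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    ppv_den = sensitivity + 1.0 - specificity
    npv_den = specificity + 1.0 - sensitivity
    ppv = sensitivity / ppv_den if ppv_den > 0 else float("nan")
    npv = specificity / npv_den if npv_den > 0 else float("nan")
    return ppv, npv, (sensitivity + specificity) / 2.0


def stratified_auc(samples: pd.DataFrame, model, stratum_field: str = "tumor_type",
                   month_days: float | None = None,
                   window_days: int | None = None) -> dict[str, float]:
    """Per-stratum test AUC for a fitted model (e.g. per tumor type).

    Strata where only one class occurs (or where no complete panels exist)
    are flagged with NaN rather than silently dropped.
    """
    from . import models as _models
    from .cohort import MONTH_DAYS, WINDOW_DAYS

    if stratum_field not in samples.columns:
        raise ValueError(f"unknown stratum field {stratum_field!r}")
    month_days = MONTH_DAYS if month_days is None else month_days
    window_days = WINDOW_DAYS if window_days is None else window_days
    out: dict[str, float] = {}
    for stratum, group in samples.groupby(stratum_field, sort=True):
        try:
            scores, y = _models.score_samples(model, group, month_days=month_days,
                                              window_days=window_days)
            out[str(stratum)] = auc_trapezoid(roc_points(scores, y))
        except ValueError:
            out[str(stratum)] = float("nan")
    return out


def trajectory_bins(observations: pd.DataFrame, patients: pd.DataFrame,
                    item: str, bin_days: int = 30,
                    window_days: int = 365) -> pd.DataFrame:
    """Per-bin mean with normal-approximation 95% CI for one item.

    Observations are bucketed by days to death into [0, bin_days),
    [bin_days, 2*bin_days), ... up to the window.  Bins with fewer than two
    observations get NaN CI bounds (undefined, not zero-width).
    """
    obs = observations[observations["item_code"] == item]
    if len(obs) == 0:
        raise ValueError(f"no observations for item {item!r}")
    merged = obs.merge(patients[["patient_id", "death_date"]], on="patient_id")
    d = (merged["death_date"] - merged["obs_date"]).dt.days
    merged = merged[(d >= 0) & (d <= window_days)]
    d = d[(d >= 0) & (d <= window_days)]
    edges = np.arange(0, window_days + bin_days, bin_days)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        vals = merged["value"].to_numpy()[which == b]
        n = vals.size
        mean = float(vals.mean()) if n else float("nan")
        if n >= 2:
            se = float(vals.std(ddof=1)) / np.sqrt(n)
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        else:
            lo = hi = float("nan")
        rows.append((int(edges[b]), int(edges[b + 1]), n, mean, lo, hi))
    return pd.DataFrame(rows, columns=["bin_start_days", "bin_end_days", "n",
                                       "mean", "ci_low", "ci_high"])
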
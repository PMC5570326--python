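"""Exhaustive k-item model search with ridge-penalized logistic fits.

For each prediction horizon (1-6 months) every k-item combination from the
retained panel is fitted on the training cohort — complete-case rows only,
classes balanced by minority oversampling — and evaluated on the test
cohort, where the ROC curve yields the AUC used for ranking and the Youden
cutoff stored with the model.  With 40 items and k = 3 this is the
C(40,3) = 9,880 combinations x 6 horizons = 59,280-model sweep.

The fit maximizes the ridge-penalized log-likelihood

    l(beta) - lambda/2 * ||beta_std||^2

with the penalty on *standardized* slopes and the intercept unpenalized;
coefficients are reported back on the raw item scale, so they are directly
interpretable per item unit.  Newton/IRLS with step halving converges
quadratically for these tiny (k <= 4) designs and stays finite under
complete separation whenever lambda > 0.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (MONTH_DAYS, WINDOW_DAYS, ItemPanel, event_indicator,
                     item_columns)
from .evaluation import (confusion_metrics, derive_seed, oversampled_indices,
                         roc_points, auc_trapezoid, youden_cutoff)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "enumerate_combinations",
    "complete_case_design",
    "oversample_balance",
    "fit_regularized_logistic",
    "search_all",
    "write_results_csv",
]

logger = logging.getLogger(__name__)

#: Default ridge strength on standardized slopes.
DEFAULT_LAMBDA = 0.01

# Re-export under the search-stage name; balancing is shared with evaluation.
oversample_balance = oversampled_indices


@dataclass(frozen=True)
class ModelSpec:
    """An item combination at one prediction horizon."""
    items: tuple[str, ...]
    horizon_n: int

    def __post_init__(self) -> None:
        if list(self.items) != sorted(set(self.items)):
            raise ValueError("items must be sorted and distinct")
        if not (isinstance(self.horizon_n, (int, np.integer))
                and self.horizon_n >= 1):
            raise ValueError("horizon_n must be a positive integer")


@dataclass(frozen=True)
class FittedModel:
    """A fitted combination: raw-scale coefficients, intercept and cutoff.

    The predicted event probability is
    ``p = 1 / (1 + exp(-(sum_i coef_i * value_i) - intercept))`` and the
    classification rule is ``p >= cutoff -> event``.
    """
    spec: ModelSpec
    coefficients: dict[str, float]
    intercept: float
    cutoff: float
    reg_lambda: float | None = None

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.spec.items):
            raise ValueError("coefficients must cover exactly the spec items")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")
        if self.reg_lambda is not None and self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")

    @property
    def items(self) -> tuple[str, ...]:
        return self.spec.items

    @property
    def horizon_n(self) -> int:
        return self.spec.horizon_n

    def to_dict(self) -> dict:
        return {
            "items": list(self.spec.items),
            "horizon": int(self.spec.horizon_n),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "cutoff": float(self.cutoff),
            "reg_lambda": None if self.reg_lambda is None else float(self.reg_lambda),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedModel":
        return cls(
            spec=ModelSpec(items=tuple(doc["items"]), horizon_n=int(doc["horizon"])),
            coefficients={k: float(v) for k, v in doc["coefficients"].items()},
            intercept=float(doc["intercept"]),
            cutoff=float(doc["cutoff"]),
            reg_lambda=doc.get("reg_lambda"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _panel_items(panel) -> tuple[str, ...]:
    if isinstance(panel, ItemPanel):
        return tuple(panel.retained_items)
    return tuple(panel)


def enumerate_combinations(panel, k: int) -> list[tuple[str, ...]]:
    """All C(n, k) sorted k-item combinations in lexicographic order."""
    items = sorted(set(_panel_items(panel)))
    if not (1 <= k <= len(items)):
        raise ValueError(f"k must be in [1, {len(items)}]")
    return list(itertools.combinations(items, k))


def complete_case_design(samples: pd.DataFrame, combo: Sequence[str]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix over the samples where every combo item was measured.

    Returns ``(X, kept)`` where ``X`` has one column per combo item in combo
    order and ``kept`` holds the positional indices of the retained rows.
    """
    missing = [c for c in combo if c not in samples.columns]
    if missing:
        raise ValueError(f"items not in samples: {missing}")
    x = samples[list(combo)].to_numpy(dtype=float)
    ok = np.isfinite(x).all(axis=1)
    if not ok.any():
        raise ValueError(f"no complete cases for combination {tuple(combo)}")
    return x[ok], np.flatnonzero(ok)


def _nll_penalized(z: np.ndarray, y: np.ndarray, beta_slopes: np.ndarray,
                   lam: float) -> float:
    # sum log(1 + e^z) - y z, computed stably, plus the ridge term
    return (float(np.sum(np.logaddexp(0.0, z) - y * z))
            + 0.5 * lam * float(beta_slopes @ beta_slopes))


def fit_regularized_logistic(design: np.ndarray, labels, reg_lambda: float =
                             DEFAULT_LAMBDA, max_iter: int = 100,
                             tol: float = 1e-11) -> tuple[np.ndarray, float]:
    """Ridge-penalized logistic regression, coefficients on the raw scale.

    Features are standardized internally (a zero-variance column contributes
    a zero slope); the penalty ``reg_lambda/2 * ||beta||^2`` applies to the
    standardized slopes only, never the intercept.  Newton/IRLS with step
    halving; convergence to a max step below ``tol`` on the standardized
    scale, so refitting after an affine rescaling of an item reproduces the
    raw coefficient up to the exact rescaling factor.

    Returns ``(coefficients, intercept)`` in item units.  Raises
    ``RuntimeError`` on non-convergence (possible at ``reg_lambda = 0``
    under complete separation).
    """
    x = np.asarray(design, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("design values must be finite")
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    y = np.asarray(labels)
    from .evaluation import as_event_indicator
    y = as_event_indicator(y).astype(float)
    if y.size != x.shape[0]:
        raise ValueError("labels and design row counts differ")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    live = sd > 0
    xs = np.zeros_like(x)
    xs[:, live] = (x[:, live] - mu[live]) / sd[live]

    n, k = xs.shape
    beta = np.zeros(k + 1)  # [slopes..., intercept]
    p_bar = y.mean()
    beta[-1] = math.log(p_bar / (1.0 - p_bar))  # warm start at the null model
    xa = np.hstack([xs, np.ones((n, 1))])
    pen = np.zeros(k + 1)
    pen[:k] = reg_lambda

    z = xa @ beta
    obj = _nll_penalized(z, y, beta[:k], reg_lambda)
    for _ in range(max_iter):
        p = expit(z)
        grad = xa.T @ (p - y) + pen * beta
        w = p * (1.0 - p)
        hess = (xa * w[:, None]).T @ xa + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in logistic fit") from exc
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(40):
            beta_new = beta - t * step
            z_new = xa @ beta_new
            obj_new = _nll_penalized(z_new, y, beta_new[:k], reg_lambda)
            if obj_new <= obj + 1e-12:
                break
            t *= 0.5
        beta, z, obj = beta_new, z_new, obj_new
        if np.max(np.abs(t * step)) < tol:
            break
    else:
        raise RuntimeError("logistic fit did not converge "
                           f"(lambda={reg_lambda}, n={n}, k={k})")

    coef = np.zeros(k)
    coef[live] = beta[:k][live] / sd[live]
    intercept = float(beta[k] - np.dot(coef[live], mu[live]))
    return coef, intercept


def _predict(x: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    return expit(x @ coef + intercept)


def search_all(train_samples: pd.DataFrame, test_samples: pd.DataFrame,
               panel, k: int = 3, horizons: Iterable[int] = range(1, 7),
               reg_lambda: float = DEFAULT_LAMBDA, seed: int = 0,
               month_days: float = MONTH_DAYS,
               window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Fit and evaluate every combination at every horizon.

    Per horizon and combination: complete-case training rows are labeled,
    oversampled to class balance, and fitted; the fitted model is scored on
    the test cohort's complete cases, the test ROC supplies the AUC and the
    Youden cutoff, and PPV/NPV/accuracy are computed on balanced test
    resamples at that cutoff.  Combinations that cannot be fitted (a class
    missing among complete cases) are recorded with ``status != "ok"`` and
    NaN metrics instead of aborting the sweep.

    Returns one row per combination x horizon with columns ``items``
    (tuple), ``horizon``, ``model`` (:class:`FittedModel` or None), the
    evaluation metrics, ``n_train``/``n_test`` complete-case counts and
    ``status``.
    """
    items = sorted(set(_panel_items(panel)))
    combos = enumerate_combinations(items, k)
    horizons = list(horizons)

    def _prepare(samples):
        x = samples[items].to_numpy(dtype=float)
        finite = np.isfinite(x)
        days = samples["days_to_death"].to_numpy()
        pid = samples["patient_id"].to_numpy()
        return x, finite, days, pid

    xtr, ftr, dtr, _ = _prepare(train_samples)
    xte, fte, dte, pid_te = _prepare(test_samples)
    col = {item: j for j, item in enumerate(items)}

    rows = []
    for h in horizons:
        ytr_all = event_indicator(dtr, h, month_days, window_days)
        yte_all = event_indicator(dte, h, month_days, window_days)
        for combo in combos:
            cols = [col[c] for c in combo]
            row = {"items": combo, "horizon": h, "model": None,
                   "auc": np.nan, "sensitivity": np.nan, "specificity": np.nan,
                   "ppv": np.nan, "npv": np.nan, "accuracy": np.nan,
                   "n_train": 0, "n_test": 0, "status": "ok"}
            try:
                keep_tr = ftr[:, cols].all(axis=1)
                ytr = ytr_all[keep_tr]
                row["n_train"] = int(keep_tr.sum())
                if ytr.size == 0 or ytr.all() or not ytr.any():
                    raise ValueError("training classes incomplete")
                x = xtr[np.ix_(keep_tr.nonzero()[0], cols)]
                os_idx = oversample_balance(
                    ytr, seed=derive_seed(seed, h, "+".join(combo), "train"))
                coef, intercept = fit_regularized_logistic(
                    x[os_idx], ytr[os_idx], reg_lambda)

                keep_te = fte[:, cols].all(axis=1)
                yte = yte_all[keep_te]
                row["n_test"] = int(keep_te.sum())
                if yte.size == 0 or yte.all() or not yte.any():
                    raise ValueError("test classes incomplete")
                scores = _predict(xte[np.ix_(keep_te.nonzero()[0], cols)],
                                  coef, intercept)
                curve = roc_points(scores, yte)
                cutoff = youden_cutoff(curve)
                # Youden can land on an endpoint score of exactly 0/1 only
                # for degenerate scores; clamp into the open interval.
                cutoff = min(max(cutoff, 1e-12), 1.0 - 1e-12)
                model = FittedModel(
                    spec=ModelSpec(items=combo, horizon_n=h),
                    coefficients=dict(zip(combo, map(float, coef))),
                    intercept=intercept, cutoff=cutoff, reg_lambda=reg_lambda)
                result = confusion_metrics(
                    scores, yte, cutoff, balance=True,
                    seed=derive_seed(seed, h, "+".join(combo), "test"),
                    n_patients=len(np.unique(pid_te[keep_te])))
                row.update(model=model, auc=result.auc,
                           sensitivity=result.sensitivity,
                           specificity=result.specificity, ppv=result.ppv,
                           npv=result.npv, accuracy=result.accuracy)
            except (ValueError, RuntimeError) as exc:
                row["status"] = f"skipped: {exc}"
                logger.warning("combination %s at horizon %d skipped: %s",
                               "+".join(combo), h, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(results: pd.DataFrame, path) -> None:
    """Serialize a search-result table to CSV.

    Items are '+'-joined; coefficients become an ``item:value`` list so the
    file round-trips through plain-text tooling.
    """
    out = results.copy()
    out["items"] = out["items"].map("+".join)
    out["coefficients"] = out["model"].map(
        lambda m: "" if m is None else
        ";".join(f"{k}:{v:.10g}" for k, v in m.coefficients.items()))
    out["intercept"] = out["model"].map(
        lambda m: np.nan if m is None else m.intercept)
    out["cutoff"] = out["model"].map(
        lambda m: np.nan if m is None else m.cutoff)
    cols = ["items", "horizon", "coefficients", "intercept", "cutoff", "auc",
            "sensitivity", "specificity", "ppv", "npv", "accuracy",
            "n_train", "n_test", "status"]
    out[cols].to_csv(path, index=False)
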
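"""The published six-horizon prognosis model set and its application.

A single item triple — serum albumin (ALB, falls terminally), lactate
dehydrogenase (LDH, rises with tumor burden) and neutrophils (NEU, rise
terminally) — carries a separately fitted logistic model per prediction
horizon of 1-6 months.  The event probability is

    p = 1 / (1 + exp(-(c_Alb*Alb + c_LDH*LDH + c_Neu*Neu + const)))

and a panel is classified as an event (death expected within the horizon)
when ``p >= cutoff``.  Coefficients are per item unit in the source
laboratory's units (ALB g/dL; LDH and NEU unstated there, so predictions
are only meaningful in those original units).

This module also houses the cross-horizon family selection (rank-sum over
per-horizon AUC rankings) and the external-validation harness that applies
fixed coefficients and cutoffs to a new cohort without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import MONTH_DAYS, WINDOW_DAYS, event_indicator
from .evaluation import EvaluationResult, confusion_metrics, derive_seed
from .search import FittedModel, ModelSpec

__all__ = [
    "SAPModelSet",
    "SelectionResult",
    "published_models",
    "predict_probability",
    "classify",
    "rank_table",
    "select_family",
    "external_validate",
    "score_samples",
    "evaluate_model",
]

PUBLISHED_ITEMS = ("ALB", "LDH", "NEU")

# Published per-horizon constants: horizon (months) ->
# (c_Alb, c_LDH, c_Neu, const, cutoff).  Version stamp: sapmodels 0.1.0.
_PUBLISHED_CONSTANTS: dict[int, tuple[float, float, float, float, float]] = {
    1: (-0.701, 0.002, 0.023, -0.051, 0.496),
    2: (-0.573, 0.002, 0.020, -0.042, 0.488),
    3: (-0.482, 0.001, 0.017, -0.039, 0.501),
    4: (-0.407, 0.001, 0.015, -0.031, 0.497),
    5: (-0.347, 0.001, 0.013, -0.033, 0.507),
    6: (-0.334, 0.001, 0.012, -0.031, 0.503),
}


@dataclass(frozen=True)
class SAPModelSet:
    """Six fitted models (horizons 1-6 months) sharing one item combination."""
    models: dict[int, FittedModel]

    def __post_init__(self) -> None:
        if sorted(self.models) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("model set must cover horizons 1..6 exactly")
        items = {m.items for m in self.models.values()}
        if len(items) != 1:
            raise ValueError("all models in a set must share one item combination")

    @property
    def items(self) -> tuple[str, ...]:
        return next(iter(self.models.values())).items

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(h): m.to_dict() for h, m in sorted(self.models.items())},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SAPModelSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls({int(h): FittedModel.from_dict(d) for h, d in doc.items()})


def published_models() -> SAPModelSet:
    """The published ALB/LDH/NEU model constants, exactly as printed."""
    models = {}
    for h, (c_alb, c_ldh, c_neu, const, cutoff) in _PUBLISHED_CONSTANTS.items():
        # items sorted lexicographically: ALB, LDH, NEU
        models[h] = FittedModel(
            spec=ModelSpec(items=PUBLISHED_ITEMS, horizon_n=h),
            coefficients={"ALB": c_alb, "LDH": c_ldh, "NEU": c_neu},
            intercept=const, cutoff=cutoff, reg_lambda=None)
    return SAPModelSet(models)


def _linear(model: FittedModel, item_values) -> float | np.ndarray:
    if isinstance(item_values, pd.DataFrame):
        missing = [c for c in model.items if c not in item_values.columns]
        if missing:
            raise KeyError(f"missing item(s) {missing} required by the model")
        x = item_values[list(model.items)].to_numpy(dtype=float)
        coef = np.array([model.coefficients[c] for c in model.items])
        return x @ coef + model.intercept
    z = model.intercept
    for item in model.items:
        try:
            v = item_values[item]
        except (KeyError, IndexError) as exc:
            raise KeyError(f"missing item {item!r} required by the model") from exc
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for item {item!r}")
        z += model.coefficients[item] * float(v)
    return z


def predict_probability(model: FittedModel, item_values) -> float | np.ndarray:
    """Event probability for one panel (mapping) or many (DataFrame rows)."""
    z = _linear(model, item_values)
    p = expit(z)
    return p if isinstance(z, np.ndarray) else float(p)


def classify(model: FittedModel, item_values) -> tuple[str, float]:
    """Label a panel; the boundary ``p == cutoff`` classifies as event."""
    p = predict_probability(model, item_values)
    if isinstance(p, np.ndarray):
        raise TypeError("classify takes a single panel; use predict_probability "
                        "for batch scoring")
    return ("event" if p >= model.cutoff else "control"), p


def rank_table(results: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Combinations at one horizon ordered by descending test AUC.

    Ranks are 1..M; AUC ties break lexicographically on the item tuple so
    the ordering is deterministic.
    """
    sub = results[(results["horizon"] == horizon)
                  & (results["status"] == "ok")].copy()
    sub = sub.sort_values(["auc", "items"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    return sub


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the cross-horizon family selection."""
    items: tuple[str, ...]
    rank_sums: dict[tuple[str, ...], int]
    rank_tables: dict[int, pd.DataFrame]

    def top10(self) -> dict[int, pd.DataFrame]:
        cols = ["rank", "items", "auc", "sensitivity", "specificity", "ppv",
                "npv", "accuracy"]
        return {h: t[cols].head(10).copy() for h, t in self.rank_tables.items()}


def select_family(results: pd.DataFrame) -> SelectionResult:
    """Pick the item combination with the best rank-sum across horizons.

    Every horizon must rank the same combination universe.  Ties on the rank
    sum break toward the higher mean AUC, then lexicographic item order.
    """
    horizons = sorted(results["horizon"].unique())
    tables = {h: rank_table(results, h) for h in horizons}
    universes = {h: frozenset(t["items"]) for h, t in tables.items()}
    if len(set(universes.values())) != 1:
        raise ValueError("horizons rank inconsistent combination universes")

    rank_sums: dict[tuple[str, ...], int] = {}
    auc_sums: dict[tuple[str, ...], float] = {}
    for h, t in tables.items():
        for items, rank, auc in zip(t["items"], t["rank"], t["auc"]):
            rank_sums[items] = rank_sums.get(items, 0) + int(rank)
            auc_sums[items] = auc_sums.get(items, 0.0) + float(auc)
    best = min(rank_sums,
               key=lambda c: (rank_sums[c], -auc_sums[c], c))
    return SelectionResult(items=best, rank_sums=rank_sums, rank_tables=tables)


def score_samples(model: FittedModel, samples: pd.DataFrame,
                  month_days: float = MONTH_DAYS,
                  window_days: int = WINDOW_DAYS
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Scores and event labels for a model over its complete-case samples."""
    from .search import complete_case_design
    x, kept = complete_case_design(samples, model.items)
    coef = np.array([model.coefficients[c] for c in model.items])
    scores = expit(x @ coef + model.intercept)
    days = samples["days_to_death"].to_numpy()[kept]
    y = event_indicator(days, model.horizon_n, month_days, window_days)
    if y.all() or not y.any():
        raise ValueError(f"horizon {model.horizon_n}: only one class present")
    return scores, y


def evaluate_model(model: FittedModel, samples: pd.DataFrame, seed: int = 0,
                   month_days: float = MONTH_DAYS,
                   window_days: int = WINDOW_DAYS) -> EvaluationResult:
    """Apply a fitted model (fixed coefficients and cutoff) to a cohort."""
    from .search import complete_case_design
    scores, y = score_samples(model, samples, month_days, window_days)
    _, kept = complete_case_design(samples, model.items)
    n_patients = samples["patient_id"].iloc[kept].nunique()
    return confusion_metrics(
        scores, y, model.cutoff, balance=True,
        seed=derive_seed(seed, model.horizon_n, "+".join(model.items), "test"),
        n_patients=int(n_patients))


def external_validate(model_set: SAPModelSet, samples: pd.DataFrame,
                      horizons=None, seed: int = 0,
                      month_days: float = MONTH_DAYS,
                      window_days: int = WINDOW_DAYS
                      ) -> dict[int, EvaluationResult]:
    """Validate fixed models on an independent, already-assembled cohort.

    ``horizons`` restricts validation (e.g. skip the 6-month model for a
    cohort censored at 180 days); the result map contains only the horizons
    actually validated.
    """
    if horizons is None:
        horizons = sorted(model_set.models)
    out = {}
    for h in horizons:
        out[h] = evaluate_model(model_set.models[h], samples, seed=seed,
                                month_days=month_days, window_days=window_days)
    return out
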
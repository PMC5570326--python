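"""Cohort reading, item-panel filtering, time-point assembly and labeling.

The analysis treats every laboratory panel drawn within one year of a
patient's death as one sample.  For a prediction horizon of ``n`` months a
sample is an *event* if the draw lies within ``n`` months of death and a
*control* if it lies between ``n`` months and the end of the one-year
window.  Months are 30.4375 days (365.25 / 12) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTH_DAYS",
    "WINDOW_DAYS",
    "META_COLUMNS",
    "Cohort",
    "ItemPanel",
    "read_cohort",
    "filter_items",
    "filter_to_panel",
    "assemble_time_points",
    "label_for_horizon",
    "event_indicator",
    "split_patients",
    "item_columns",
]

#: Days per month used to convert horizons to days (365.25 / 12).
MONTH_DAYS: float = 30.4375
#: Default look-back window before death, days.
WINDOW_DAYS: int = 365

#: Non-item columns of an assembled time-point table.
META_COLUMNS: tuple[str, ...] = ("patient_id", "obs_date", "days_to_death",
                                 "tumor_type")

_LAB_COLUMNS = ["patient_id", "obs_date", "item_code", "value", "specimen"]
_PATIENT_COLUMNS = ["patient_id", "death_date", "tumor_type"]


class Cohort(NamedTuple):
    """Parsed cohort tables plus the referential-integrity rejection report."""
    patients: pd.DataFrame
    observations: pd.DataFrame
    rejected: pd.DataFrame


@dataclass(frozen=True)
class ItemPanel:
    """The retained laboratory item panel with per-item coverage."""
    retained_items: tuple[str, ...]
    coverage: dict[str, float]


def _parse_dates(raw: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any() or raw.isna().any():
        row = int((bad | raw.isna()).idxmax())
        raise ValueError(
            f"{path}: malformed {column} {raw.get(row)!r} at data row {row}")
    return parsed


def read_cohort(lab_path, patient_path) -> Cohort:
    """Read the long-format lab CSV and the patient CSV.

    Malformed dates or values raise ``ValueError`` naming the offending row.
    Duplicate ``(patient_id, obs_date, item_code)`` rows keep the last
    occurrence with a warning.  Observations whose ``patient_id`` is absent
    from the patient table are split off into ``rejected`` (with a warning)
    rather than silently dropped.
    """
    patients = pd.read_csv(patient_path, dtype=str)
    missing = set(_PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"{patient_path}: missing columns {sorted(missing)}")
    patients = patients[_PATIENT_COLUMNS].copy()
    patients["death_date"] = _parse_dates(patients["death_date"], patient_path,
                                          "death_date")
    if patients["patient_id"].duplicated().any():
        warnings.warn(f"{patient_path}: duplicate patient ids, keeping last")
        patients = patients.drop_duplicates("patient_id", keep="last")
    patients = patients.reset_index(drop=True)

    obs = pd.read_csv(lab_path, dtype=str)
    missing = set(_LAB_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"{lab_path}: missing columns {sorted(missing)}")
    obs = obs[_LAB_COLUMNS].copy()
    obs["obs_date"] = _parse_dates(obs["obs_date"], lab_path, "obs_date")
    values = pd.to_numeric(obs["value"], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        row = int(np.argmax(bad))
        raise ValueError(
            f"{lab_path}: malformed value {obs['value'].iloc[row]!r} "
            f"at data row {row}")
    obs["value"] = values.astype(float)
    unknown_spec = ~obs["specimen"].isin(["blood", "urine"])
    if unknown_spec.any():
        row = int(np.argmax(unknown_spec.to_numpy()))
        raise ValueError(
            f"{lab_path}: unknown specimen {obs['specimen'].iloc[row]!r} "
            f"at data row {row}")

    dup = obs.duplicated(["patient_id", "obs_date", "item_code"], keep="last")
    if dup.any():
        warnings.warn(f"{lab_path}: {int(dup.sum())} duplicate "
                      "(patient, date, item) rows, keeping last")
        obs = obs[~dup]

    known = obs["patient_id"].isin(patients["patient_id"])
    rejected = obs[~known].reset_index(drop=True)
    if len(rejected):
        warnings.warn(f"{lab_path}: {len(rejected)} observations reference "
                      "unknown patients; see the rejection report")
    return Cohort(patients, obs[known].reset_index(drop=True), rejected)


def filter_items(observations: pd.DataFrame, min_coverage: float = 0.5,
                 exclude_urine: bool = True) -> ItemPanel:
    """Retain routinely monitored blood items.

    Coverage of an item is the fraction of distinct (patient, date) time
    points at which the item was measured.  Items below ``min_coverage``
    (infrequently ordered tests such as tumor markers) and, by default, all
    urine-based items are dropped.  The boundary is closed: coverage exactly
    equal to ``min_coverage`` is retained.
    """
    if len(observations) == 0:
        raise ValueError("empty observation set")
    points = observations.drop_duplicates(["patient_id", "obs_date"])
    n_points = len(points)
    per_item = (observations
                .drop_duplicates(["patient_id", "obs_date", "item_code"])
                .groupby("item_code", sort=True))
    coverage = (per_item.size() / n_points).to_dict()
    urine_items = set(observations.loc[observations["specimen"] == "urine",
                                       "item_code"])
    retained = tuple(sorted(
        item for item, cov in coverage.items()
        if cov >= min_coverage and not (exclude_urine and item in urine_items)))
    return ItemPanel(retained_items=retained, coverage=coverage)


def filter_to_panel(observations: pd.DataFrame, panel: ItemPanel) -> pd.DataFrame:
    """Restrict an observation table to the retained items."""
    return observations[observations["item_code"].isin(panel.retained_items)]


def assemble_time_points(observations: pd.DataFrame, patients: pd.DataFrame,
                         window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Group observations into per-(patient, date) time-point samples.

    Returns a wide table with one row per time point: the ``META_COLUMNS``
    followed by one column per item (NaN where the item was not measured that
    day — no imputation or carry-forward).  Samples outside
    ``0 <= days_to_death <= window_days`` are dropped.
    """
    merged = observations.merge(
        patients[["patient_id", "death_date", "tumor_type"]],
        on="patient_id", how="inner", validate="many_to_one")
    merged["days_to_death"] = (
        (merged["death_date"] - merged["obs_date"]).dt.days)
    merged = merged[(merged["days_to_death"] >= 0)
                    & (merged["days_to_death"] <= window_days)]
    if len(merged) == 0:
        return pd.DataFrame(columns=list(META_COLUMNS))
    wide = merged.pivot_table(index=["patient_id", "obs_date"],
                              columns="item_code", values="value",
                              aggfunc="last")
    meta = (merged.drop_duplicates(["patient_id", "obs_date"])
            .set_index(["patient_id", "obs_date"])
            [["days_to_death", "tumor_type"]])
    out = meta.join(wide).reset_index()
    out["days_to_death"] = out["days_to_death"].astype(int)
    return out[list(META_COLUMNS) + sorted(wide.columns)]


def item_columns(samples: pd.DataFrame) -> list[str]:
    """Item columns of an assembled time-point table."""
    return [c for c in samples.columns if c not in META_COLUMNS]


def label_for_horizon(days_to_death, horizon_n: int,
                      month_days: float = MONTH_DAYS,
                      window_days: int = WINDOW_DAYS):
    """Label samples for an ``n``-month prediction horizon.

    ``event`` if ``days_to_death <= n * month_days`` (death within the
    horizon), ``control`` if the sample lies in the remainder of the window.
    Accepts a scalar or array; samples outside the window raise — callers
    must pre-filter with :func:`assemble_time_points`.
    """
    mask = event_indicator(days_to_death, horizon_n, month_days, window_days)
    labels = np.where(mask, "event", "control")
    return str(labels[()]) if np.isscalar(days_to_death) else labels


def event_indicator(days_to_death, horizon_n: int,
                    month_days: float = MONTH_DAYS,
                    window_days: int = WINDOW_DAYS) -> np.ndarray:
    """Boolean event mask for a horizon (True = event); vectorized core."""
    if not (isinstance(horizon_n, (int, np.integer)) and horizon_n >= 1):
        raise ValueError("horizon_n must be a positive integer")
    if horizon_n * month_days >= window_days:
        raise ValueError("horizon must lie strictly inside the window")
    d = np.asarray(days_to_death, dtype=float)
    if np.any((d < 0) | (d > window_days)):
        raise ValueError("sample outside the look-back window")
    return d <= horizon_n * month_days


def split_patients(patients: pd.DataFrame | Sequence[str],
                   test_fraction: float = 0.5,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Randomly split patients into disjoint training and test cohorts.

    The split is at the patient level (no patient contributes time points to
    both cohorts), unstratified, with ``floor(N * (1 - test_fraction))``
    training patients, and deterministic for a given seed.
    """
    if isinstance(patients, pd.DataFrame):
        ids = patients["patient_id"].tolist()
    else:
        ids = list(patients)
    ids = sorted(set(ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * (1.0 - test_fraction)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test
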
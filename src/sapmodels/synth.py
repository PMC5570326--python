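"""Synthetic longitudinal laboratory cohorts with pre-mortem trend structure.

Real oncology registries record routine laboratory panels at irregular
intervals; in decedents the final year shows characteristic terminal trends
(albumin falls, lactate dehydrogenase and neutrophils rise).  This module
generates cohorts with exactly that structure so the labeling, model-search
and evaluation stages can be exercised end to end without patient data.

Each item follows an exponential approach to a terminal level:

    mean(d) = baseline_mean + terminal_shift * exp(-d / onset_tau_days)

where ``d`` is days to death.  Far from death the item sits at its baseline;
at death it sits at ``baseline_mean + terminal_shift``.  Observed values add
a per-patient baseline offset (``baseline_sd``) and per-measurement Gaussian
noise (``noise_sd``), truncated at the physiologic floor of zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemTrendSpec",
    "SynthConfig",
    "item_trajectory_mean",
    "generate_cohort",
    "default_item_specs",
    "default_config",
    "write_cohort",
    "save_config",
    "load_config",
]

#: Tumor-type label frequencies, loosely mirroring a mixed solid-tumor
#: chemotherapy population (lung and pancreas dominant).
TUMOR_TYPE_FREQS: dict[str, float] = {
    "lung": 0.30,
    "pancreas": 0.15,
    "colorectal": 0.12,
    "stomach": 0.10,
    "breast": 0.07,
    "esophagus": 0.05,
    "bile_duct": 0.05,
    "lymphoma": 0.05,
    "liver": 0.04,
    "other": 0.07,
}


@dataclass(frozen=True)
class ItemTrendSpec:
    """Trend parameters for one laboratory item.

    Parameters
    ----------
    item_code : str
        Short item code, e.g. ``"ALB"``.
    baseline_mean : float
        Population mean far from death, in item units.
    baseline_sd : float
        Between-patient SD of the stable baseline level.
    terminal_shift : float
        Signed displacement reached at death; negative for albumin-like
        decline, positive for LDH/neutrophil-like rise, zero for null items.
    onset_tau_days : float
        Time constant of the exponential terminal change, days.
    noise_sd : float
        Within-patient measurement noise SD.
    specimen : str
        ``"blood"`` or ``"urine"``.
    """

    item_code: str
    baseline_mean: float
    baseline_sd: float = 0.0
    terminal_shift: float = 0.0
    onset_tau_days: float = 60.0
    noise_sd: float = 0.0
    specimen: str = "blood"

    def __post_init__(self) -> None:
        if not self.item_code:
            raise ValueError("item_code must be non-empty")
        if self.onset_tau_days <= 0:
            raise ValueError("onset_tau_days must be > 0")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("baseline_sd and noise_sd must be >= 0")
        if self.specimen not in ("blood", "urine"):
            raise ValueError(f"unknown specimen {self.specimen!r}")


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic cohort.

    ``signal_items`` defaults to the items whose ``terminal_shift`` is
    non-zero; if given explicitly it must match them.
    """

    n_patients: int
    item_specs: tuple[ItemTrendSpec, ...]
    panel_interval_days_mean: float = 8.5
    missing_rate: float = 0.25
    follow_up_days: int = 365
    seed: int = 0
    signal_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.panel_interval_days_mean <= 0:
            raise ValueError("panel_interval_days_mean must be > 0")
        if self.follow_up_days <= 0:
            raise ValueError("follow_up_days must be > 0")
        codes = [s.item_code for s in self.item_specs]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate item codes in item_specs")
        shifted = tuple(s.item_code for s in self.item_specs if s.terminal_shift != 0)
        if not self.signal_items:
            object.__setattr__(self, "signal_items", shifted)
        elif set(self.signal_items) - set(codes):
            raise ValueError("signal_items must be a subset of item codes")

    @property
    def n_items(self) -> int:
        return len(self.item_specs)


def item_trajectory_mean(spec: ItemTrendSpec, days_to_death) -> float | np.ndarray:
    """Noise-free expected value of an item ``days_to_death`` days before death.

    Exponential approach to the terminal level:
    ``baseline_mean + terminal_shift * exp(-d / onset_tau_days)``.
    """
    d = np.asarray(days_to_death, dtype=float)
    if np.any(d < 0):
        raise ValueError("days_to_death must be >= 0")
    out = spec.baseline_mean + spec.terminal_shift * np.exp(-d / spec.onset_tau_days)
    return float(out) if np.isscalar(days_to_death) else out


# 37 routine-panel null items with plausible adult reference-range values.
# (code, baseline_mean, baseline_sd, noise_sd)
_NULL_ITEMS: list[tuple[str, float, float, float]] = [
    ("WBC", 6.5, 1.5, 1.2), ("RBC", 4.4, 0.4, 0.2), ("HGB", 13.0, 1.3, 0.6),
    ("HCT", 39.0, 3.5, 1.5), ("PLT", 250.0, 50.0, 30.0), ("MCV", 90.0, 4.0, 1.5),
    ("MCH", 30.0, 1.5, 0.6), ("MCHC", 33.0, 1.0, 0.5), ("LYMPH", 28.0, 7.0, 4.0),
    ("MONO", 6.0, 1.5, 1.2), ("EOS", 2.5, 1.2, 0.8), ("BASO", 0.6, 0.2, 0.2),
    ("TP", 7.0, 0.5, 0.3), ("ALP", 250.0, 70.0, 30.0), ("AST", 25.0, 8.0, 5.0),
    ("ALT", 22.0, 9.0, 5.0), ("GGT", 40.0, 20.0, 8.0), ("TBIL", 0.7, 0.2, 0.15),
    ("BUN", 14.0, 4.0, 2.5), ("CRE", 0.8, 0.2, 0.08), ("NA", 140.0, 2.0, 1.5),
    ("K", 4.2, 0.3, 0.2), ("CL", 103.0, 2.5, 1.5), ("CA", 9.2, 0.4, 0.25),
    ("P", 3.5, 0.5, 0.3), ("GLU", 105.0, 20.0, 12.0), ("CRP", 1.5, 1.0, 0.8),
    ("UA", 5.0, 1.2, 0.5), ("AMY", 70.0, 25.0, 10.0), ("CK", 90.0, 40.0, 20.0),
    ("TCHO", 185.0, 35.0, 15.0), ("TG", 120.0, 45.0, 25.0), ("PT", 11.5, 0.8, 0.5),
    ("APTT", 30.0, 3.0, 1.5), ("FIB", 350.0, 70.0, 35.0), ("MG", 2.0, 0.2, 0.12),
    ("FE", 80.0, 30.0, 15.0),
]


def default_item_specs(n_items: int = 40) -> tuple[ItemTrendSpec, ...]:
    """Default roster: 3 signal items plus null routine-panel items.

    ALB declines terminally (g/dL), LDH rises (U/L), NEU (% of leukocytes)
    rises.  ``n_items`` trims the roster; the 3 signal items always come
    first, so the smallest usable roster is 3.
    """
    if not (3 <= n_items <= 3 + len(_NULL_ITEMS)):
        raise ValueError(f"n_items must be in [3, {3 + len(_NULL_ITEMS)}]")
    specs = [
        ItemTrendSpec("ALB", 4.0, 0.3, terminal_shift=-1.5, onset_tau_days=60.0,
                      noise_sd=0.3),
        ItemTrendSpec("LDH", 200.0, 40.0, terminal_shift=180.0, onset_tau_days=60.0,
                      noise_sd=40.0),
        ItemTrendSpec("NEU", 60.0, 8.0, terminal_shift=15.0, onset_tau_days=60.0,
                      noise_sd=8.0),
    ]
    for code, mean, bsd, nsd in _NULL_ITEMS[: n_items - 3]:
        specs.append(ItemTrendSpec(code, mean, bsd, noise_sd=nsd))
    return tuple(specs)


def default_config(n_patients: int = 500, n_items: int = 40, seed: int = 0,
                   **overrides) -> SynthConfig:
    """Convenience builder for the standard study conditions."""
    return SynthConfig(
        n_patients=n_patients,
        item_specs=default_item_specs(n_items),
        seed=seed,
        **overrides,
    )


def _panel_days(rng: np.random.Generator, mean_gap: float, follow_up: int) -> np.ndarray:
    """Irregular panel times (days to death), Poisson-process-like spacing.

    Exponential inter-panel gaps rounded to whole days (minimum 1 day) and
    accumulated back from the death date, truncated to the follow-up window.
    Every patient gets at least one panel.
    """
    n_draw = max(20, int(3 * follow_up / mean_gap) + 10)
    gaps = np.maximum(1, np.round(rng.exponential(mean_gap, size=n_draw)))
    days = np.cumsum(gaps)
    days = days[days <= follow_up]
    if days.size == 0:
        days = np.array([float(min(follow_up, max(1, round(gaps[0]))))])
    return days.astype(int)


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a decedent cohort and its long-format lab observations.

    Returns
    -------
    patients : DataFrame with columns ``patient_id, death_date, tumor_type``.
    observations : DataFrame with columns
        ``patient_id, obs_date, item_code, value, specimen``.

    Identical ``config`` (including seed) gives bit-identical tables.  No
    observation postdates the patient's death date, and with
    ``missing_rate = 0`` every panel carries all items.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.item_specs
    n_items = len(specs)
    codes = np.array([s.item_code for s in specs])
    specimens = np.array([s.specimen for s in specs])
    base_mean = np.array([s.baseline_mean for s in specs])
    base_sd = np.array([s.baseline_sd for s in specs])
    shift = np.array([s.terminal_shift for s in specs])
    tau = np.array([s.onset_tau_days for s in specs])
    noise_sd = np.array([s.noise_sd for s in specs])

    tumor_types = list(TUMOR_TYPE_FREQS)
    tumor_p = np.array(list(TUMOR_TYPE_FREQS.values()))
    tumor_p = tumor_p / tumor_p.sum()

    width = max(4, len(str(config.n_patients)))
    patient_rows = []
    obs_parts = []
    anchor = pd.Timestamp("2014-01-01")
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        death = anchor + pd.Timedelta(days=int(rng.integers(0, 365)))
        tumor = tumor_types[rng.choice(len(tumor_types), p=tumor_p)]
        patient_rows.append((pid, death, tumor))

        days = _panel_days(rng, config.panel_interval_days_mean, config.follow_up_days)
        n_panels = days.size
        offsets = rng.normal(0.0, base_sd, size=n_items)
        mean = base_mean + offsets + shift * np.exp(-days[:, None] / tau)
        values = mean + rng.normal(0.0, 1.0, size=(n_panels, n_items)) * noise_sd
        np.clip(values, 0.0, None, out=values)  # physiologic floor

        if config.missing_rate > 0:
            keep = rng.random((n_panels, n_items)) >= config.missing_rate
        else:
            keep = np.ones((n_panels, n_items), dtype=bool)
        panel_idx, item_idx = np.nonzero(keep)
        obs_parts.append(pd.DataFrame({
            "patient_id": pid,
            "obs_date": death - pd.to_timedelta(days[panel_idx], unit="D"),
            "item_code": codes[item_idx],
            "value": values[panel_idx, item_idx],
            "specimen": specimens[item_idx],
        }))

    patients = pd.DataFrame(patient_rows,
                            columns=["patient_id", "death_date", "tumor_type"])
    observations = pd.concat(obs_parts, ignore_index=True)
    return patients, observations


def write_cohort(patients: pd.DataFrame, observations: pd.DataFrame,
                 lab_path, patient_path) -> None:
    """Write the two cohort tables in the CSV dialects the readers expect."""
    pat = patients.copy()
    pat["death_date"] = pd.to_datetime(pat["death_date"]).dt.strftime("%Y-%m-%d")
    pat.to_csv(patient_path, index=False)
    obs = observations.copy()
    obs["obs_date"] = pd.to_datetime(obs["obs_date"]).dt.strftime("%Y-%m-%d")
    obs.to_csv(lab_path, index=False)


def save_config(config: SynthConfig, path) -> None:
    """Serialize a config to a flat YAML document with an item-spec table."""
    doc = dataclasses.asdict(config)
    doc["item_specs"] = [dataclasses.asdict(s) for s in config.item_specs]
    doc["signal_items"] = list(config.signal_items)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SynthConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = tuple(ItemTrendSpec(**s) for s in doc.pop("item_specs"))
    doc["signal_items"] = tuple(doc.get("signal_items") or ())
    return SynthConfig(item_specs=specs, **doc)
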
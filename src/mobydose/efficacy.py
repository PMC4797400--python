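"""Therapy-outcome analysis: tumor volumes, endpoints, survival.

Caliper tumor volume uses the rotated-ellipsoid approximation
V = (1/2) w^2 l.  The humane-endpoint rule removes an animal when body
weight drops by more than 20 % from baseline or any tumor diameter
exceeds 15 mm; both comparisons are strict, so exactly-at-boundary values
do not trigger.  Survival is summarized with the Kaplan-Meier
product-limit estimator (via lifelines); the median is the earliest time
at which S(t) <= 0.5 and is reported as ``None`` when S stays above 0.5
through the end of follow-up (120 days), the convention used when almost
all animals in a group are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "CaliperMeasurement",
    "SurvivalRecord",
    "tumor_volume",
    "evaluate_endpoint",
    "kaplan_meier",
    "percent_volume_change",
    "STUDY_END_DAY",
    "ENDPOINT_DIAMETER_MM",
    "ENDPOINT_WEIGHT_LOSS_FRACTION",
]

STUDY_END_DAY = 120.0
ENDPOINT_DIAMETER_MM = 15.0
ENDPOINT_WEIGHT_LOSS_FRACTION = 0.20

_COHORT_COLUMNS = ["animal_id", "group", "day", "width_mm", "length_mm", "weight_g"]


@dataclass(frozen=True)
class CaliperMeasurement:
    """One caliper reading; width <= length by caliper convention."""

    animal_id: str
    day: float
    width_mm: float
    length_mm: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.width_mm < 0 or self.length_mm < 0:
            raise ValueError("caliper dimensions must be non-negative")
        if self.width_mm > self.length_mm:
            raise ValueError("caliper convention requires width <= length")


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    group: str
    event_time_days: float
    event: bool  # True = endpoint reached, False = censored at study end

    def __post_init__(self) -> None:
        if not 0 < self.event_time_days <= STUDY_END_DAY:
            raise ValueError(f"event time must lie in (0, {STUDY_END_DAY}] days")


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Rotated-ellipsoid caliper volume V = 0.5 w^2 l, in mm^3."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("caliper width and length must be positive")
    return 0.5 * width_mm**2 * length_mm


def evaluate_endpoint(m: CaliperMeasurement, baseline_weight_g: float) -> bool:
    """True when the animal meets the removal criterion.

    Weight loss strictly greater than 20 % of baseline, or a tumor
    diameter strictly exceeding 15 mm.  A measurement exactly at either
    boundary does not trigger.
    """
    if baseline_weight_g is None or baseline_weight_g <= 0:
        raise ValueError("baseline body weight (day 0) is required")
    weight_trigger = m.body_weight_g < (1.0 - ENDPOINT_WEIGHT_LOSS_FRACTION) * baseline_weight_g
    size_trigger = max(m.width_mm, m.length_mm) > ENDPOINT_DIAMETER_MM
    return bool(weight_trigger or size_trigger)


def kaplan_meier(
    records: list[SurvivalRecord],
) -> tuple[pd.DataFrame, float | None]:
    """Product-limit survival estimate and median survival in days.

    Returns ``(survival_table, median)`` where the table has columns
    ``time`` and ``survival``; the median is the earliest time with
    S(t) <= 0.5 or ``None`` if the survival curve never drops that far
    within follow-up.
    """
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.event_time_days for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        return sf, None
    return sf, median


def percent_volume_change(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-animal tumor volume as percent of its day-0 volume.

    Expects columns animal_id, group, day, width_mm, length_mm, weight_g.
    Returns one row per (group, day) with the mean percent volume over the
    animals still measured at that day (attrition handled by averaging
    surviving animals only, recorded in the ``n_animals`` column).
    Raises ``ValueError`` for animals with a zero day-0 volume.
    """
    missing = [c for c in _COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    df = cohort.copy()
    df["volume"] = 0.5 * df["width_mm"] ** 2 * df["length_mm"]
    pct_rows = []
    for animal, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("day")
        base = grp.loc[grp["day"] == grp["day"].min(), "volume"].iloc[0]
        if base <= 0:
            raise ValueError(f"animal {animal}: zero baseline tumor volume")
        for _, row in grp.iterrows():
            pct_rows.append(
                {
                    "group": row["group"],
                    "animal_id": animal,
                    "day": row["day"],
                    "percent_of_initial": 100.0 * row["volume"] / base,
                }
            )
    pct = pd.DataFrame(pct_rows)
    out = (
        pct.groupby(["group", "day"])
        .agg(
            mean_percent=("percent_of_initial", "mean"),
            n_animals=("animal_id", "nunique"),
        )
        .reset_index()
    )
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (animal_id, group, day, width_mm, length_mm, weight_g)."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    return df


def survival_records_from_cohort(cohort: pd.DataFrame) -> list[SurvivalRecord]:
    """Apply the endpoint rule measurement-by-measurement to build records.

    The event time is the first measurement day at which the rule
    triggers; animals never triggering are censored at day 120.  Animals
    with a cured (zero-size) tumor simply never trigger the size rule.
    """
    records = []
    for animal, grp in cohort.groupby("animal_id", sort=False):
        grp = grp.sort_values("day")
        baseline = float(grp["weight_g"].iloc[0])
        group = str(grp["group"].iloc[0])
        event_day = None
        for _, row in grp.iterrows():
            if row["day"] <= 0:
                continue
            m = CaliperMeasurement(
                animal_id=str(animal),
                day=float(row["day"]),
                width_mm=float(row["width_mm"]),
                length_mm=float(row["length_mm"]),
                body_weight_g=float(row["weight_g"]),
            )
            if evaluate_endpoint(m, baseline):
                event_day = float(row["day"])
                break
        if event_day is None:
            records.append(SurvivalRecord(str(animal), group, STUDY_END_DAY, False))
        else:
            records.append(SurvivalRecord(str(animal), group, event_day, True))
    return records
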
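"""Dual-threshold habitat classification and scenario accounting.

A reach is suitable for acid-sensitive coldwater species only when its
July mean daily maximum stream temperature is strictly below the thermal
threshold (default 20 C) AND its ANC is strictly above the acidity
threshold (default 50 ueq/L).  The four categories partition every
(temperature, ANC) pair:

    suitable  T <  t_max and ANC >  anc_min
    warm      T >= t_max and ANC >  anc_min
    acidic    T <  t_max and ANC <= anc_min
    both      T >= t_max and ANC <= anc_min

Summaries follow the stressor-column convention in which the "too warm"
and "too acidic" columns each include the overlap and the overlap is also
reported on its own, giving the per-unit accounting identity

    warm + acidic - both + suitable = total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stream_network import StreamNetwork

SUITABLE, WARM, ACIDIC, BOTH = "suitable", "warm", "acidic", "both"
CATEGORIES = (WARM, ACIDIC, BOTH, SUITABLE)


@dataclass
class HabitatThresholds:
    t_max_c: float = 20.0
    anc_min_ueq_l: float = 50.0

    def __post_init__(self) -> None:
        if not (5.0 <= self.t_max_c <= 35.0):
            raise ValueError("thermal threshold outside plausible 5-35 C range")
        if self.anc_min_ueq_l <= 0:
            raise ValueError("ANC threshold must be positive")


def classify_reach(
    jmmst_c: float, anc_ueq_l: float, thresholds: HabitatThresholds
) -> str:
    """Category for one reach.  Boundary-equal values (T exactly at the
    thermal threshold, ANC exactly at the acidity threshold) are
    unsuitable, matching the strict inequalities in the suitability
    definition."""
    if not (np.isfinite(jmmst_c) and np.isfinite(anc_ueq_l)):
        raise ValueError("temperature and ANC must be finite")
    warm = jmmst_c >= thresholds.t_max_c
    acidic = anc_ueq_l <= thresholds.anc_min_ueq_l
    if warm and acidic:
        return BOTH
    if warm:
        return WARM
    if acidic:
        return ACIDIC
    return SUITABLE


def classify_series(
    jmmst_c, anc_ueq_l, thresholds: HabitatThresholds
) -> np.ndarray:
    t = np.asarray(jmmst_c, dtype=float)
    a = np.asarray(anc_ueq_l, dtype=float)
    warm = t >= thresholds.t_max_c
    acidic = a <= thresholds.anc_min_ueq_l
    out = np.where(
        warm & acidic, BOTH,
        np.where(warm, WARM, np.where(acidic, ACIDIC, SUITABLE)),
    )
    return out


_SUMMARY_COLS = [
    "total_km",
    "warm_km", "warm_pct",
    "acidic_km", "acidic_pct",
    "both_km", "both_pct",
    "suitable_km", "suitable_pct",
]


def summary_from_lengths(
    warm_km: float, acidic_km: float, both_km: float, suitable_km: float
) -> dict[str, float]:
    """One summary row from category lengths alone (the overlap is counted
    once in each stressor column, so it is subtracted when totaling)."""
    total = warm_km + acidic_km - both_km + suitable_km
    row = {
        "total_km": total,
        "warm_km": warm_km,
        "acidic_km": acidic_km,
        "both_km": both_km,
        "suitable_km": suitable_km,
    }
    for cat in ("warm", "acidic", "both", "suitable"):
        row[f"{cat}_pct"] = 100.0 * row[f"{cat}_km"] / total if total > 0 else 0.0
    return row


def summarize(
    network: StreamNetwork,
    jmmst: Mapping[int, float] | pd.Series,
    anc: Mapping[int, float] | pd.Series,
    thresholds: HabitatThresholds,
    unit_level: str = "district",
) -> pd.DataFrame:
    """Per-unit stream-length accounting under the dual thresholds.

    Stressor columns (warm, acidic) each include the overlap; the overlap
    ("both") is reported separately, so warm + acidic - both + suitable =
    total in every row.  A TOTAL row sums the units.  Empty units yield a
    zero row with zero percents.
    """
    rows: dict[str, dict[str, float]] = {}
    for r in network:
        if unit_level == "forest":
            unit = r.unit_forest
        elif unit_level == "district":
            unit = r.unit_district
        elif unit_level == "all":
            unit = "ALL"
        else:
            raise ValueError(f"unknown unit level {unit_level!r}")
        cat = classify_reach(float(jmmst[r.reach_id]), float(anc[r.reach_id]),
                             thresholds)
        acc = rows.setdefault(
            unit, {WARM: 0.0, ACIDIC: 0.0, BOTH: 0.0, SUITABLE: 0.0}
        )
        if cat == BOTH:  # overlap counts in both stressor columns
            acc[WARM] += r.length_km
            acc[ACIDIC] += r.length_km
            acc[BOTH] += r.length_km
        else:
            acc[cat] += r.length_km

    out = []
    for unit in sorted(rows):
        acc = rows[unit]
        row = summary_from_lengths(
            acc[WARM], acc[ACIDIC], acc[BOTH], acc[SUITABLE]
        )
        row["unit"] = unit
        out.append(row)
    df = pd.DataFrame(out).set_index("unit")[_SUMMARY_COLS]

    totals = df[[c for c in _SUMMARY_COLS if c.endswith("_km")]].sum()
    trow = summary_from_lengths(
        totals["warm_km"], totals["acidic_km"], totals["both_km"],
        totals["suitable_km"],
    )
    df.loc["TOTAL"] = [trow[c] for c in _SUMMARY_COLS]
    return df


def compare_scenarios(
    baseline: pd.DataFrame, future: pd.DataFrame
) -> pd.DataFrame:
    """Change in suitable habitat between two summaries with matching units.

    Delta percent = 100 * (future suitable - baseline suitable) / total.
    """
    if list(baseline.index) != list(future.index):
        raise ValueError("scenario summaries cover different units")
    out = pd.DataFrame(index=baseline.index)
    out["total_km"] = baseline["total_km"]
    out["suitable_km_baseline"] = baseline["suitable_km"]
    out["suitable_pct_baseline"] = baseline["suitable_pct"]
    out["suitable_km_future"] = future["suitable_km"]
    out["suitable_pct_future"] = future["suitable_pct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (
            future["suitable_km"] - baseline["suitable_km"]
        ) / baseline["total_km"]
    out["delta_pct"] = delta.fillna(0.0)
    return out
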
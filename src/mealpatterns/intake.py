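"""Diary cleaning, eating-occasion construction and time-series extraction.

The pipeline from raw diary records to clusterable series is:

1. ``validate_days`` — any individual.day containing a record with a
   missing clock time is excluded in full (clock times are what define
   eating occasions, so a day with unknown times cannot be aggregated).
2. ``build_eos`` — records sharing an exact (participant, date, time)
   stamp form one eating occasion (EO); per-item utilisable nutrients
   come from the composition module and are summed per EO.  Items with
   less than 0.5 g of (digestibility-unadjusted) protein are dropped
   first; an EO left empty disappears.
3. ``to_series`` — each retained individual.day becomes one ordered
   series of per-EO protein values (the object that is clustered), with
   per-EO IAA vectors carried alongside.

Days are indexed 1-based per participant in date order; calendar gaps do
not renumber days.  An EO at 00:30 belongs to its calendar date (days
are 00:00–23:59 windows; midnight is not crossed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import IAAS, FoodCompositionEntry, composition_frame

__all__ = [
    "IntakeSeries",
    "validate_days",
    "build_eos",
    "coverage_report",
    "to_series",
    "DEFAULT_MIN_ITEM_PROTEIN_G",
]

#: Items below this much protein per EO are excluded before summation.
DEFAULT_MIN_ITEM_PROTEIN_G = 0.5

IAA_COLS = [f"{aa}_g" for aa in IAAS]


class IntakeError(ValueError):
    pass


@dataclass(frozen=True)
class IntakeSeries:
    """One individual.day as an ordered sequence of per-EO protein values."""

    series_id: str  # "participant.day", e.g. "2.1"
    participant_id: str
    day: int
    values: np.ndarray  # per-EO utilisable protein, g
    eo_times: np.ndarray  # minutes since 00:00, strictly increasing
    iaa_values: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise IntakeError(f"{self.series_id}: empty series")
        if len(self.values) != len(self.eo_times):
            raise IntakeError(f"{self.series_id}: values/times length mismatch")
        if np.any(np.diff(self.eo_times) <= 0):
            raise IntakeError(f"{self.series_id}: EO times not strictly increasing")


def _time_to_minutes(time_str: pd.Series) -> pd.Series:
    parts = time_str.str.split(":", expand=True)
    return parts[0].astype(int) * 60 + parts[1].astype(int)


def _day_index(clean: pd.DataFrame) -> pd.Series:
    """1-based day number per participant, in date order (recording order)."""
    return (
        clean.groupby("participant_id")["date"]
        .transform(lambda s: s.map({d: i + 1 for i, d in enumerate(sorted(s.unique()))}))
        .astype(int)
    )


def validate_days(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every individual.day that contains a record with a missing time.

    Parameters
    ----------
    records : DataFrame
        Columns participant_id, date, time, food_id, amount_g; ``time``
        may be blank/NaN for records whose clock time is unknown.

    Returns
    -------
    clean : DataFrame
        Records of fully timestamped days only.
    report : DataFrame
        One row per excluded individual.day (participant_id, date,
        reason).
    """
    records = records.copy()
    records["participant_id"] = records["participant_id"].astype(str)
    missing = records["time"].isna() | (records["time"].astype(str).str.strip() == "")
    day_key = records["participant_id"] + "\0" + records["date"].astype(str)
    bad_days = set(day_key[missing])
    clean = records.loc[~day_key.isin(bad_days)].copy()
    report = (
        records.loc[day_key.isin(bad_days), ["participant_id", "date"]]
        .drop_duplicates()
        .assign(reason="missing time record")
        .reset_index(drop=True)
    )
    return clean, report


def build_eos(
    clean_records: pd.DataFrame,
    composition: Sequence[FoodCompositionEntry] | pd.DataFrame,
    min_item_protein_g: float = DEFAULT_MIN_ITEM_PROTEIN_G,
    filter_after_tid: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate records into eating occasions with utilisable nutrients.

    Records sharing an exact (participant, date, time) stamp form one
    EO.  Per-item protein and amino acids are computed from the
    composition table, digestibility-adjusted, and summed per EO.  The
    low-protein filter removes items under ``min_item_protein_g`` grams
    of protein — evaluated on unadjusted protein unless
    ``filter_after_tid`` is set.

    Returns
    -------
    eos : DataFrame
        One row per EO: participant_id, day, date, time_min, protein_g,
        one ``<aa>_g`` column per tracked IAA, item_count.
    items : DataFrame
        Retained item-level rows (used for food-group contributions and
        coverage): adds food_group, protein_raw_g and the adjusted
        nutrient columns.
    """
    comp = (
        composition
        if isinstance(composition, pd.DataFrame)
        else composition_frame(list(composition))
    )
    clean = clean_records.copy()
    clean["participant_id"] = clean["participant_id"].astype(str)
    clean["food_id"] = clean["food_id"].astype(str)

    unknown = sorted(set(clean["food_id"]) - set(comp["food_id"].astype(str)))
    if unknown:
        raise IntakeError(f"unresolvable food ids: {', '.join(unknown)}")
    if len(clean) == 0:
        empty = pd.DataFrame(
            columns=["participant_id", "day", "date", "time_min", "protein_g",
                     *IAA_COLS, "item_count"]
        )
        return empty, empty.copy()

    items = clean.merge(comp, on="food_id", how="left", validate="many_to_one")
    items["protein_raw_g"] = items["protein_per_100g"] * items["amount_g"] / 100.0
    items["protein_g"] = items["protein_raw_g"] * items["tid_protein"]
    for aa in IAAS:
        items[f"{aa}_g"] = (
            items[f"aa_{aa}_mg_per_g_protein"]
            * items["protein_raw_g"]
            / 1000.0
            * items[f"tid_{aa}"]
        )

    # day numbering fixed before filtering, so dropping a whole day's
    # items cannot renumber later days
    items["day"] = _day_index(items)
    items["time_min"] = _time_to_minutes(items["time"].astype(str))

    filter_col = "protein_g" if filter_after_tid else "protein_raw_g"
    items = items.loc[items[filter_col] >= min_item_protein_g].copy()
    eos = (
        items.groupby(["participant_id", "day", "date", "time_min"], as_index=False)
        .agg(
            protein_g=("protein_g", "sum"),
            **{col: (col, "sum") for col in IAA_COLS},
            item_count=("food_id", "size"),
        )
        .sort_values(["participant_id", "day", "time_min"], kind="stable")
        .reset_index(drop=True)
    )
    keep = [
        "participant_id", "date", "day", "time_min", "food_id", "food_group",
        "amount_g", "protein_raw_g", "protein_g", *IAA_COLS,
    ]
    return eos, items[keep].reset_index(drop=True)


def coverage_report(
    pre_filter: pd.DataFrame, post_filter: pd.DataFrame
) -> dict[str, float | None]:
    """Fraction of protein intake retained by the low-protein item filter.

    Both frames must carry participant_id and an unadjusted
    ``protein_raw_g`` column over the same record universe.  Returns the
    cohort-level retained fraction and the minimum per-participant
    retained fraction (both in percent); ``None`` when the pre-filter
    total is zero (coverage undefined).
    """
    pre_total = float(pre_filter["protein_raw_g"].sum())
    if pre_total == 0:
        return {"cohort_pct": None, "min_participant_pct": None}
    post_total = float(post_filter["protein_raw_g"].sum())
    pre_by = pre_filter.groupby("participant_id")["protein_raw_g"].sum()
    post_by = post_filter.groupby("participant_id")["protein_raw_g"].sum()
    per_participant = (post_by.reindex(pre_by.index, fill_value=0.0) / pre_by) * 100.0
    return {
        "cohort_pct": 100.0 * post_total / pre_total,
        "min_participant_pct": float(per_participant.min()),
    }


def to_series(eos: pd.DataFrame) -> list[IntakeSeries]:
    """One :class:`IntakeSeries` per retained individual.day.

    Values are per-EO utilisable protein in grams, ordered by clock
    time; the per-EO IAA vectors ride along for downstream summaries.
    Ordering of series follows (participant in input order, day).
    """
    series: list[IntakeSeries] = []
    for (pid, day), group in eos.groupby(["participant_id", "day"], sort=False):
        group = group.sort_values("time_min", kind="stable")
        series.append(
            IntakeSeries(
                series_id=f"{pid}.{day}",
                participant_id=str(pid),
                day=int(day),
                values=group["protein_g"].to_numpy(dtype=float),
                eo_times=group["time_min"].to_numpy(dtype=int),
                iaa_values=group[IAA_COLS].reset_index(drop=True),
            )
        )
    return series
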
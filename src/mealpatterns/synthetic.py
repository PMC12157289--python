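"""Synthetic food-diary cohort generator.

Emulates a four-day timestamped food diary for a vegan cohort whose
individuals follow one of three latent meal-pattern archetypes:

* ``grazing`` — frequent eating occasions (EOs) with low protein each
  (many small snacks spread across a long eating window);
* ``moderate`` — intermediate frequency and per-EO protein;
* ``infrequent_high`` — fewer EOs, each carrying meal-sized protein.

Default archetype calibration targets the cluster statistics the
downstream analysis is designed to recover: per-EO protein means of
6.5 / 11.4 / 19.0 g and 6.5 / 5.2 / 5.0 EOs per day, with mixture
weights 0.384 / 0.46 / 0.156.  Within-archetype protein standard
deviations are free parameters (see docs/methods.md).

Every draw flows through one :func:`numpy.random.default_rng` stream, so
identical (config, seed) yields byte-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import FoodCompositionEntry, write_composition

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "default_archetypes",
    "default_composition",
    "generate_cohort",
    "inject_missing_times",
    "write_cohort",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeSpec:
    """One latent meal-pattern archetype.

    ``eo_per_day_mean`` is the expected number of EOs per day (realised
    as 1 + Poisson(mean - 1), so the minimum is one EO and the mean is
    exact).  ``protein_per_eo_mean``/``sd`` parameterise a
    truncated-at-zero normal for per-EO target protein in grams, on
    the utilisable (digestibility-adjusted) scale the analysis reports.
    ``foodgroup_weights`` are sampling probabilities over food groups
    present in the composition table.  Timestamps fall in
    [``start_hour``, ``end_hour``).
    """

    label: str
    eo_per_day_mean: float
    protein_per_eo_mean: float
    protein_per_eo_sd: float
    foodgroup_weights: Mapping[str, float]
    start_hour: int = 7
    end_hour: int = 22
    body_fat_mean: float = 30.0
    body_fat_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.eo_per_day_mean <= 0:
            raise ConfigurationError("eo_per_day_mean must be > 0")
        if self.protein_per_eo_sd < 0:
            raise ConfigurationError("protein_per_eo_sd must be >= 0")
        total = sum(self.foodgroup_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"foodgroup_weights must sum to 1 (got {total})"
            )
        if not 0 <= self.start_hour < self.end_hour <= 24:
            raise ConfigurationError("need 0 <= start_hour < end_hour <= 24")


@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 193
    n_days: int = 4
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "grazing": 0.384,
            "moderate": 0.460,
            "infrequent_high": 0.156,
        }
    )
    n_corrupted_days: int = 0
    #: Fraction of EOs that receive an extra sub-0.5 g protein item, to
    #: exercise the low-protein item filter.  Zero by default.
    low_protein_item_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype_mix must sum to 1 (got {total})"
            )
        if self.n_corrupted_days > self.n_individuals * self.n_days:
            raise ConfigurationError(
                "n_corrupted_days exceeds available individual.days"
            )


# ---------------------------------------------------------------------------
# Defaults

def default_composition() -> list[FoodCompositionEntry]:
    """A compact plant-food composition table.

    Protein densities and amino-acid profiles are typical literature
    values for common vegan staples; TID fractions are in the 0.75-0.95
    range reported for plant foods.  The table is deliberately small —
    it provides realistic relative food-group contributions, not a food
    database.
    """
    # (food_id, group, protein/100g, {aa mg/g protein}, tid)
    legume_aa = {
        "tryptophan": 10.0, "threonine": 37.0, "leucine": 76.0,
        "lysine": 66.0, "methionine": 11.0, "cystine": 11.0,
        "histidine": 27.0,
    }
    grain_aa = {
        "tryptophan": 12.0, "threonine": 30.0, "leucine": 70.0,
        "lysine": 28.0, "methionine": 17.0, "cystine": 22.0,
        "histidine": 23.0,
    }
    soy_aa = {
        "tryptophan": 13.0, "threonine": 40.0, "leucine": 80.0,
        "lysine": 63.0, "methionine": 13.0, "cystine": 13.0,
        "histidine": 26.0,
    }
    nut_aa = {
        "tryptophan": 10.0, "threonine": 29.0, "leucine": 69.0,
        "lysine": 29.0, "methionine": 10.0, "cystine": 15.0,
        "histidine": 25.0,
    }
    veg_aa = {
        "tryptophan": 11.0, "threonine": 39.0, "leucine": 60.0,
        "lysine": 55.0, "methionine": 14.0, "cystine": 10.0,
        "histidine": 21.0,
    }
    fruit_aa = {
        "tryptophan": 9.0, "threonine": 28.0, "leucine": 50.0,
        "lysine": 45.0, "methionine": 8.0, "cystine": 9.0,
        "histidine": 55.0,
    }

    def tid(base: float) -> dict[str, float]:
        out = {"protein": base}
        # methionine/cystine digest slightly worse in plant matrices
        for aa in ("tryptophan", "threonine", "leucine", "lysine", "histidine"):
            out[aa] = min(1.0, base + 0.02)
        out["methionine"] = max(0.0, base - 0.03)
        out["cystine"] = max(0.0, base - 0.05)
        return out

    entries = [
        FoodCompositionEntry("lentils_cooked", "legumes and pulses", 9.0, legume_aa, tid(0.84)),
        FoodCompositionEntry("chickpeas_cooked", "legumes and pulses", 8.9, legume_aa, tid(0.83)),
        FoodCompositionEntry("baked_beans", "legumes and pulses", 5.2, legume_aa, tid(0.80)),
        FoodCompositionEntry("tofu_firm", "soy products", 12.0, soy_aa, tid(0.92)),
        FoodCompositionEntry("soy_milk", "soy products", 3.3, soy_aa, tid(0.92)),
        FoodCompositionEntry("pbma_burger", "soy products", 17.0, soy_aa, tid(0.90)),
        FoodCompositionEntry("bread_wholemeal", "breads and cereals", 9.5, grain_aa, tid(0.87)),
        FoodCompositionEntry("oats_rolled", "breads and cereals", 13.0, grain_aa, tid(0.88)),
        FoodCompositionEntry("pasta_cooked", "grains and pasta", 5.5, grain_aa, tid(0.89)),
        FoodCompositionEntry("rice_brown_cooked", "grains and pasta", 2.7, grain_aa, tid(0.86)),
        FoodCompositionEntry("almonds", "nuts and seeds", 21.0, nut_aa, tid(0.80)),
        FoodCompositionEntry("peanut_butter", "nuts and seeds", 25.0, nut_aa, tid(0.82)),
        FoodCompositionEntry("broccoli_cooked", "vegetables", 2.8, veg_aa, tid(0.78)),
        FoodCompositionEntry("potato_cooked", "potatoes, kumara and taro", 2.0, veg_aa, tid(0.80)),
        FoodCompositionEntry("banana", "fruit", 1.1, fruit_aa, tid(0.75)),
    ]
    return entries


def default_archetypes() -> list[ArchetypeSpec]:
    """Archetypes calibrated to the three-cluster structure the analysis targets."""
    return [
        ArchetypeSpec(
            label="grazing",
            eo_per_day_mean=6.5,
            protein_per_eo_mean=6.5,
            protein_per_eo_sd=1.8,
            foodgroup_weights={
                "fruit": 0.22, "breads and cereals": 0.24,
                "vegetables": 0.14, "nuts and seeds": 0.16,
                "grains and pasta": 0.10, "soy products": 0.08,
                "legumes and pulses": 0.04, "potatoes, kumara and taro": 0.02,
            },
            start_hour=7, end_hour=22,
            body_fat_mean=32.0, body_fat_sd=6.5,
        ),
        ArchetypeSpec(
            label="moderate",
            eo_per_day_mean=5.2,
            protein_per_eo_mean=11.4,
            protein_per_eo_sd=2.4,
            foodgroup_weights={
                "fruit": 0.10, "breads and cereals": 0.20,
                "vegetables": 0.12, "nuts and seeds": 0.12,
                "grains and pasta": 0.14, "soy products": 0.16,
                "legumes and pulses": 0.12, "potatoes, kumara and taro": 0.04,
            },
            start_hour=7, end_hour=21,
            body_fat_mean=30.0, body_fat_sd=7.6,
        ),
        ArchetypeSpec(
            label="infrequent_high",
            eo_per_day_mean=5.0,
            protein_per_eo_mean=19.0,
            protein_per_eo_sd=3.0,
            foodgroup_weights={
                "fruit": 0.04, "breads and cereals": 0.12,
                "vegetables": 0.10, "nuts and seeds": 0.10,
                "grains and pasta": 0.12, "soy products": 0.28,
                "legumes and pulses": 0.20, "potatoes, kumara and taro": 0.04,
            },
            start_hour=8, end_hour=21,
            body_fat_mean=25.4, body_fat_sd=6.8,
        ),
    ]


# ---------------------------------------------------------------------------
# Generation

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero, by rejection (mean >> 0 here)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > 0:
            return value
    return max(mean, 1e-6)  # pragma: no cover - pathological parameters


def _draw_items(
    rng: np.random.Generator,
    target_protein: float,
    archetype: ArchetypeSpec,
    foods_by_group: Mapping[str, list[FoodCompositionEntry]],
    min_item_protein: float = 0.6,
) -> list[tuple[str, float]]:
    """Realise a target EO protein as 1-3 food items with amounts in grams.

    The archetype target is *utilisable* (digestibility-adjusted)
    protein — the scale on which the downstream analysis reports — so
    item amounts are back-computed through each food's protein TID.
    Item protein shares are Dirichlet-distributed above a floor of
    ``min_item_protein`` grams each, so no generated item falls under
    the 0.5 g analysis filter unless injected explicitly.
    """
    groups = list(archetype.foodgroup_weights)
    probs = np.array([archetype.foodgroup_weights[g] for g in groups])
    max_items = max(1, min(3, int(target_protein / min_item_protein)))
    n_items = int(rng.integers(1, max_items + 1))
    floor_total = min_item_protein * n_items
    if target_protein > floor_total:
        weights = rng.dirichlet(np.full(n_items, 5.0))
        shares = min_item_protein + (target_protein - floor_total) * weights
    else:
        n_items = 1
        shares = np.array([target_protein])
    items: list[tuple[str, float]] = []
    for share in shares:
        group = groups[int(rng.choice(len(groups), p=probs))]
        food = foods_by_group[group][int(rng.integers(len(foods_by_group[group])))]
        tid_protein = food.tid.get("protein", 1.0)
        amount_g = share / (food.protein_per_100g / 100.0 * tid_protein)
        items.append((food.food_id, round(float(amount_g), 1)))
    return items


def generate_cohort(
    config: CohortConfig,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    composition: Sequence[FoodCompositionEntry] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate participants, diary records and truth labels.

    Returns
    -------
    participants : DataFrame
        participant_id, sex, body_weight_kg, bmi, body_fat_pct.
    diary : DataFrame
        participant_id, date (ISO-8601), time (HH:MM, possibly blank),
        food_id, amount_g.  Timestamps are strictly increasing within a
        participant-day; EO identity is controlled by distinct
        timestamps (records sharing a timestamp form one EO).
    truth : DataFrame
        participant_id, day, archetype — one row per individual.day.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if composition is None:
        composition = default_composition()
    if not composition:
        raise ConfigurationError("composition table is empty")
    by_label = {a.label: a for a in archetypes}
    missing = set(config.archetype_mix) - set(by_label)
    if missing:
        raise ConfigurationError(f"archetype_mix references unknown labels {missing}")

    foods_by_group: dict[str, list[FoodCompositionEntry]] = {}
    for entry in composition:
        foods_by_group.setdefault(entry.food_group, []).append(entry)
    for arch in archetypes:
        absent = set(arch.foodgroup_weights) - set(foods_by_group)
        if absent:
            raise ConfigurationError(
                f"archetype {arch.label} samples food groups with no foods: {absent}"
            )

    rng = np.random.default_rng(config.seed)
    mix_labels = list(config.archetype_mix)
    mix_probs = np.array([config.archetype_mix[l] for l in mix_labels])
    base_date = pd.Timestamp("2023-03-06")

    participant_rows, diary_rows, truth_rows = [], [], []
    for i in range(1, config.n_individuals + 1):
        pid = str(i)
        arch = by_label[mix_labels[int(rng.choice(len(mix_labels), p=mix_probs))]]
        sex = "F" if rng.random() < 0.731 else "M"
        body_weight = float(
            np.clip(rng.normal(70.0 if sex == "F" else 82.0, 12.0), 42.0, 140.0)
        )
        bmi = float(np.clip(rng.normal(24.0, 3.0), 16.5, 40.0))
        body_fat = float(
            np.clip(rng.normal(arch.body_fat_mean, arch.body_fat_sd), 8.0, 55.0)
        )
        participant_rows.append(
            {
                "participant_id": pid,
                "sex": sex,
                "body_weight_kg": round(body_weight, 1),
                "bmi": round(bmi, 1),
                "body_fat_pct": round(body_fat, 1),
            }
        )
        for day in range(1, config.n_days + 1):
            truth_rows.append(
                {"participant_id": pid, "day": day, "archetype": arch.label}
            )
            n_eo = 1 + int(rng.poisson(arch.eo_per_day_mean - 1.0))
            window = (arch.end_hour - arch.start_hour) * 60
            minutes = np.sort(rng.choice(window, size=min(n_eo, window), replace=False))
            date = (base_date + pd.Timedelta(days=day - 1)).date().isoformat()
            for minute in minutes:
                clock = arch.start_hour * 60 + int(minute)
                time_str = f"{clock // 60:02d}:{clock % 60:02d}"
                target = _truncated_normal(
                    rng, arch.protein_per_eo_mean, arch.protein_per_eo_sd
                )
                for food_id, amount in _draw_items(
                    rng, target, arch, foods_by_group
                ):
                    diary_rows.append(
                        {
                            "participant_id": pid,
                            "date": date,
                            "time": time_str,
                            "food_id": food_id,
                            "amount_g": amount,
                        }
                    )
                if (
                    config.low_protein_item_rate > 0
                    and rng.random() < config.low_protein_item_rate
                ):
                    # deliberately sub-filter item (< 0.5 g protein)
                    low_protein = rng.uniform(0.05, 0.45)
                    food = composition[int(rng.integers(len(composition)))]
                    amount = low_protein / (food.protein_per_100g / 100.0)
                    diary_rows.append(
                        {
                            "participant_id": pid,
                            "date": date,
                            "time": time_str,
                            "food_id": food.food_id,
                            "amount_g": round(float(amount), 1),
                        }
                    )

    participants = pd.DataFrame(participant_rows)
    diary = pd.DataFrame(diary_rows)
    truth = pd.DataFrame(truth_rows)
    if config.n_corrupted_days:
        diary, _ = inject_missing_times(
            diary, config.n_corrupted_days, seed=rng.integers(2**31)
        )
    return participants, diary, truth


def inject_missing_times(
    diary: pd.DataFrame, n_corrupted_days: int, seed: int | np.integer = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank the time field of every record on ``n_corrupted_days`` distinct
    individual.days, emulating diaries whose clock times could not be
    recovered (such days are excluded in full downstream).

    Returns the corrupted diary and a frame listing the corrupted days.
    """
    diary = diary.copy()
    days = diary[["participant_id", "date"]].drop_duplicates().reset_index(drop=True)
    if n_corrupted_days > len(days):
        raise ConfigurationError(
            f"n_corrupted_days={n_corrupted_days} exceeds {len(days)} recorded days"
        )
    if n_corrupted_days == 0:
        return diary, days.iloc[0:0]
    rng = np.random.default_rng(int(seed))
    picked = days.iloc[
        np.sort(rng.choice(len(days), size=n_corrupted_days, replace=False))
    ]
    key = diary["participant_id"].astype(str) + "\0" + diary["date"].astype(str)
    picked_key = set(
        picked["participant_id"].astype(str) + "\0" + picked["date"].astype(str)
    )
    diary.loc[key.isin(picked_key), "time"] = ""
    return diary, picked.reset_index(drop=True)


def write_cohort(
    out_dir: str | Path,
    participants: pd.DataFrame,
    diary: pd.DataFrame,
    truth: pd.DataFrame,
    composition: Sequence[FoodCompositionEntry] | None = None,
) -> dict[str, str]:
    """Write the four cohort CSVs; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if composition is None:
        composition = default_composition()
    paths = {
        "participants": out / "participants.csv",
        "diary": out / "diary.csv",
        "truth_labels": out / "truth_labels.csv",
        "composition": out / "composition.csv",
    }
    participants.to_csv(paths["participants"], index=False)
    diary.to_csv(paths["diary"], index=False)
    truth.to_csv(paths["truth_labels"], index=False)
    write_composition(list(composition), paths["composition"])
    return {k: str(v) for k, v in paths.items()}


def cohort_digest(diary: pd.DataFrame) -> str:
    """SHA-256 of the serialised diary; used to assert reproducibility."""
    return hashlib.sha256(diary.to_csv(index=False).encode()).hexdigest()
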
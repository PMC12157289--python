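"""Food-composition data model and protein-quality arithmetic.

A food is described by its protein density (g per 100 g of food), an
indispensable-amino-acid (IAA) profile expressed per gram of protein
(mg AA / g protein, the form in which reference amino-acid profiles are
published), and true-ileal-digestibility (TID) coefficients for protein
and for each tracked IAA.  Keying the amino-acid profile to protein makes
normalisation to a locally reported protein content a single multiply:
the amino-acid quantity in a food portion is the reference profile times
the portion's protein.

The tracked IAA set is the seven amino acids for which plant-food TID
values are available in the literature: tryptophan, threonine, leucine,
lysine, methionine, cystine and histidine.  Cystine is carried although it
is not strictly indispensable, because digestibility adjustment applies
to it in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "IAAS",
    "FoodCompositionEntry",
    "NutrientVector",
    "normalise_aa",
    "apply_tid",
    "nutrient_for_item",
    "read_composition",
    "write_composition",
    "composition_frame",
]

#: Amino acids tracked through digestibility adjustment, in canonical order.
IAAS: tuple[str, ...] = (
    "tryptophan",
    "threonine",
    "leucine",
    "lysine",
    "methionine",
    "cystine",
    "histidine",
)

#: Nutrient keys of a NutrientVector: total protein plus each tracked IAA.
NUTRIENTS: tuple[str, ...] = ("protein",) + IAAS


class CompositionError(ValueError):
    """Invalid composition data or composition arithmetic inputs."""


@dataclass(frozen=True)
class FoodCompositionEntry:
    """Composition of one food item.

    Parameters
    ----------
    food_id
        Unique identifier used to resolve diary records.
    food_group
        Food-group name (2008/09 NZ Adult Nutrition Survey style, e.g.
        ``"legumes and pulses"``, ``"grains and pasta"``).
    protein_per_100g
        Grams of protein per 100 g of food (as eaten).
    iaa_per_g_protein
        mg of each tracked amino acid per gram of food protein.
    tid
        True-ileal-digestibility fractions in [0, 1], keyed by
        ``"protein"`` and each amino-acid name.
    """

    food_id: str
    food_group: str
    protein_per_100g: float
    iaa_per_g_protein: Mapping[str, float] = field(default_factory=dict)
    tid: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_per_100g < 0:
            raise CompositionError(
                f"{self.food_id}: protein_per_100g must be >= 0"
            )
        unknown = set(self.iaa_per_g_protein) - set(IAAS)
        if unknown:
            raise CompositionError(
                f"{self.food_id}: unknown amino acids {sorted(unknown)}"
            )
        for key, value in self.tid.items():
            if not 0.0 <= value <= 1.0:
                raise CompositionError(
                    f"{self.food_id}: TID for {key} is {value}, not in [0, 1]"
                )


@dataclass(frozen=True)
class NutrientVector:
    """Protein plus per-IAA amounts, all in grams.

    Supports componentwise addition and scalar scaling, the only algebra
    the aggregation pipeline needs.
    """

    protein: float = 0.0
    iaa: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein < 0 or any(v < 0 for v in self.iaa.values()):
            raise CompositionError("nutrient amounts must be >= 0")

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        keys = set(self.iaa) | set(other.iaa)
        return NutrientVector(
            protein=self.protein + other.protein,
            iaa={k: self.iaa.get(k, 0.0) + other.iaa.get(k, 0.0) for k in keys},
        )

    def scale(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise CompositionError("scale factor must be >= 0")
        return NutrientVector(
            protein=self.protein * factor,
            iaa={k: v * factor for k, v in self.iaa.items()},
        )

    def get(self, nutrient: str) -> float:
        if nutrient == "protein":
            return self.protein
        return self.iaa.get(nutrient, 0.0)


def normalise_aa(
    reference_iaa_per_g_protein: Mapping[str, float], local_protein: float
) -> dict[str, float]:
    """Scale a reference amino-acid profile to a local protein content.

    Reference amino-acid profiles are published per gram of protein; the
    amino-acid quantity in a portion whose protein content is known is
    the profile times that protein, converted mg -> g.

    Parameters
    ----------
    reference_iaa_per_g_protein
        mg of amino acid per g protein, keyed by amino-acid name.
    local_protein
        Grams of protein in the portion being evaluated.

    Returns
    -------
    dict
        Grams of each amino acid in the portion.
    """
    if local_protein < 0:
        raise CompositionError("local_protein must be >= 0")
    if any(v < 0 for v in reference_iaa_per_g_protein.values()):
        raise CompositionError("amino-acid reference values must be >= 0")
    return {
        aa: mg_per_g * local_protein / 1000.0
        for aa, mg_per_g in reference_iaa_per_g_protein.items()
    }


def apply_tid(raw: NutrientVector, tid: Mapping[str, float]) -> NutrientVector:
    """Adjust a nutrient vector for true ileal digestibility.

    Each component is multiplied by its TID fraction, giving the
    utilisable (absorbed) amount.  A TID value must be supplied for every
    nonzero component; silently passing a component through unadjusted
    would overstate protein quality.
    """
    missing = [
        name
        for name in NUTRIENTS
        if raw.get(name) > 0 and name not in tid
    ]
    if missing:
        raise CompositionError(
            f"missing TID for nonzero components: {', '.join(missing)}"
        )
    return NutrientVector(
        protein=raw.protein * tid.get("protein", 1.0),
        iaa={aa: amount * tid.get(aa, 1.0) for aa, amount in raw.iaa.items()},
    )


def nutrient_for_item(
    entry: FoodCompositionEntry, amount_g: float, adjust: bool = True
) -> NutrientVector:
    """Utilisable protein and IAA content of ``amount_g`` grams of a food.

    Protein comes from the food's protein density; amino acids from the
    per-g-protein profile scaled to that protein; everything is then
    TID-adjusted unless ``adjust`` is False (raw amounts are needed for
    the low-protein item filter, which operates on unadjusted protein).
    """
    if amount_g < 0:
        raise CompositionError("amount_g must be >= 0")
    protein = entry.protein_per_100g * amount_g / 100.0
    raw = NutrientVector(
        protein=protein, iaa=normalise_aa(entry.iaa_per_g_protein, protein)
    )
    return apply_tid(raw, entry.tid) if adjust else raw


# ---------------------------------------------------------------------------
# CSV interface

def _expected_columns() -> list[str]:
    cols = ["food_id", "food_group", "protein_per_100g"]
    cols += [f"aa_{aa}_mg_per_g_protein" for aa in IAAS]
    cols += ["tid_protein"] + [f"tid_{aa}" for aa in IAAS]
    return cols


def composition_frame(entries: list[FoodCompositionEntry]) -> pd.DataFrame:
    """Wide-format composition table, one row per food."""
    rows = []
    for e in entries:
        row: dict[str, object] = {
            "food_id": e.food_id,
            "food_group": e.food_group,
            "protein_per_100g": e.protein_per_100g,
        }
        for aa in IAAS:
            row[f"aa_{aa}_mg_per_g_protein"] = e.iaa_per_g_protein.get(aa, 0.0)
        row["tid_protein"] = e.tid.get("protein", 1.0)
        for aa in IAAS:
            row[f"tid_{aa}"] = e.tid.get(aa, 1.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=_expected_columns())


def write_composition(entries: list[FoodCompositionEntry], path: str | Path) -> None:
    composition_frame(entries).to_csv(path, index=False)


def read_composition(path: str | Path) -> list[FoodCompositionEntry]:
    """Read a composition CSV with strict header validation."""
    df = pd.read_csv(path, dtype={"food_id": str})
    expected = _expected_columns()
    if list(df.columns) != expected:
        raise CompositionError(
            f"composition CSV header mismatch: expected {expected}, "
            f"got {list(df.columns)}"
        )
    entries = []
    for _, row in df.iterrows():
        entries.append(
            FoodCompositionEntry(
                food_id=str(row["food_id"]),
                food_group=str(row["food_group"]),
                protein_per_100g=float(row["protein_per_100g"]),
                iaa_per_g_protein={
                    aa: float(row[f"aa_{aa}_mg_per_g_protein"]) for aa in IAAS
                },
                tid={"protein": float(row["tid_protein"])}
                | {aa: float(row[f"tid_{aa}"]) for aa in IAAS},
            )
        )
    return entries
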
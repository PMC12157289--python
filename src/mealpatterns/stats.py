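"""Per-cluster protein-adequacy statistics and nonparametric tests.

The adequacy thresholds are the lowest per-eating-occasion values the
muscle-protein-synthesis literature supports: 20 g of protein per EO
absolute, 0.24 g per kg body weight relative.  Daily totals are
compared with the Australia/NZ Estimated Average Requirement (EAR):
0.68 g/kg/day for males, 0.60 for females.  "Below threshold" is a
strict inequality throughout.

Group comparisons use the Kruskal–Wallis H test with tie correction and
post hoc Dunn tests with Bonferroni adjustment, both implemented from
the joint-rank formulas (scipy's versions serve as cross-checks in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .composition import IAAS
from .intake import IAA_COLS

__all__ = [
    "ThresholdConfig",
    "ClusterReport",
    "eo_threshold_flags",
    "cluster_summary",
    "foodgroup_contribution",
    "hourly_profile",
    "kruskal_wallis",
    "dunn_test",
]


@dataclass(frozen=True)
class ThresholdConfig:
    absolute_per_eo: float = 20.0  # g protein per EO
    relative_per_eo: float = 0.24  # g protein / kg body weight per EO
    ear_male: float = 0.68  # g/kg/day
    ear_female: float = 0.60  # g/kg/day

    def __post_init__(self) -> None:
        if min(self.absolute_per_eo, self.relative_per_eo,
               self.ear_male, self.ear_female) <= 0:
            raise ValueError("all thresholds must be positive")


def eo_threshold_flags(
    protein_g: float,
    body_weight_kg: float | None,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> dict[str, bool | None]:
    """Strict below-threshold flags for one eating occasion.

    ``below_relative`` is None when body weight is unavailable.
    """
    flags: dict[str, bool | None] = {
        "below_absolute": protein_g < cfg.absolute_per_eo
    }
    if body_weight_kg is None or (
        isinstance(body_weight_kg, float) and np.isnan(body_weight_kg)
    ):
        flags["below_relative"] = None
    elif body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    else:
        flags["below_relative"] = protein_g / body_weight_kg < cfg.relative_per_eo
    return flags


# ---------------------------------------------------------------------------
# Rank tests

@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    degenerate: bool = False


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal–Wallis H test with tie correction.

    H = 12/(N(N+1)) * sum n_g (rbar_g - (N+1)/2)^2, divided by
    1 - sum(t^3 - t)/(N^3 - N).  p from chi-square with g-1 df.
    When every value is identical the tie correction is zero and H is
    undefined; the result is flagged degenerate with NaN statistics.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    df = len(groups) - 1
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction == 0.0:
        return KWResult(H=float("nan"), df=df, p=float("nan"), degenerate=True)
    offsets = np.cumsum([0] + [g.size for g in groups])
    H = 0.0
    for idx, g in enumerate(groups):
        rbar = ranks[offsets[idx]:offsets[idx + 1]].mean()
        H += g.size * (rbar - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    H /= correction
    return KWResult(H=float(H), df=df, p=float(chi2.sf(H, df)))


def dunn_test(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's post hoc pairwise test on joint ranks.

    z_ij = (rbar_i - rbar_j) / sqrt[ (N(N+1)/12 - sum(t^3-t)/(12(N-1)))
    * (1/n_i + 1/n_j) ]; two-sided p from the standard normal;
    Bonferroni multiplies by the number of pairs, capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if labels is None:
        labels = [str(i + 1) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    offsets = np.cumsum([0] + [g.size for g in groups])
    rbars = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))]
    variance = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se2 = variance * (1.0 / groups[i].size + 1.0 / groups[j].size)
            if se2 <= 0:
                z, p = float("nan"), float("nan")
                degenerate = True
            else:
                z = (rbars[i] - rbars[j]) / np.sqrt(se2)
                p = float(2.0 * norm.sf(abs(z)))
                degenerate = False
            p_adj = p if adjust == "none" else min(1.0, p * n_pairs)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": float(z),
                    "p_raw": p,
                    "p_adj": float(p_adj),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster report

@dataclass
class ClusterReport:
    """Bundle of per-cluster summary tables.

    ``summary`` — one row per cluster (means, threshold percentages,
    EO frequency, daily intake vs EAR, body composition);
    ``cohort`` — scalar cohort-wide statistics; ``contribution`` —
    food-group percentages per cluster and nutrient; ``hourly`` — mean
    intake per (cluster, hour, nutrient); ``tests`` — KW and Dunn
    results per outcome variable.
    """

    summary: pd.DataFrame
    cohort: dict[str, float]
    contribution: pd.DataFrame | None = None
    hourly: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        self.summary.to_csv(out / "cluster_summary.csv", index=False)
        paths["cluster_summary"] = str(out / "cluster_summary.csv")
        if self.contribution is not None:
            self.contribution.to_csv(out / "foodgroup_contribution.csv", index=False)
            paths["foodgroup_contribution"] = str(out / "foodgroup_contribution.csv")
        if self.hourly is not None:
            self.hourly.to_csv(out / "hourly_profile.csv", index=False)
            paths["hourly_profile"] = str(out / "hourly_profile.csv")
        if self.tests is not None:
            self.tests.to_csv(out / "tests.csv", index=False)
            paths["tests"] = str(out / "tests.csv")
        import json

        report = {"cohort": self.cohort, "extras": self.extras}
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        paths["report"] = str(out / "report.json")
        return paths


def cluster_summary(
    labels_by_series: Mapping[str, int],
    eos: pd.DataFrame,
    participants: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
    run_tests: bool = True,
) -> ClusterReport:
    """Per-cluster adequacy statistics.

    Parameters
    ----------
    labels_by_series
        series_id ("participant.day") -> cluster label (1-based,
        semantically ordered).
    eos
        EO table from :func:`mealpatterns.intake.build_eos`.
    participants
        participant_id, sex, body_weight_kg, optional bmi and
        body_fat_pct.

    Per-EO means are EO-weighted (every EO counts once).  Threshold
    percentages are over all EOs pooled within a cluster; a secondary
    per-individual metric (share of individuals whose mean EO protein
    is below threshold) is reported at cohort level.
    """
    if not labels_by_series:
        raise ValueError("empty label set")
    eos = eos.copy()
    eos["series_id"] = (
        eos["participant_id"].astype(str) + "." + eos["day"].astype(str)
    )
    unlabelled = set(eos["series_id"]) - set(labels_by_series)
    if unlabelled:
        raise ValueError(f"series without labels: {sorted(unlabelled)[:5]} ...")
    eos["cluster"] = eos["series_id"].map(labels_by_series)

    part = participants.copy()
    part["participant_id"] = part["participant_id"].astype(str)
    part = part.set_index("participant_id")
    eos["body_weight_kg"] = eos["participant_id"].astype(str).map(
        part["body_weight_kg"]
    )
    eos["protein_g_per_kg"] = eos["protein_g"] / eos["body_weight_kg"]
    eos["total_iaa_g"] = eos[IAA_COLS].sum(axis=1)
    eos["below_absolute"] = eos["protein_g"] < cfg.absolute_per_eo
    eos["below_relative"] = eos["protein_g_per_kg"] < cfg.relative_per_eo

    # daily totals per individual.day
    daily = eos.groupby(["cluster", "participant_id", "series_id"], as_index=False).agg(
        protein_day_g=("protein_g", "sum"),
        n_eos=("protein_g", "size"),
        body_weight_kg=("body_weight_kg", "first"),
    )
    daily["protein_day_g_per_kg"] = daily["protein_day_g"] / daily["body_weight_kg"]
    daily["sex"] = daily["participant_id"].map(part["sex"])
    daily["ear"] = np.where(daily["sex"] == "M", cfg.ear_male, cfg.ear_female)
    daily["below_ear"] = daily["protein_day_g_per_kg"] < daily["ear"]

    rows = []
    for cluster, group in eos.groupby("cluster"):
        dcluster = daily[daily["cluster"] == cluster]
        ids = group["participant_id"].unique()
        body = part.loc[part.index.intersection(ids)]
        rows.append(
            {
                "cluster": cluster,
                "n_eos": len(group),
                "n_series": group["series_id"].nunique(),
                "n_individuals": len(ids),
                "mean_protein_g_per_eo": group["protein_g"].mean(),
                "sd_protein_g_per_eo": group["protein_g"].std(ddof=1),
                "mean_protein_g_per_kg_per_eo": group["protein_g_per_kg"].mean(),
                "pct_eos_below_absolute": 100.0 * group["below_absolute"].mean(),
                "pct_eos_below_relative": 100.0 * group["below_relative"].mean(),
                "mean_total_iaa_g_per_eo": group["total_iaa_g"].mean(),
                **{
                    f"mean_{aa}_g_per_eo": group[f"{aa}_g"].mean() for aa in IAAS
                },
                "mean_eos_per_day": dcluster["n_eos"].mean(),
                "mean_daily_protein_g_per_kg": dcluster["protein_day_g_per_kg"].mean(),
                "pct_days_below_ear": 100.0 * dcluster["below_ear"].mean(),
                "mean_bmi": body["bmi"].mean() if "bmi" in body else np.nan,
                "mean_body_fat_pct": (
                    body["body_fat_pct"].mean() if "body_fat_pct" in body else np.nan
                ),
            }
        )
    summary = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)

    # cohort-level secondary metric: individuals by their mean EO intake
    per_individual = eos.groupby("participant_id").agg(
        mean_eo_protein=("protein_g", "mean"),
        mean_eo_protein_per_kg=("protein_g_per_kg", "mean"),
    )
    cohort = {
        "n_eos": int(len(eos)),
        "n_series": int(eos["series_id"].nunique()),
        "mean_protein_g_per_eo": float(eos["protein_g"].mean()),
        "pct_eos_below_absolute": float(100.0 * eos["below_absolute"].mean()),
        "pct_eos_below_relative": float(100.0 * eos["below_relative"].mean()),
        "pct_individuals_mean_eo_below_absolute": float(
            100.0 * (per_individual["mean_eo_protein"] < cfg.absolute_per_eo).mean()
        ),
        "pct_individuals_mean_eo_below_relative": float(
            100.0
            * (per_individual["mean_eo_protein_per_kg"] < cfg.relative_per_eo).mean()
        ),
    }

    tests = None
    if run_tests and summary["cluster"].nunique() >= 2:
        tests = _cluster_tests(eos, daily, part)

    return ClusterReport(summary=summary, cohort=cohort, tests=tests)


def _cluster_tests(
    eos: pd.DataFrame, daily: pd.DataFrame, part: pd.DataFrame
) -> pd.DataFrame:
    """KW + Dunn across clusters for the report's outcome variables."""
    clusters = sorted(eos["cluster"].unique())
    cluster_of_individual = (
        eos.groupby("participant_id")["cluster"]
        .agg(lambda s: s.mode().iloc[0])
    )
    body = part.join(cluster_of_individual.rename("cluster"), how="inner")

    variables: dict[str, list[np.ndarray]] = {
        "protein_g_per_eo": [
            eos.loc[eos["cluster"] == c, "protein_g"].to_numpy() for c in clusters
        ],
        "total_iaa_g_per_eo": [
            eos.loc[eos["cluster"] == c, "total_iaa_g"].to_numpy() for c in clusters
        ],
        "eos_per_day": [
            daily.loc[daily["cluster"] == c, "n_eos"].to_numpy() for c in clusters
        ],
    }
    for col in ("bmi", "body_fat_pct"):
        if col in body:
            groups = [
                body.loc[body["cluster"] == c, col].dropna().to_numpy()
                for c in clusters
            ]
            if all(g.size > 0 for g in groups):
                variables[col] = groups

    rows = []
    for name, groups in variables.items():
        kw = kruskal_wallis(groups)
        rows.append(
            {
                "variable": name,
                "test": "kruskal_wallis",
                "group_a": "",
                "group_b": "",
                "statistic": kw.H,
                "p_raw": kw.p,
                "p_adj": kw.p,
                "significant": bool(kw.p < 0.05) if not kw.degenerate else False,
            }
        )
        if not kw.degenerate:
            dunn = dunn_test(groups, labels=[str(c) for c in clusters])
            for _, d in dunn.iterrows():
                rows.append(
                    {
                        "variable": name,
                        "test": "dunn",
                        "group_a": d["group_a"],
                        "group_b": d["group_b"],
                        "statistic": d["z"],
                        "p_raw": d["p_raw"],
                        "p_adj": d["p_adj"],
                        "significant": bool(d["p_adj"] < 0.05),
                    }
                )
    return pd.DataFrame(rows)


def foodgroup_contribution(
    items: pd.DataFrame,
    labels_by_series: Mapping[str, int],
    min_share: float = 0.05,
) -> pd.DataFrame:
    """Percentage contribution of food groups per cluster and nutrient.

    ``items`` is the retained item-level frame from ``build_eos`` (it
    carries food_group, protein_g and per-IAA columns).  Groups whose
    share of a cluster's *protein* falls below ``min_share`` are merged
    into "Others" for every nutrient, so the grouping is consistent
    across panels.  Percentages sum to 100 per (cluster, nutrient).
    """
    if "food_group" not in items or items["food_group"].isna().any():
        raise ValueError("item rows must carry food-group annotations")
    items = items.copy()
    items["series_id"] = (
        items["participant_id"].astype(str) + "." + items["day"].astype(str)
    )
    items["cluster"] = items["series_id"].map(labels_by_series)
    if items["cluster"].isna().any():
        raise ValueError("items reference series without cluster labels")

    nutrients = ["protein_g"] + IAA_COLS
    out_rows = []
    for cluster, group in items.groupby("cluster"):
        protein_by_group = group.groupby("food_group")["protein_g"].sum()
        share = protein_by_group / protein_by_group.sum()
        minor = set(share.index[share < min_share])
        display_group = group["food_group"].where(
            ~group["food_group"].isin(minor), "Others"
        )
        for nutrient in nutrients:
            totals = group.groupby(display_group)[nutrient].sum()
            total = totals.sum()
            if total == 0:
                continue
            for fg, value in totals.items():
                out_rows.append(
                    {
                        "cluster": cluster,
                        "nutrient": nutrient.removesuffix("_g"),
                        "food_group": fg,
                        "pct": 100.0 * value / total,
                    }
                )
    return pd.DataFrame(out_rows)


def hourly_profile(
    eos: pd.DataFrame, labels_by_series: Mapping[str, int]
) -> pd.DataFrame:
    """Mean per-EO intake in 24 hourly bins per cluster and nutrient.

    Bin h holds EOs with h <= time-in-hours < h+1 (00:00 -> bin 0,
    23:59 -> bin 23).  Bins with no EOs are absent from the long-format
    result (missing, not zero).
    """
    eos = eos.copy()
    eos["series_id"] = (
        eos["participant_id"].astype(str) + "." + eos["day"].astype(str)
    )
    eos["cluster"] = eos["series_id"].map(labels_by_series)
    if not eos["time_min"].between(0, 1439).all():
        raise ValueError("EO times must lie in [0, 1440) minutes")
    eos["hour"] = (eos["time_min"] // 60).astype(int)
    nutrients = ["protein_g"] + IAA_COLS
    long = eos.melt(
        id_vars=["cluster", "hour"],
        value_vars=nutrients,
        var_name="nutrient",
        value_name="intake_g",
    )
    profile = (
        long.groupby(["cluster", "nutrient", "hour"], as_index=False)["intake_g"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "mean_g_per_eo", "size": "n_eos"})
    )
    profile["nutrient"] = profile["nutrient"].str.removesuffix("_g")
    return profile
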
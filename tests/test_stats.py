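import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal, rankdata

import mealpatterns as mp
from mealpatterns.stats import KWResult


# ---------------------------------------------------------------------------
# threshold flags

def test_threshold_flags_examples():
    cfg = mp.ThresholdConfig()
    flags = mp.eo_threshold_flags(19.0, 70.0, cfg)
    assert flags["below_absolute"] is True  # 19 < 20
    assert flags["below_relative"] is False  # 0.271 >= 0.24
    assert mp.eo_threshold_flags(20.0, 70.0, cfg)["below_absolute"] is False
    # 16.8 / 70 = 0.24 exactly: strict < means not below
    assert mp.eo_threshold_flags(16.8, 70.0, cfg)["below_relative"] is False


def test_threshold_flags_missing_weight():
    assert mp.eo_threshold_flags(10.0, None)["below_relative"] is None
    with pytest.raises(ValueError):
        mp.eo_threshold_flags(10.0, -1.0)


def test_threshold_config_validation():
    with pytest.raises(ValueError):
        mp.ThresholdConfig(absolute_per_eo=0.0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def test_kw_hand_example():
    result = mp.kruskal_wallis([[1, 2], [3, 4]])
    assert result.H == pytest.approx(2.4)
    assert result.df == 1


def test_kw_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(3)]
        ours = mp.kruskal_wallis(groups)
        H_ref, p_ref = kruskal(*groups)
        assert ours.H == pytest.approx(H_ref, rel=1e-12)
        assert ours.p == pytest.approx(p_ref, rel=1e-12)


def test_kw_with_ties_matches_scipy():
    groups = [[1, 1, 2, 3], [2, 2, 3, 3], [1, 3, 3, 4]]
    ours = mp.kruskal_wallis(groups)
    H_ref, p_ref = kruskal(*groups)
    assert ours.H == pytest.approx(H_ref, rel=1e-12)
    assert ours.p == pytest.approx(p_ref, rel=1e-12)


def test_kw_rank_invariance_under_within_group_relabelling():
    a = mp.kruskal_wallis([[5, 1, 9], [2, 8]])
    b = mp.kruskal_wallis([[9, 5, 1], [8, 2]])
    assert a.H == pytest.approx(b.H)


def test_kw_all_identical_is_degenerate():
    result = mp.kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
    assert result.degenerate and np.isnan(result.H)


def test_kw_two_groups_equals_squared_ranksum_z():
    """On tie-free data, KW with 2 groups equals the squared
    normal-approximation rank-sum statistic."""
    rng = np.random.default_rng(1)
    x, y = rng.permutation(40)[:25].astype(float), rng.permutation(100)[60:75].astype(float)
    y = y + 0.5  # guarantee no cross-group ties
    H = mp.kruskal_wallis([x, y]).H
    n1, n2 = len(x), len(y)
    N = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    W = ranks[:n1].sum()
    z = (W - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12)
    assert H == pytest.approx(z**2, rel=1e-10)


def test_kw_input_validation():
    with pytest.raises(ValueError):
        mp.kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(ValueError):
        mp.kruskal_wallis([[1.0], []])


# ---------------------------------------------------------------------------
# Dunn's test

def test_dunn_identical_groups_z_zero():
    table = mp.dunn_test([[1.0, 2.0], [1.0, 2.0]])
    assert table.loc[0, "z"] == pytest.approx(0.0)
    assert table.loc[0, "p_raw"] == pytest.approx(1.0)


def test_dunn_pair_count_and_bonferroni_factor():
    table = mp.dunn_test([[1, 2], [3, 4], [5, 6]])
    assert len(table) == 3
    expected = np.minimum(1.0, table["p_raw"] * 3)
    assert np.allclose(table["p_adj"], expected)


def test_dunn_hand_computed_z():
    """Tie-free 3x3 groups: z from the joint-rank formula by hand.

    Joint ranks are 1..9; rank means 2, 5, 8; variance term
    N(N+1)/12 = 7.5; se = sqrt(7.5 * (1/3 + 1/3)) = sqrt(5).
    """
    groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
    table = mp.dunn_test(groups, labels=["a", "b", "c"])
    se = np.sqrt(7.5 * (2 / 3))
    expect = {("a", "b"): -3 / se, ("a", "c"): -6 / se, ("b", "c"): -3 / se}
    for _, row in table.iterrows():
        assert row["z"] == pytest.approx(expect[(row["group_a"], row["group_b"])])


def test_dunn_degenerate_all_tied():
    table = mp.dunn_test([[2.0, 2.0], [2.0, 2.0]])
    assert bool(table.loc[0, "degenerate"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(min_value=-50, max_value=50,
                           allow_nan=False), min_size=2, max_size=8),
        min_size=2, max_size=4,
    )
)
def test_bonferroni_never_below_raw_and_capped(groups):
    table = mp.dunn_test(groups)
    valid = table[~table["degenerate"]]
    assert (valid["p_adj"] >= valid["p_raw"] - 1e-15).all()
    assert (valid["p_adj"] <= 1.0).all()


# ---------------------------------------------------------------------------
# cluster summary

def make_single_cluster_inputs():
    eos = pd.DataFrame(
        {
            "participant_id": ["1"] * 3,
            "day": [1, 1, 1],
            "date": ["2023-01-01"] * 3,
            "time_min": [480, 780, 1140],
            "protein_g": [10.0, 10.0, 10.0],
            **{f"{aa}_g": [0.1, 0.1, 0.1] for aa in mp.IAAS},
            "item_count": [1, 1, 1],
        }
    )
    participants = pd.DataFrame(
        {
            "participant_id": ["1"],
            "sex": ["F"],
            "body_weight_kg": [70.0],
            "bmi": [24.0],
            "body_fat_pct": [30.0],
        }
    )
    return eos, participants


def test_cluster_summary_single_cluster_identical_eos():
    eos, participants = make_single_cluster_inputs()
    report = mp.cluster_summary({"1.1": 1}, eos, participants, run_tests=False)
    row = report.summary.iloc[0]
    assert row["mean_protein_g_per_eo"] == pytest.approx(10.0)
    assert row["pct_eos_below_absolute"] == pytest.approx(100.0)
    assert row["mean_eos_per_day"] == pytest.approx(3.0)
    assert row["mean_total_iaa_g_per_eo"] == pytest.approx(0.7)
    # daily: 30 g / 70 kg = 0.43 g/kg < female EAR 0.60
    assert row["pct_days_below_ear"] == pytest.approx(100.0)


def test_cluster_summary_empty_labels_is_error():
    eos, participants = make_single_cluster_inputs()
    with pytest.raises(ValueError):
        mp.cluster_summary({}, eos, participants)


def test_cluster_summary_eo_counts_partition(small_series):
    eos, _, series = small_series
    labels = {s.series_id: 1 + (i % 3) for i, s in enumerate(series)}
    participants = pd.DataFrame(
        {
            "participant_id": sorted(eos["participant_id"].unique()),
            "sex": "F",
            "body_weight_kg": 70.0,
            "bmi": 24.0,
            "body_fat_pct": 30.0,
        }
    )
    report = mp.cluster_summary(labels, eos, participants, run_tests=False)
    assert report.summary["n_eos"].sum() == len(eos)
    assert report.summary["n_series"].sum() == len(series)
    assert report.summary["pct_eos_below_absolute"].between(0, 100).all()


def test_pct_below_threshold_monotone_in_threshold(small_series):
    eos, _, series = small_series
    labels = {s.series_id: 1 for s in series}
    participants = pd.DataFrame(
        {
            "participant_id": sorted(eos["participant_id"].unique()),
            "sex": "M",
            "body_weight_kg": 80.0,
        }
    )
    loose = mp.cluster_summary(
        labels, eos, participants, cfg=mp.ThresholdConfig(absolute_per_eo=20.0),
        run_tests=False,
    ).summary.iloc[0]["pct_eos_below_absolute"]
    tight = mp.cluster_summary(
        labels, eos, participants, cfg=mp.ThresholdConfig(absolute_per_eo=10.0),
        run_tests=False,
    ).summary.iloc[0]["pct_eos_below_absolute"]
    assert tight <= loose


# ---------------------------------------------------------------------------
# food-group contributions and hourly profile

def items_frame(rows):
    cols = ["participant_id", "day", "food_group", "protein_g"]
    df = pd.DataFrame(rows, columns=cols)
    for aa in mp.IAAS:
        df[f"{aa}_g"] = df["protein_g"] * 0.01
    return df


def test_contribution_single_group_is_100():
    items = items_frame([("1", 1, "soy products", 10.0)])
    table = mp.foodgroup_contribution(items, {"1.1": 1})
    assert np.allclose(table["pct"], 100.0)


def test_contribution_60_40_split():
    items = items_frame(
        [("1", 1, "soy products", 6.0), ("1", 1, "legumes and pulses", 4.0)]
    )
    table = mp.foodgroup_contribution(items, {"1.1": 1})
    protein = table[table["nutrient"] == "protein"].set_index("food_group")["pct"]
    assert protein["soy products"] == pytest.approx(60.0)
    assert protein["legumes and pulses"] == pytest.approx(40.0)


def test_contribution_minor_group_folds_into_others():
    items = items_frame(
        [("1", 1, "soy products", 95.1), ("1", 1, "fruit", 4.9)]
    )
    table = mp.foodgroup_contribution(items, {"1.1": 1})
    groups = set(table["food_group"])
    assert "fruit" not in groups and "Others" in groups


def test_contribution_sums_to_100_per_nutrient(small_series):
    eos, items, series = small_series
    labels = {s.series_id: 1 + (i % 2) for i, s in enumerate(series)}
    table = mp.foodgroup_contribution(items, labels)
    sums = table.groupby(["cluster", "nutrient"])["pct"].sum()
    assert np.allclose(sums, 100.0, atol=1e-6)


def test_contribution_requires_annotations():
    items = items_frame([("1", 1, None, 5.0)])
    with pytest.raises(ValueError):
        mp.foodgroup_contribution(items, {"1.1": 1})


def test_hourly_profile_binning_and_means():
    eos = pd.DataFrame(
        {
            "participant_id": ["1"] * 4,
            "day": [1] * 4,
            "time_min": [0, 1439, 18 * 60 + 30, 12 * 60 + 15],
            "protein_g": [5.0, 7.0, 9.0, 8.0],
            **{f"{aa}_g": [0.0] * 4 for aa in mp.IAAS},
        }
    )
    eos = pd.concat(
        [eos, eos.iloc[[3]].assign(time_min=12 * 60 + 40, protein_g=12.0)],
        ignore_index=True,
    )
    profile = mp.hourly_profile(eos, {"1.1": 1})
    protein = profile[profile["nutrient"] == "protein"].set_index("hour")
    assert protein.loc[0, "mean_g_per_eo"] == pytest.approx(5.0)
    assert protein.loc[23, "mean_g_per_eo"] == pytest.approx(7.0)
    assert protein.loc[18, "mean_g_per_eo"] == pytest.approx(9.0)
    assert protein.loc[12, "mean_g_per_eo"] == pytest.approx(10.0)  # (8+12)/2
    assert set(protein.index) == {0, 12, 18, 23}  # empty bins absent
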
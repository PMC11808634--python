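"""Additive expectations, parity-line analysis, transgression labels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybridmorph import (
    DomainError,
    classify_transgression,
    default_config,
    expected_value,
    parity_analysis,
    simulate_colony,
)
from hybridmorph.synthetic_colony import SimConfig
from dataclasses import replace


def test_expectation_endpoints_equal_parental_means():
    assert expected_value(0.0, 583.00, 575.13) == pytest.approx(583.00)
    assert expected_value(1.0, 583.00, 575.13) == pytest.approx(575.13)


def test_half_ancestry_gives_mid_parent_value():
    # oracle: unweighted mean of the two parental means
    assert expected_value(0.5, 16.02, 12.78) == pytest.approx((16.02 + 12.78) / 2)
    assert expected_value(0.5, 16.02, 12.78) == pytest.approx(14.40)


def test_ancestry_outside_unit_interval_is_rejected():
    with pytest.raises(DomainError):
        expected_value(1.2, 10.0, 20.0)
    with pytest.raises(DomainError):
        expected_value(-0.1, 10.0, 20.0)


@given(
    st.floats(0, 1), st.floats(0, 1),
    st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
)
def test_expectation_is_monotone_and_bounded_by_parental_means(a1, a2, mi, mc):
    e1, e2 = expected_value(a1, mi, mc), expected_value(a2, mi, mc)
    lo, hi = sorted((mi, mc))
    assert lo - 1e-9 <= e1 <= hi + 1e-9
    if a1 < a2:  # moving toward Chinese ancestry moves toward the Chinese mean
        assert (e2 - e1) * (mc - mi) >= -1e-9


@pytest.mark.parametrize(
    "value,means,rng,vs_means,vs_range",
    [
        (600.0, (583.00, 575.13), None, "above_both", None),
        (583.00, (583.00, 575.13), None, "between", None),  # boundary is inward
        (570.0, (583.00, 575.13), (560.0, 600.0), "below_both", "within"),
        (550.0, (583.00, 575.13), (560.0, 600.0), "below_both", "below_parental_min"),
        (601.0, (583.00, 575.13), (560.0, 600.0), "above_both", "above_parental_max"),
        (560.0, (583.00, 575.13), (560.0, 600.0), "below_both", "within"),
    ],
)
def test_transgression_labels_use_closed_intervals(value, means, rng, vs_means, vs_range):
    assert classify_transgression(value, means, rng) == (vs_means, vs_range)


def test_parity_counts_mean_deviation_and_sign_test(records_factory):
    # parental means (10, 10): expectation is 10 for any ancestry;
    # hybrid weights 11, 8, 7 give deviations +1, -2, -3
    df = records_factory([
        {"ancestry": 0.0, "weight": 10},
        {"ancestry": 1.0, "weight": 10},
        {"ancestry": 0.5, "weight": 11},
        {"ancestry": 0.5, "weight": 8},
        {"ancestry": 0.5, "weight": 7},
    ])
    _, parity = parity_analysis(df, measurements=["weight"])
    row = parity.iloc[0]
    assert (row["n_above"], row["n_below"], row["n_on"]) == (1, 2, 0)
    assert row["mean_deviation"] == pytest.approx(-4 / 3)
    # two-sided exact binomial, k=1 of n=3 at p=0.5 -> 1.0
    assert row["sign_test_p"] == pytest.approx(1.0)


def test_hybrids_exactly_on_parity_line(records_factory):
    df = records_factory([
        {"ancestry": 0.0, "weight": 16.0},
        {"ancestry": 1.0, "weight": 12.0},
        {"ancestry": 0.25, "weight": 15.0},
        {"ancestry": 0.5, "weight": 14.0},
    ])
    _, parity = parity_analysis(df, measurements=["weight"])
    row = parity.iloc[0]
    assert (row["n_above"], row["n_below"], row["n_on"]) == (0, 0, 2)
    assert row["mean_deviation"] == pytest.approx(0.0)
    assert row["sign_test_p"] == 1.0


def test_deviation_agrees_with_scalar_formula_recomputation(default_colony):
    colony, _ = default_colony
    expectations, _ = parity_analysis(colony)
    means = {}
    full = colony[colony["group"].isin(["indian", "chinese"])]
    for m in expectations["measurement"].unique():
        means[m] = (
            full.loc[full["group"] == "indian", m].mean(),
            full.loc[full["group"] == "chinese", m].mean(),
        )
    for row in expectations.sample(n=50, random_state=0).itertuples():
        mi, mc = means[row.measurement]
        exp = (1 - row.ancestry) * mi + row.ancestry * mc
        assert row.deviation == pytest.approx(row.actual - exp, abs=1e-12)
        assert {"above": 1, "below": -1, "on": 0}[row.parity_side] == np.sign(row.deviation)


def _half_ancestry_config(lam_per_meas: float, seed: int, n: int = 200) -> SimConfig:
    """All-female colony at A = 1/2 with dominance L*d = lam x env_sd."""
    cfg = default_config(seed=seed, realized_ancestry=True)
    return replace(
        cfg,
        bin_counts={0.0: (25, 0), 0.5: (n, 0), 1.0: (25, 0)},
        dominance={m: lam_per_meas * cfg.env_sd[m] / cfg.loci for m in cfg.env_sd},
    )


@pytest.mark.parametrize("lam,sign", [(4.0, 1), (-4.0, -1)])
def test_dominance_sign_is_recovered_in_mean_deviation(lam, sign):
    colony, truth = simulate_colony(_half_ancestry_config(lam, seed=77))
    means = {
        m: (truth.parental_mean_indian[m], truth.parental_mean_chinese[m])
        for m in truth.parental_mean_indian
    }
    _, parity = parity_analysis(colony, parental_means=means)
    dev = parity.set_index("measurement")["mean_deviation"]
    assert all(np.sign(dev) == sign)


def test_mean_deviation_grows_with_dominance_magnitude():
    devs = []
    for lam in (2.0, 6.0):
        colony, truth = simulate_colony(_half_ancestry_config(lam, seed=78))
        means = {
            m: (truth.parental_mean_indian[m], truth.parental_mean_chinese[m])
            for m in truth.parental_mean_indian
        }
        _, parity = parity_analysis(colony, parental_means=means)
        devs.append(parity.set_index("measurement")["mean_deviation"])
    assert (devs[1] > devs[0]).all()


def test_additive_null_parity_fraction_near_half():
    """1000 additive hybrids: the above-parity fraction sits inside the
    central 99% binomial interval around 1/2 (truth-referenced)."""
    cfg = default_config(seed=99)
    cfg = replace(cfg, bin_counts={0.5: (1000, 0)})
    colony, truth = simulate_colony(cfg)
    means = {
        m: (truth.parental_mean_indian[m], truth.parental_mean_chinese[m])
        for m in truth.parental_mean_indian
    }
    _, parity = parity_analysis(colony, parental_means=means)
    n = 1000
    half_width = 2.5758 * 0.5 / np.sqrt(n)
    frac = parity["n_above"] / (parity["n_above"] + parity["n_below"])
    # pooled across the six measurements for a single stable check
    assert abs(frac.mean() - 0.5) < half_width


def test_measurement_without_parental_mean_is_skipped_with_warning(records_factory):
    df = records_factory([
        {"ancestry": 0.0, "weight": 16, "tibia": None},
        {"ancestry": 1.0, "weight": 12, "tibia": None},
        {"ancestry": 0.5, "weight": 14, "tibia": 180.0},
    ])
    with pytest.warns(UserWarning, match="tibia"):
        _, parity = parity_analysis(df, measurements=["weight", "tibia"])
    assert parity["measurement"].tolist() == ["weight"]
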
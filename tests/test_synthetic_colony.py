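"""The L-locus additive simulator: genotypes, traits, colonies, power."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridmorph import (
    SimConfig,
    default_config,
    power_analysis,
    sim_truth,
    simulate_colony,
    simulate_genotypes,
    simulate_trait,
)
from hybridmorph.errors import DomainError
from hybridmorph.phenodata import RAW_MEASUREMENTS


@pytest.fixture(scope="module")
def cfg():
    return default_config(seed=0)


def test_fullbred_genotypes_are_single_lineage(cfg):
    rng = np.random.default_rng(0)
    g0 = simulate_genotypes(0.0, cfg, rng)
    g1 = simulate_genotypes(1.0, cfg, rng)
    assert g0.shape == (cfg.loci, 2)
    assert g0.sum() == 0
    assert g1.sum() == 2 * cfg.loci


def test_deterministic_split_is_exact_and_even(cfg):
    rng = np.random.default_rng(0)
    g = simulate_genotypes(0.5, cfg, rng)  # L=100 -> exactly 100 Chinese alleles
    assert g.sum() == 100
    # spread evenly: no homozygous-Chinese locus before every locus has one
    assert set(g.sum(axis=1)) <= {0, 1}
    g2 = simulate_genotypes(0.5, cfg, rng)
    assert np.array_equal(g, g2)  # no randomness in deterministic mode


def test_realized_ancestry_allele_count_near_expectation():
    """A = 0.8 with 10,000 loci: about 16,000 of the 20,000 alleles are
    Chinese-derived (binomial, within 3 sigma)."""
    cfg = replace(default_config(seed=0, realized_ancestry=True), loci=10_000)
    rng = np.random.default_rng(123)
    g = simulate_genotypes(0.8, cfg, rng)
    count = g.sum()
    sigma = np.sqrt(2 * 10_000 * 0.8 * 0.2)
    assert abs(count - 16_000) <= 3 * sigma


def test_ancestry_outside_unit_interval_rejected(cfg):
    with pytest.raises(DomainError):
        simulate_genotypes(1.5, cfg, np.random.default_rng(0))


def test_noiseless_fullbred_trait_is_exactly_the_parental_mean(cfg):
    noiseless = replace(
        cfg,
        allele_effect_sd={m: 0.0 for m in RAW_MEASUREMENTS},
        env_sd={m: 0.0 for m in RAW_MEASUREMENTS},
    )
    truth = sim_truth(noiseless)
    rng = np.random.default_rng(1)
    g = simulate_genotypes(0.0, noiseless, rng)
    female = simulate_trait(g, noiseless, "F", "weight", rng)
    male = simulate_trait(g, noiseless, "M", "weight", rng)
    assert female == pytest.approx(truth.parental_mean_indian["weight"], abs=1e-9)
    assert male == pytest.approx(
        truth.parental_mean_indian["weight"] + noiseless.dimorphism_indian["weight"],
        abs=1e-9,
    )


def test_half_ancestry_trait_mean_matches_mid_parent(cfg):
    """Monte-Carlo mean of the explicit per-allele path against the
    closed-form mid-parent expectation, within 3 standard errors."""
    truth = sim_truth(cfg)
    rng = np.random.default_rng(2)
    g = simulate_genotypes(0.5, cfg, rng)
    draws = np.array(
        [simulate_trait(g, cfg, "F", "crown_rump", rng) for _ in range(10_000)]
    )
    mid = 0.5 * (
        truth.parental_mean_indian["crown_rump"] + truth.parental_mean_chinese["crown_rump"]
    )
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - mid) < 3 * se


def test_heterotic_shift_matches_closed_form():
    """d > 0 with realized ancestry at A = 1/2: mean excess over the
    mid-parent equals 2 * 0.25 * L * d within 3 SE."""
    base = default_config(seed=0, realized_ancestry=True)
    d = {m: 3.0 * base.env_sd[m] / base.loci for m in RAW_MEASUREMENTS}
    cfg = replace(base, dominance=d, bin_counts={0.5: (4000, 0)})
    colony, truth = simulate_colony(cfg)
    m = "femur"
    mid = 0.5 * (truth.parental_mean_indian[m] + truth.parental_mean_chinese[m])
    excess = colony[m].to_numpy() - mid
    expected_shift = 2 * 0.25 * cfg.loci * d[m]
    assert truth.heterotic_shift(0.5, m) == pytest.approx(expected_shift)
    se = excess.std(ddof=1) / np.sqrt(excess.size)
    assert abs(excess.mean() - expected_shift) < 3 * se


def test_default_colony_composition(cfg):
    colony, _ = simulate_colony(cfg)
    assert len(colony) == 134
    assert (colony["sex"] == "F").sum() == 92
    assert (colony["sex"] == "M").sum() == 42
    counts = colony["group"].value_counts()
    assert counts["indian"] == 19
    assert counts["chinese"] == 13
    assert counts["hybrid"] == 102
    assert colony[list(RAW_MEASUREMENTS)].gt(0).all().all()
    assert colony["id"].is_unique


def test_same_seed_is_bit_identical_different_seed_differs(cfg):
    a, _ = simulate_colony(cfg)
    b, _ = simulate_colony(default_config(seed=0))
    pd.testing.assert_frame_equal(a, b)
    c, _ = simulate_colony(default_config(seed=1))
    assert not np.allclose(a["weight"], c["weight"])


def test_single_bin_colony_is_all_one_group(cfg):
    only_indian = replace(cfg, bin_counts={0.0: (5, 5)})
    colony, _ = simulate_colony(only_indian)
    assert (colony["group"] == "indian").all()
    assert len(colony) == 10


def test_config_dict_round_trip(cfg):
    again = SimConfig.from_dict(cfg.to_dict())
    assert again == cfg


def test_group_means_track_truth(default_colony):
    colony, truth = default_colony
    for m in ("weight", "femur"):
        for grp, mu in (
            ("indian", truth.parental_mean_indian[m]),
            ("chinese", truth.parental_mean_chinese[m]),
        ):
            sub = colony[colony["group"] == grp]
            fem = sub.loc[sub["sex"] == "F", m]
            se = fem.std(ddof=1) / np.sqrt(len(fem))
            assert abs(fem.mean() - mu) < 4 * se


def test_regression_on_ancestry_recovers_additive_slope():
    """OLS of trait on ancestry over 500 additive females recovers the
    lineage mean difference mu_C - mu_I within two standard errors."""
    cfg = default_config(seed=1234)
    bins = {a: (60, 0) for a in (0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75)}
    bins[0.875] = (50, 0)
    bins[1.0] = (30, 0)
    cfg = replace(cfg, bin_counts=bins)
    colony, truth = simulate_colony(cfg)
    assert len(colony) == 500
    m = "weight"
    fit = stats.linregress(colony["ancestry"], colony[m])
    true_slope = truth.parental_mean_chinese[m] - truth.parental_mean_indian[m]
    assert abs(fit.slope - true_slope) < 2 * fit.stderr


def test_power_is_monotone_and_calibrated_on_a_small_grid():
    cfg = default_config(seed=0)
    tab = power_analysis(cfg, [0.0, 1.0, 3.0], alpha=0.05, reps=60, seed=9)
    mean_rate = (
        tab[~tab["measurement"].isin(["any", "all"])]
        .groupby("effect_L_d_env_sd")["rejection_rate"]
        .mean()
    )
    # monotone non-decreasing within Monte-Carlo tolerance (2 SE ~ 0.13)
    assert mean_rate[1.0] >= mean_rate[0.0] - 0.13
    assert mean_rate[3.0] >= mean_rate[1.0] - 0.13
    assert mean_rate[3.0] > 0.9
    # null per-test rate stays near alpha/6
    assert mean_rate[0.0] < 0.1


def test_invalid_configs_are_rejected(cfg):
    with pytest.raises(ValueError):
        replace(cfg, loci=0)
    with pytest.raises(DomainError):
        replace(cfg, bin_counts={1.5: (1, 1)})
    with pytest.raises(ValueError):
        replace(cfg, env_sd={m: -1.0 for m in RAW_MEASUREMENTS})
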
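"""Synthetic population generator and coupon recruitment process."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import rdskit as rk
from rdskit.simulate import SimulationConfig, TraitSpec


def small_config(**kw):
    base = dict(
        population_size=10_000,
        target_n=1_000,
        max_waves=60,
        rng_seed=3,
        trait_specs={"t": TraitSpec(("a", "b"), (0.3, 0.7), None, 0.0)},
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_population_prevalence_within_binomial_error():
    cfg = SimulationConfig(
        population_size=10_000, target_n=1_000, rng_seed=7,
        trait_specs={"hiv": TraitSpec(("neg", "pos"), (0.848, 0.152), None, 0.0)},
    )
    truth = rk.generate_population(cfg)
    p = truth.proportions["hiv"]["pos"]
    se = np.sqrt(0.152 * 0.848 / 10_000)
    assert abs(p - 0.152) < 3 * se


def test_population_degenerate_prevalence():
    cfg = small_config(trait_specs={"t": TraitSpec(("a", "b"), (1.0, 0.0), None, 0.0)})
    truth = rk.generate_population(cfg)
    assert (truth.population["t"] == "a").all()


def test_population_mean_degrees_match_config():
    cfg = SimulationConfig(rng_seed=5)  # HIV-like: means 38 / 52
    truth = rk.generate_population(cfg)
    pop = truth.population
    for cat, mu in [("negative", 38.0), ("positive", 52.0)]:
        d = pop.loc[pop["hiv"] == cat, "degree"]
        assert abs(d.mean() - mu) < 3 * d.std() / np.sqrt(len(d))
    assert (pop["degree"] >= 1).all()


def test_generation_is_deterministic():
    cfg = small_config()
    t1, t2 = rk.generate_population(cfg), rk.generate_population(cfg)
    pd.testing.assert_frame_equal(t1.population, t2.population)
    s1 = rk.simulate_recruitment(t1, cfg)
    s2 = rk.simulate_recruitment(t2, cfg)
    assert s1 == s2


def test_infeasible_mean_degree_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        SimulationConfig(
            trait_specs={"t": TraitSpec(("a", "b"), (0.5, 0.5), (0.2, 30.0), 0.0)}
        ).validate()


def test_zero_return_prob_gives_seeds_only():
    cfg = small_config(coupon_return_prob=0.0, n_seeds=5)
    truth = rk.generate_population(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample = rk.simulate_recruitment(truth, cfg)
    assert len(sample) == sample.n_seeds == 5
    assert sample.max_wave == 0


def test_without_replacement_and_wave_increments(study_sim):
    _, _, sample = study_sim
    assert sample.df["participant_id"].is_unique
    df = sample.df
    lut = df.set_index("participant_id")["wave"]
    recruits = df[df["recruiter_id"].notna()]
    parent_wave = lut.loc[recruits["recruiter_id"]].to_numpy()
    assert (recruits["wave"].to_numpy() == parent_wave + 1).all()


def test_study_config_return_rate_and_depth(study_sim):
    cfg, _, sample = study_sim
    rate = sample.n_recruits / sample.coupons_distributed
    se = np.sqrt(0.36 * 0.64 / sample.coupons_distributed)
    assert abs(rate - 0.36) < 3 * se
    assert sample.max_wave > 10
    assert len(sample) == cfg.target_n


def test_neutral_recruitment_matches_prevalence():
    # homophily 0, equal degrees: within-group recruitment proportion tracks
    # the (degree-weighted ~ plain) category prevalence
    cfg = small_config(
        population_size=30_000, target_n=2_500, max_waves=200, rng_seed=11
    )
    truth = rk.generate_population(cfg)
    sample = rk.simulate_recruitment(truth, cfg)
    view = rk.exclude_seeds(sample)
    tm = rk.transition_matrix(view, "t", smoothing=False)
    n_pairs = tm.counts[0].sum()
    p = truth.proportions["t"]["a"]
    se = np.sqrt(p * (1 - p) / n_pairs)
    assert abs(tm.matrix[0, 0] - p) < 3 * se


def test_homophilous_recruitment_exceeds_prevalence():
    cfg = small_config(
        population_size=30_000, target_n=2_500, max_waves=200, rng_seed=13,
        trait_specs={"t": TraitSpec(("a", "b"), (0.3, 0.7), None, 0.4)},
    )
    truth = rk.generate_population(cfg)
    sample = rk.simulate_recruitment(truth, cfg)
    tm = rk.transition_matrix(rk.exclude_seeds(sample), "t", smoothing=False)
    assert tm.matrix[0, 0] > truth.proportions["t"]["a"] + 0.2


def test_extinction_warns_but_returns_valid_sample():
    cfg = small_config(coupon_return_prob=0.02, n_seeds=4)
    truth = rk.generate_population(cfg)
    with pytest.warns(UserWarning, match="extinct"):
        sample = rk.simulate_recruitment(truth, cfg)
    assert sample.n_seeds == 4
    assert len(sample) < cfg.target_n


def test_degree_reporting_error_perturbs_only_reports():
    cfg = small_config(degree_reporting_error=0.5, rng_seed=21)
    truth = rk.generate_population(cfg)
    sample = rk.simulate_recruitment(truth, cfg)
    lut = truth.population.set_index("unit_id")["degree"]
    true_deg = lut.loc[sample.df["participant_id"]].to_numpy()
    reported = sample.df["degree"].to_numpy()
    assert (reported >= 1).all()
    assert (reported != true_deg).mean() > 0.5  # most reports perturbed


def test_seed_trait_bias_and_batches():
    cfg = small_config(
        n_seeds=6,
        seed_trait_bias={"t": "a"},
        seed_batches=(3, 3),
        rng_seed=17,
    )
    truth = rk.generate_population(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample = rk.simulate_recruitment(truth, cfg)
    seeds = sample.df[sample.is_seed]
    assert (seeds["t"] == "a").all()


def test_explicit_network_mode_runs():
    cfg = small_config(
        population_size=4_000, target_n=400, mean_degree=15.0,
        explicit_network=True, rng_seed=19,
        trait_specs={"t": TraitSpec(("a", "b"), (0.3, 0.7), None, 0.3)},
    )
    truth = rk.generate_population(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample = rk.simulate_recruitment(truth, cfg)
    assert sample.n_recruits > 50
    assert sample.df["participant_id"].is_unique


def test_recruitment_summary_conservation(study_sim):
    _, _, sample = study_sim
    table = rk.recruitment_summary(sample)
    per_seed = table[table["seed_id"] != "total"]
    total = table[table["seed_id"] == "total"].iloc[0]
    assert per_seed["n_recruited"].sum() == sample.n_recruits == total["n_recruited"]
    assert total["coupons_distributed"] == sample.coupons_distributed
    assert total["coupon_return_rate"] == pytest.approx(
        sample.n_recruits / sample.coupons_distributed
    )


def test_summary_single_seed_no_recruits(ab_schema):
    from conftest import build_sample

    sample = build_sample([("s", None, 5, {"grp": "A"})], ab_schema)
    table = rk.recruitment_summary(sample)
    row = table[table["seed_id"] == "s"].iloc[0]
    assert row["waves"] == 0
    assert row["coupon_return_rate"] == 0.0


def test_printed_process_counts_reproduce_rate():
    assert round(rk.coupon_return_rate(1_429, 3_997), 2) == 0.36


def test_config_yaml_roundtrip(tmp_path):
    cfg = rk.study_config(rng_seed=9, seed_batches=(7, 7))
    path = tmp_path / "cfg.yaml"
    rk.config_to_yaml(cfg, path)
    back = rk.config_from_yaml(path)
    assert back == cfg
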
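"""Estimator formulas: hand-checked values, identities, and oracles."""

import numpy as np
import pytest

import rdskit as rk
from conftest import build_sample
from rdskit._ss import depletion_inclusion_probs
from rdskit.experiments import mc_inclusion_frequencies


# ---------------------------------------------------------------------------
# degree preparation
# ---------------------------------------------------------------------------

def degrees_sample(degrees, ab_schema):
    rows = [("s", None, 10, {"grp": "A"})]
    rows += [
        (f"r{i}", "s", d, {"grp": "A"}) for i, d in enumerate(degrees)
    ]
    return build_sample(rows, ab_schema)


def test_prepare_degrees_passthrough(ab_schema):
    view = rk.exclude_seeds(degrees_sample([10, 20, 5], ab_schema))
    dv = rk.prepare_degrees(view)
    assert list(dv.values) == [10, 20, 5]
    assert dv.n_imputed == 0


def test_prepare_degrees_median_imputation(ab_schema):
    view = rk.exclude_seeds(degrees_sample([10, None, 30], ab_schema))
    dv = rk.prepare_degrees(view)
    assert list(dv.values) == [10, 20, 30]  # median of {10, 30}
    assert dv.n_imputed == 1
    assert list(dv.imputed) == [False, True, False]


def test_prepare_degrees_drop_policy(ab_schema):
    view = rk.exclude_seeds(degrees_sample([10, 0, 30], ab_schema))
    dv = rk.prepare_degrees(view, policy="drop")
    assert len(dv.values) == 2


def test_prepare_degrees_all_missing_errors(ab_schema):
    view = rk.exclude_seeds(degrees_sample([None, None], ab_schema))
    with pytest.raises(rk.EstimationError, match="sample proportion"):
        rk.prepare_degrees(view)


# ---------------------------------------------------------------------------
# sample proportion
# ---------------------------------------------------------------------------

def star_sample(counts, trait, schema, missing=0):
    """One seed recruiting every participant directly (wave-1 star)."""
    rows = [("s", None, 10, {trait: None})]
    i = 0
    for cat, k in counts.items():
        for _ in range(k):
            rows.append((f"r{i}", "s", 10, {trait: cat}))
            i += 1
    for _ in range(missing):
        rows.append((f"r{i}", "s", 10, {trait: None}))
        i += 1
    return build_sample(rows, schema)


def test_sample_proportion_printed_birthplace_counts():
    schema = {"born_in_russia": ("no", "yes")}
    sample = star_sample({"yes": 1164, "no": 212}, "born_in_russia", schema)
    res = rk.sample_proportion(rk.exclude_seeds(sample), "born_in_russia")
    assert res.n_used == 1376
    assert round(100 * res.proportions["yes"], 1) == 84.6
    assert round(100 * res.proportions["no"], 1) == 15.4


def test_sample_proportion_missing_values_shrink_denominator():
    schema = {"married": ("never", "past_current")}
    sample = star_sample({"never": 1128, "past_current": 240}, "married", schema, missing=8)
    res = rk.sample_proportion(rk.exclude_seeds(sample), "married")
    assert res.n_used == 1368
    assert round(100 * res.proportions["past_current"], 1) == 17.5


def test_sample_proportion_single_category(ab_schema):
    sample = star_sample({"A": 5}, "grp", ab_schema)
    res = rk.sample_proportion(rk.exclude_seeds(sample), "grp")
    assert res.proportions == {"A": 1.0, "B": 0.0}
    lo, hi = res.ci["A"]
    assert 0 <= lo <= hi <= 1


def test_sample_proportion_unknown_trait(mixing_sample):
    with pytest.raises(rk.SchemaError):
        rk.sample_proportion(rk.exclude_seeds(mixing_sample), "nope")


# ---------------------------------------------------------------------------
# RDS-II
# ---------------------------------------------------------------------------

def test_rds_ii_hand_example(ab_schema):
    rows = [
        ("s", None, 10, {"grp": "A"}),
        ("r1", "s", 10, {"grp": "A"}),
        ("r2", "s", 20, {"grp": "A"}),
        ("r3", "s", 5, {"grp": "B"}),
    ]
    view = rk.exclude_seeds(build_sample(rows, ab_schema))
    res = rk.rds_ii(view, "grp", rk.prepare_degrees(view))
    assert res.proportions["A"] == pytest.approx(3 / 7)
    assert res.proportions["B"] == pytest.approx(4 / 7)


def test_rds_ii_equals_sp_under_equal_degrees(equal_degree_mixing_sample):
    view = rk.exclude_seeds(equal_degree_mixing_sample)
    sp = rk.sample_proportion(view, "grp")
    r2 = rk.rds_ii(view, "grp", rk.prepare_degrees(view))
    assert all(
        r2.proportions[c] == pytest.approx(sp.proportions[c], abs=1e-12)
        for c in sp.proportions
    )


def test_rds_ii_downweights_high_degree_group(study_sim):
    _, _, sample = study_sim
    view = rk.exclude_seeds(sample)
    sp = rk.sample_proportion(view, "hiv")
    r2 = rk.rds_ii(view, "hiv", rk.prepare_degrees(view))
    # HIV-positive units have the larger mean network size (52 vs 38)
    assert r2.proportions["positive"] < sp.proportions["positive"]


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------

def test_transition_matrix_hand_counts(mixing_sample):
    tm = rk.transition_matrix(rk.exclude_seeds(mixing_sample), "grp", smoothing=False)
    np.testing.assert_allclose(tm.counts, [[2, 2], [1, 1]])
    np.testing.assert_allclose(tm.matrix, [[0.5, 0.5], [0.5, 0.5]])
    np.testing.assert_allclose(tm.equilibrium, [0.5, 0.5])
    err = np.max(np.abs(tm.equilibrium @ tm.matrix - tm.equilibrium))
    assert err < 1e-10


def test_transition_matrix_smoothing_symmetrizes_cross_counts(ab_schema):
    rows = [
        ("s", None, 10, {"grp": "A"}),
        ("b1", "s", 10, {"grp": "B"}),   # A->B
        ("b2", "s", 10, {"grp": "B"}),   # A->B
        ("b3", "s", 10, {"grp": "B"}),   # A->B
        ("a1", "b1", 10, {"grp": "A"}),  # B->A
        ("b4", "b1", 10, {"grp": "B"}),  # B->B
    ]
    view = rk.exclude_seeds(build_sample(rows, ab_schema))
    tm = rk.transition_matrix(view, "grp", smoothing=True)
    # off-diagonals averaged: t'_AB = t'_BA = (3 + 1) / 2 = 2
    np.testing.assert_allclose(tm.matrix[0], [0.0, 1.0])
    np.testing.assert_allclose(tm.matrix[1], [2 / 3, 1 / 3])


def test_transition_matrix_within_group_only_falls_back(ab_schema):
    rows = [
        ("sa", None, 10, {"grp": "A"}),
        ("sb", None, 10, {"grp": "B"}),
        ("a1", "sa", 10, {"grp": "A"}),
        ("b1", "sb", 10, {"grp": "B"}),
    ]
    view = rk.exclude_seeds(build_sample(rows, ab_schema))
    with pytest.warns(UserWarning, match="reducible"):
        tm = rk.transition_matrix(view, "grp", smoothing=False)
    assert tm.reducible
    assert tm.equilibrium_source == "fallback"
    np.testing.assert_allclose(tm.matrix, np.eye(2))


def test_transition_matrix_zero_recruiter_row_uniform(ab_schema):
    rows = [
        ("s", None, 10, {"grp": "A"}),
        ("a1", "s", 10, {"grp": "A"}),
        ("b1", "a1", 10, {"grp": "B"}),  # B recruits nobody
    ]
    view = rk.exclude_seeds(build_sample(rows, ab_schema))
    with pytest.warns(UserWarning, match="recruited nobody"):
        tm = rk.transition_matrix(view, "grp", smoothing=False)
    np.testing.assert_allclose(tm.matrix[1], [0.5, 0.5])


# ---------------------------------------------------------------------------
# RDS-I
# ---------------------------------------------------------------------------

def test_rds_i_symmetric_case_gives_half(equal_degree_mixing_sample):
    view = rk.exclude_seeds(equal_degree_mixing_sample)
    tm = rk.transition_matrix(view, "grp", smoothing=False)
    res = rk.rds_i(view, "grp", rk.prepare_degrees(view), tm)
    assert res.proportions["A"] == pytest.approx(0.5, abs=1e-12)


def test_rds_i_two_group_hand_reduction(mixing_sample):
    # C_AB = C_BA = 0.5, Dhat_A = 20, Dhat_B = 10 ->
    # theta_A = 0.5*10 / (0.5*20 + 0.5*10) = 1/3
    view = rk.exclude_seeds(mixing_sample)
    tm = rk.transition_matrix(view, "grp", smoothing=False)
    res = rk.rds_i(view, "grp", rk.prepare_degrees(view), tm)
    assert res.proportions["A"] == pytest.approx(1 / 3, abs=1e-12)
    assert res.metadata["mean_degrees"] == {"A": pytest.approx(20), "B": pytest.approx(10)}


def test_rds_i_reducible_matrix_errors(ab_schema):
    rows = [
        ("sa", None, 10, {"grp": "A"}),
        ("sb", None, 10, {"grp": "B"}),
        ("a1", "sa", 10, {"grp": "A"}),
        ("b1", "sb", 10, {"grp": "B"}),
    ]
    view = rk.exclude_seeds(build_sample(rows, ab_schema))
    with pytest.warns(UserWarning):
        tm = rk.transition_matrix(view, "grp", smoothing=False)
    with pytest.raises(rk.EstimationError, match="reducible"):
        rk.rds_i(view, "grp", rk.prepare_degrees(view), tm)


def test_estimators_agree_under_neutral_recruitment():
    from rdskit.simulate import SimulationConfig, TraitSpec

    cfg = SimulationConfig(
        population_size=30_000, target_n=2_500, max_waves=200, rng_seed=11,
        trait_specs={"t": TraitSpec(("a", "b"), (0.3, 0.7), None, 0.0)},
    )
    truth = rk.generate_population(cfg)
    sample = rk.simulate_recruitment(truth, cfg)
    view = rk.exclude_seeds(sample)
    dv = rk.prepare_degrees(view)
    vals = [
        rk.sample_proportion(view, "t").proportions["a"],
        rk.rds_i(view, "t", dv).proportions["a"],
        rk.rds_ii(view, "t", dv).proportions["a"],
    ]
    se = np.sqrt(0.3 * 0.7 / len(view))
    assert max(vals) - min(vals) < 3 * se
    assert all(abs(v - truth.proportions["t"]["a"]) < 3 * se for v in vals)


# ---------------------------------------------------------------------------
# RDS-SS
# ---------------------------------------------------------------------------

def test_rds_ss_limits_to_rds_ii_at_tiny_sampling_fraction(study_sim):
    _, _, sample = study_sim
    view = rk.exclude_seeds(sample)
    dv = rk.prepare_degrees(view)
    r2 = rk.rds_ii(view, "hiv", dv)
    rss = rk.rds_ss(view, "hiv", dv, population_size=100_000_000)
    for c in r2.proportions:
        assert abs(rss.proportions[c] - r2.proportions[c]) < 1e-3


def test_rds_ss_finite_population_pulls_toward_sp(study_sim):
    # at a non-trivial sampling fraction high degrees are depleted, so the
    # inverse-inclusion weights are flatter than 1/d
    cfg, _, sample = study_sim
    view = rk.exclude_seeds(sample)
    dv = rk.prepare_degrees(view)
    sp = rk.sample_proportion(view, "hiv").proportions["positive"]
    r2 = rk.rds_ii(view, "hiv", dv).proportions["positive"]
    rss = rk.rds_ss(view, "hiv", dv, cfg.population_size).proportions["positive"]
    assert min(r2, sp) <= rss <= max(r2, sp)


def test_rds_ss_records_assumed_population_sizes(study_sim):
    _, _, sample = study_sim
    view = rk.exclude_seeds(sample)
    dv = rk.prepare_degrees(view)
    res = [rk.rds_ss(view, "hiv", dv, n) for n in rk.ss_population_bracket(3_467_836)]
    assert [r.population_size_assumed for r in res] == [34_678, 104_035]


def test_rds_ss_population_smaller_than_sample_rejected(study_sim):
    _, _, sample = study_sim
    view = rk.exclude_seeds(sample)
    dv = rk.prepare_degrees(view)
    with pytest.raises(ValueError, match="population_size"):
        rk.rds_ss(view, "hiv", dv, population_size=100)


def test_depletion_recursion_matches_monte_carlo():
    degrees = np.array([1.0] * 10 + [2.0] * 10 + [5.0] * 10)
    rng = np.random.default_rng(42)
    emp_unit = mc_inclusion_frequencies(degrees, n_draws=10, n_sims=4_000, rng=rng)
    grid, codes = np.unique(degrees, return_inverse=True)
    comp = np.bincount(codes).astype(float)
    pi = depletion_inclusion_probs(comp[None, :], grid, 10)[0]
    emp = np.array([emp_unit[codes == k].mean() for k in range(len(grid))])
    se = np.sqrt(pi * (1 - pi) / (4_000 * comp))
    assert np.all(np.abs(emp - pi) < 3 * se)
    # n_draws expected inclusions in total
    assert (pi * comp).sum() == pytest.approx(10, rel=1e-9)


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", rk.METHODS)
def test_proportions_sum_to_one_and_order_invariance(method, mixing_sample, ab_schema):
    view = rk.exclude_seeds(mixing_sample)
    dv = rk.prepare_degrees(view)
    res = rk.estimate(view, "grp", method, degrees=dv, population_size=10_000)
    assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    # permute record order and re-estimate
    perm = mixing_sample.df.sample(frac=1.0, random_state=4)
    shuffled = rk.RecruitmentSample(perm, ab_schema)
    view2 = rk.exclude_seeds(shuffled)
    res2 = rk.estimate(
        view2, "grp", method, degrees=rk.prepare_degrees(view2), population_size=10_000
    )
    for c in res.proportions:
        assert res2.proportions[c] == pytest.approx(res.proportions[c], abs=1e-12)


def test_population_bracket_for_unknown_msm_population():
    assert rk.ss_population_bracket(3_467_836) == (34_678, 104_035)
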
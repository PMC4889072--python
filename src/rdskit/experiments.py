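"""Reproduction studies: simulation experiments behind the headline claims.

Three study designs, each returning plain dictionaries of numbers:

* :func:`ss_recursion_check` — validates the deterministic expected-depletion
  inclusion-probability recursion against brute-force Monte-Carlo successive
  sampling on a small population;
* :func:`coverage_study` — parameter recovery: how often each RDS estimator's
  95% chain-bootstrap interval covers the true population proportion across
  independent simulated recruitment chains;
* :func:`cv_pattern_study` — the two qualitative variability patterns:
  across-methods CV falls with recruitment depth, and the unweighted sample
  proportion is the most depth-stable estimator.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._ss import depletion_inclusion_probs
from .bootstrap import BootstrapSpec, bootstrap_many
from .comparison import build_grid, cv_across_depths, cv_across_methods
from .data import exclude_seeds
from .estimators import METHODS, prepare_degrees
from .simulate import SimulationConfig, generate_population, simulate_recruitment

__all__ = ["ss_recursion_check", "coverage_study", "cv_pattern_study"]

RDS_METHODS = ("RDS-I", "RDS-II", "RDS-SS")


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n).astype(np.int64) % (2**31)


def mc_inclusion_frequencies(
    degrees: np.ndarray, n_draws: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Brute-force successive sampling: draw ``n_draws`` units one at a time,
    probability proportional to degree among the units not yet drawn, and
    count how often each unit is included."""
    degrees = np.asarray(degrees, dtype=float)
    n_units = len(degrees)
    hits = np.zeros(n_units)
    for _ in range(n_sims):
        w = degrees.copy()
        for _ in range(n_draws):
            cum = np.cumsum(w)
            j = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            j = min(j, n_units - 1)
            hits[j] += 1
            w[j] = 0.0
    return hits / n_sims


def ss_recursion_check(
    degrees=(1,) * 10 + (2,) * 10 + (5,) * 10,
    n_draws: int = 10,
    n_sims: int = 20_000,
    seed: int = 0,
) -> dict:
    """Compare recursion inclusion probabilities with Monte-Carlo frequencies.

    Returns per-degree-class recursion and empirical values plus the largest
    absolute z-score (difference over the Monte-Carlo binomial SE).
    """
    degrees = np.asarray(degrees, dtype=float)
    rng = np.random.default_rng(seed)
    emp_unit = mc_inclusion_frequencies(degrees, n_draws, n_sims, rng)
    grid, codes = np.unique(degrees, return_inverse=True)
    comp = np.bincount(codes).astype(float)
    pi = depletion_inclusion_probs(comp[None, :], grid, n_draws)[0]
    emp = np.array([emp_unit[codes == k].mean() for k in range(len(grid))])
    se = np.sqrt(pi * (1 - pi) / (n_sims * comp))
    z = np.abs(emp - pi) / se
    return {
        "degrees": grid.tolist(),
        "recursion": pi.tolist(),
        "monte_carlo": emp.tolist(),
        "se": se.tolist(),
        "max_z": float(z.max()),
        "n_sims": n_sims,
    }


def coverage_study(
    n_replicates: int = 50,
    bootstrap_iterations: int = 1_000,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    trait: str = "hiv",
    focal_category: str = "positive",
    methods=RDS_METHODS,
) -> dict:
    """95% chain-bootstrap CI coverage of the true proportion, per estimator.

    Each replicate simulates an independent recruitment chain from the same
    scenario (new population, new chains), bootstraps every estimator on one
    shared set of pseudo-chains, and records whether the interval covers the
    replicate's own true (finite-population) proportion.
    """
    base = config or SimulationConfig()
    seeds = _child_seeds(base_seed, n_replicates)
    covered = {m: 0 for m in methods}
    evaluated = {m: 0 for m in methods}
    realized_n = []
    from dataclasses import replace

    for i in range(n_replicates):
        cfg = replace(base, rng_seed=int(seeds[i]))
        truth = generate_population(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = simulate_recruitment(truth, cfg)
        realized_n.append(len(sample))
        view = exclude_seeds(sample)
        degrees = prepare_degrees(view)
        spec = BootstrapSpec(iterations=bootstrap_iterations, rng_seed=int(seeds[i]))
        true_p = truth.proportions[trait][focal_category]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = bootstrap_many(
                    view, trait, methods, spec, degrees=degrees,
                    population_size=cfg.population_size,
                )
        except Exception:
            continue  # degenerate replicate (e.g. total extinction); not evaluated
        for m, res in fits.items():
            lo, hi = res.ci[focal_category]
            evaluated[m] += 1
            covered[m] += int(lo <= true_p <= hi)
    out = {
        "n_replicates": n_replicates,
        "bootstrap_iterations": bootstrap_iterations,
        "median_sample_size": float(np.median(realized_n)),
        "coverage": {
            m: (covered[m] / evaluated[m] if evaluated[m] else float("nan"))
            for m in methods
        },
        "evaluated": dict(evaluated),
    }
    return out


def cv_pattern_study(
    n_replicates: int = 50,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    trait: str = "hiv",
    focal_category: str = "positive",
    depths=(5, 10, 15, 20, "full"),
    shallow: int = 5,
    deep: int = 20,
) -> dict:
    """Median CV patterns over independent simulated chains.

    Returns the median across-methods CV at the shallow and deep cuts and the
    median across-depths CV per method, plus the per-replicate comparison
    fractions.
    """
    base = config or SimulationConfig()
    seeds = _child_seeds(base_seed + 1, n_replicates)
    cv_shallow, cv_deep = [], []
    cv_depth = {m: [] for m in METHODS}
    from dataclasses import replace

    for i in range(n_replicates):
        cfg = replace(base, rng_seed=int(seeds[i]))
        truth = generate_population(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = simulate_recruitment(truth, cfg)
            grid = build_grid(
                sample, [trait], depths=depths,
                focal_categories={trait: focal_category},
                population_size=cfg.population_size,
            )
        cv_shallow.append(cv_across_methods(grid, trait, shallow))
        cv_deep.append(cv_across_methods(grid, trait, deep))
        for m in METHODS:
            cv_depth[m].append(cv_across_depths(grid, trait, m))
    cv_shallow = np.asarray(cv_shallow)
    cv_deep = np.asarray(cv_deep)
    rds_min = np.nanmin(
        np.vstack([cv_depth[m] for m in RDS_METHODS]), axis=0
    )
    return {
        "n_replicates": n_replicates,
        "median_cv_across_methods_shallow": float(np.nanmedian(cv_shallow)),
        "median_cv_across_methods_deep": float(np.nanmedian(cv_deep)),
        "fraction_cv_declines_with_depth": float(np.nanmean(cv_deep <= cv_shallow)),
        "median_cv_across_depths": {
            m: float(np.nanmedian(cv_depth[m])) for m in METHODS
        },
        "fraction_sp_most_stable": float(
            np.nanmean(np.asarray(cv_depth["SP"]) <= rds_min)
        ),
    }
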
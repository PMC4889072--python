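"""Numerics for the successive-sampling (PPS without replacement) model.

The estimator treats respondent-driven recruitment as drawing n units one at
a time, each draw probability-proportional-to-degree among the units not yet
drawn, from a finite population of known size N.  The inclusion probability
of a degree class is obtained with a deterministic *expected-depletion*
recursion: track the expected number of remaining units per degree class and
remove the expected fractional draw at every step.

Everything here is batched: compositions are (B, U) arrays over a common
grid of U degree values so that bootstrap replicates are processed in one
vectorized pass.
"""

from __future__ import annotations

import numpy as np

#: outer self-consistency loop
MAX_OUTER = 75
REL_TOL = 1e-5


def depletion_inclusion_probs(comp: np.ndarray, grid: np.ndarray, n_draws: int) -> np.ndarray:
    """Inclusion probability per degree class under PPS-WOR of ``n_draws`` units.

    Parameters
    ----------
    comp:
        (B, U) expected population counts per degree class (need not be
        integers; rows must sum to at least ``n_draws``).
    grid:
        (U,) degree value of each class (all >= 1).
    n_draws:
        number of successive draws.

    Returns
    -------
    (B, U) array of inclusion probabilities, 0 where a class is empty.
    """
    comp = np.atleast_2d(np.asarray(comp, dtype=float))
    grid = np.asarray(grid, dtype=float)
    remaining = comp.copy()
    drawn = np.zeros_like(remaining)
    for _ in range(int(n_draws)):
        weight = remaining @ grid  # (B,)
        # guard: nothing left to draw in a replicate
        weight = np.where(weight <= 0, np.inf, weight)
        p = remaining * (grid / weight[:, None])
        np.minimum(p, remaining, out=p)
        remaining -= p
        drawn += p
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(comp > 0, drawn / comp, 0.0)
    return np.clip(pi, 0.0, 1.0)


def self_consistent_weights(
    deg_codes: np.ndarray,
    grid: np.ndarray,
    population_size: float,
    max_outer: int = MAX_OUTER,
    rel_tol: float = REL_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Successive-sampling unit weights 1/pi(d_i) for each replicate.

    Parameters
    ----------
    deg_codes:
        (B, n) indices into *grid* giving each sampled unit's degree class.
    grid:
        (U,) unique observed degree values.
    population_size:
        assumed finite population size N (>= n).

    Returns
    -------
    weights:
        (B, n) final unit weights 1 / pi(d_i).
    pi:
        (B, U) converged inclusion probabilities per degree class.
    converged:
        (B,) boolean per replicate.
    last_rel:
        (B,) last relative weight change seen per replicate.

    The loop alternates: (i) scale current weights into an estimated
    population composition over the degree grid, (ii) run the expected
    depletion recursion to get pi(d), (iii) reset weights to 1/pi(d_i);
    until the largest relative weight change falls below ``rel_tol``.
    """
    deg_codes = np.atleast_2d(np.asarray(deg_codes))
    B, n = deg_codes.shape
    U = len(grid)
    grid = np.asarray(grid, dtype=float)
    if population_size < n:
        raise ValueError("population_size must be at least the sample size")

    d = grid[deg_codes]  # (B, n)
    w = 1.0 / d
    pi = np.full((B, U), np.nan)
    active = np.arange(B)
    converged = np.zeros(B, dtype=bool)
    last_rel = np.full(B, np.inf)
    for _ in range(max_outer):
        codes_a = deg_codes[active]
        w_a = w[active]
        # weight mass per degree class, scaled to N
        comp = bincount_rows(codes_a, U, weights=w_a)
        comp *= population_size / comp.sum(axis=1, keepdims=True)
        pi_a = depletion_inclusion_probs(comp, grid, n)
        pi_unit = np.take_along_axis(pi_a, codes_a, axis=1)
        w_new = 1.0 / np.maximum(pi_unit, 1e-300)
        rel = np.max(np.abs(w_new - w_a) / w_a, axis=1)
        w[active] = w_new
        pi[active] = pi_a
        last_rel[active] = rel
        done = rel < rel_tol
        converged[active[done]] = True
        active = active[~done]
        if len(active) == 0:
            break
    return w, pi, converged, last_rel


def bincount_rows(codes: np.ndarray, n_bins: int, weights: np.ndarray | None = None) -> np.ndarray:
    """Row-wise bincount: (B, n) int codes -> (B, n_bins) counts/sums."""
    codes = np.atleast_2d(codes)
    B, n = codes.shape
    flat = codes + n_bins * np.arange(B)[:, None]
    wflat = None if weights is None else np.atleast_2d(weights).ravel()
    out = np.bincount(flat.ravel(), weights=wflat, minlength=B * n_bins)
    return out.reshape(B, n_bins)
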
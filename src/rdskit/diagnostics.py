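"""Recruitment diagnostics: homophily, convergence depth, mean network size.

These quantities describe how far a chain-referral sample is from the
idealized Markov-process sampling that underlies RDS inference: homophily
measures the tendency to recruit within one's own subgroup relative to the
equilibrium expectation, convergence depth the number of waves needed for
the seed mixture to forget its (purposive) starting point, and per-subgroup
mean network size the raw material of the inverse-degree weights.
"""

from __future__ import annotations

import math

import numpy as np

from .data import AnalysisView, EstimationError, RecruitmentSample
from .estimators import DegreeVector, TransitionMatrix, _aligned, multiplicity_mean_degrees

__all__ = [
    "homophily",
    "convergence_depth",
    "mean_degree_by_group",
    "seeds_propagation",
    "propagation_count",
    "dominant_seed_share",
]


def homophily(tmatrix: TransitionMatrix, category: str) -> float:
    """Piecewise homophily index in [-1, 1] for one category.

    With S_AA the within-category recruitment proportion and e_A the
    equilibrium proportion::

        H = (S_AA - e_A) / (1 - e_A)   if S_AA >= e_A   (in-group preference)
        H = (S_AA - e_A) / e_A         otherwise        (in-group avoidance)

    H = 1 means all recruitment stays within the subgroup, H = 0 neutral
    recruitment, negative values active avoidance.  Undefined (NaN) when the
    category's equilibrium share is 0 or 1.
    """
    i = tmatrix.categories.index(category)
    s_aa = float(tmatrix.matrix[i, i])
    e_a = float(tmatrix.equilibrium[i])
    if e_a <= 0.0 or e_a >= 1.0:
        return math.nan
    if s_aa >= e_a:
        return (s_aa - e_a) / (1.0 - e_a)
    return (s_aa - e_a) / e_a


def convergence_depth(
    tmatrix: TransitionMatrix,
    seed_distribution,
    tolerance: float = 0.02,
    max_waves: int = 1_000,
) -> int:
    """Waves needed for the seed mixture to approach sampling equilibrium.

    Returns the smallest w >= 0 with ``max|seed_distribution . S^w - e| <=
    tolerance``.  The default tolerance of 0.02 is the conventional RDS
    equilibrium criterion.
    """
    if tmatrix.reducible:
        raise EstimationError(
            "transition matrix is reducible; convergence depth undefined"
        )
    k = len(tmatrix.categories)
    if isinstance(seed_distribution, dict):
        dist = np.array([seed_distribution.get(c, 0.0) for c in tmatrix.categories])
    else:
        dist = np.asarray(seed_distribution, dtype=float)
    if dist.shape != (k,) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("seed_distribution must be a probability vector over the categories")
    e = tmatrix.equilibrium
    cur = dist.copy()
    for w in range(max_waves + 1):
        if np.max(np.abs(cur - e)) <= tolerance:
            return w
        cur = cur @ tmatrix.matrix
    raise EstimationError(
        f"no convergence within {max_waves} waves (reducible or periodic chain?)"
    )


def seed_trait_distribution(sample: RecruitmentSample, trait: str) -> dict[str, float]:
    """Observed trait mixture of the wave-0 seeds (the default start vector
    for convergence diagnostics, since convergence is about seed bias)."""
    seeds = sample.df[sample.is_seed]
    vals = seeds[trait].dropna().astype(str)
    cats = sample.trait_schema[trait]
    if len(vals) == 0:
        return {c: 1.0 / len(cats) for c in cats}
    return {c: float((vals == c).mean()) for c in cats}


def mean_degree_by_group(
    view: AnalysisView, trait: str, degrees: DegreeVector
) -> dict[str, float]:
    """Arithmetic mean effective degree per category (NaN for empty ones)."""
    idx, cats, codes, degs = _aligned(view, trait, degrees)
    out = {}
    for k, c in enumerate(cats):
        sel = codes == k
        out[c] = float(degs[sel].mean()) if sel.any() else math.nan
    return out


def harmonic_mean_degree_by_group(
    view: AnalysisView, trait: str, degrees: DegreeVector
) -> dict[str, float]:
    """Multiplicity (harmonic) mean degree per category, as used by RDS-I."""
    idx, cats, codes, degs = _aligned(view, trait, degrees)
    vals = multiplicity_mean_degrees(codes, degs, len(cats))
    return {c: float(v) for c, v in zip(cats, vals)}


def propagation_count(waves_per_seed, threshold_waves: int) -> int:
    """How many seeds' chains reached at least ``threshold_waves`` waves."""
    return int(sum(1 for w in waves_per_seed if w >= threshold_waves))


def seeds_propagation(sample: RecruitmentSample, threshold_waves: int) -> int:
    """Number of seeds whose recruitment subtree reaches the given wave."""
    waves = sample.df.groupby("seed_id")["wave"].max()
    return propagation_count(waves.to_numpy(), threshold_waves)


def dominant_seed_share(eligible_per_seed) -> float:
    """Fraction of all eligible participants contributed by the largest chain."""
    arr = np.asarray(list(eligible_per_seed), dtype=float)
    if arr.sum() <= 0:
        return 0.0
    return float(arr.max() / arr.sum())
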
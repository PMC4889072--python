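"""Population-proportion estimators for respondent-driven samples.

Four estimates of a categorical trait's population distribution:

``SP``
    the unweighted sample proportion (with a Wilson binomial interval);
``RDS-II``
    the Volz-Heckathorn inverse-degree-weighted estimator,
    theta_A = sum_{i in A} 1/d_i / sum_i 1/d_i;
``RDS-I``
    the Salganik-Heckathorn estimator, combining the equilibrium of the
    cross-group recruitment transition matrix with per-group multiplicity
    (harmonic) mean degrees;
``RDS-SS``
    Gile's successive-sampling estimator, which models recruitment as
    probability-proportional-to-degree sampling *without replacement* from a
    finite population of assumed size N, and therefore needs N as input.

All estimators operate on the seed-excluded :class:`~rdskit.data.AnalysisView`
and on a prepared :class:`DegreeVector`; records missing the analyzed trait
are dropped for that trait only, so denominators vary by trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.proportion import proportion_confint

from ._ss import self_consistent_weights
from .data import AnalysisView, EstimationError

METHODS = ("SP", "RDS-I", "RDS-II", "RDS-SS")

EQUILIBRIUM_TOL = 1e-12
EQUILIBRIUM_MAX_ITER = 10_000


@dataclass
class EstimateResult:
    """A point estimate (and optional CI) of a trait's category proportions."""

    method: str
    trait: str
    proportions: dict[str, float]
    ci: dict[str, tuple[float, float]] | None = None
    depth: int | str = "full"
    n_used: int = 0
    population_size_assumed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


@dataclass
class DegreeVector:
    """Effective degrees (>= 1) for the analysis set, after imputation.

    ``values`` is indexed by the analysis view's row positions; rows dropped
    by the policy are simply absent.  ``imputed`` marks rows whose raw degree
    was missing or zero and got replaced.
    """

    values: pd.Series
    imputed: pd.Series
    n_imputed: int
    policy: str


def prepare_degrees(view: AnalysisView, policy: str = "impute_median") -> DegreeVector:
    """Turn raw self-reported network sizes into usable weights.

    Policies for missing/zero degrees:

    - ``"impute_median"`` (default): replace with the overall median of the
      positive reported degrees;
    - ``"drop"``: remove the record from all degree-weighted analyses.
    """
    raw = pd.to_numeric(view.df["degree"], errors="coerce")
    bad = raw.isna() | (raw <= 0)
    positive = raw[~bad]
    if len(positive) == 0:
        raise EstimationError(
            "no positive reported degrees; degree-weighted estimators cannot run "
            "(use the unweighted sample proportion only)"
        )
    if policy == "impute_median":
        fill = float(positive.median())
        values = raw.where(~bad, fill)
        imputed = bad.copy()
    elif policy == "drop":
        values = raw[~bad].astype(float)
        imputed = pd.Series(False, index=values.index)
    else:
        raise ValueError(f"unknown degree policy: {policy!r}")
    return DegreeVector(
        values=values.astype(float),
        imputed=imputed,
        n_imputed=int(bad.sum()) if policy == "impute_median" else 0,
        policy=policy,
    )


def _trait_index(view: AnalysisView, trait: str) -> pd.Index:
    vals = view.trait_values(trait)
    return vals[vals.notna()].index


def _categories(view: AnalysisView, trait: str) -> tuple[str, ...]:
    return tuple(view.trait_schema[trait])


def sample_proportion(view: AnalysisView, trait: str, alpha: float = 0.05) -> EstimateResult:
    """Unweighted per-category proportion with Wilson binomial intervals."""
    idx = _trait_index(view, trait)
    if len(idx) == 0:
        raise EstimationError(f"no non-missing values for trait {trait!r}")
    vals = view.df.loc[idx, trait].astype(str)
    n = len(vals)
    cats = _categories(view, trait)
    counts = {c: int((vals == c).sum()) for c in cats}
    props = {c: counts[c] / n for c in cats}
    ci = {}
    for c in cats:
        lo, hi = proportion_confint(counts[c], n, alpha=alpha, method="wilson")
        ci[c] = (float(lo), float(hi))
    return EstimateResult(
        method="SP", trait=trait, proportions=props, ci=ci, n_used=n,
        metadata={"counts": counts},
    )


def _aligned(view: AnalysisView, trait: str, degrees: DegreeVector):
    """Rows usable for a degree-weighted estimate: trait observed & degree kept."""
    idx = _trait_index(view, trait).intersection(degrees.values.index)
    if len(idx) == 0:
        raise EstimationError(f"empty analysis set for trait {trait!r}")
    cats = _categories(view, trait)
    codebook = {c: k for k, c in enumerate(cats)}
    codes = view.df.loc[idx, trait].astype(str).map(codebook).to_numpy(dtype=np.int64)
    degs = degrees.values.loc[idx].to_numpy(dtype=float)
    return idx, cats, codes, degs


def rds_ii(view: AnalysisView, trait: str, degrees: DegreeVector) -> EstimateResult:
    """Volz-Heckathorn inverse-degree-weighted proportions."""
    idx, cats, codes, degs = _aligned(view, trait, degrees)
    inv = 1.0 / degs
    tot = inv.sum()
    props = {c: float(inv[codes == k].sum() / tot) for k, c in enumerate(cats)}
    return EstimateResult(
        method="RDS-II", trait=trait, proportions=props, n_used=len(idx),
        metadata={"n_imputed": degrees.n_imputed, "degree_policy": degrees.policy},
    )


# ---------------------------------------------------------------------------
# transition matrix and RDS-I
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Cross-group recruitment proportions for one trait, plus equilibrium.

    ``matrix[x, y]`` is the (possibly smoothed) proportion of recruitments by
    category-x recruiters that produced a category-y recruit.  ``equilibrium``
    is the stationary distribution of that row-stochastic matrix; when the
    matrix is reducible the stationary distribution is not unique, a warning
    is recorded, and the observed recruit-category mixture is stored instead
    (``equilibrium_source == "fallback"``).
    """

    trait: str
    categories: tuple[str, ...]
    counts: np.ndarray
    matrix: np.ndarray
    equilibrium: np.ndarray
    smoothed: bool
    reducible: bool
    equilibrium_source: str
    warnings: list[str] = field(default_factory=list)

    def equilibrium_dict(self) -> dict[str, float]:
        return {c: float(e) for c, e in zip(self.categories, self.equilibrium)}


def stationary_distribution(
    matrix: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = EQUILIBRIUM_TOL,
    max_iter: int = EQUILIBRIUM_MAX_ITER,
) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix by power iteration."""
    k = matrix.shape[0]
    e = np.full(k, 1.0 / k) if start is None else np.asarray(start, dtype=float)
    for _ in range(max_iter):
        nxt = e @ matrix
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - e)) < tol:
            return nxt
        e = nxt
    raise EstimationError(
        f"power iteration did not reach tolerance {tol} in {max_iter} iterations"
    )


def _is_reducible(matrix: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(matrix > 0), connection="strong")
    return n_comp > 1


def transition_matrix(
    view: AnalysisView, trait: str, smoothing: bool = True
) -> TransitionMatrix:
    """Count recruiter-to-recruit category transitions and their equilibrium.

    Every recruit contributes one (recruiter category, own category) pair;
    wave-1 recruits contribute their seed's category on the recruiter side.
    Pairs with either side missing are dropped.  With ``smoothing`` on, the
    off-diagonal counts are symmetrized, t'_XY = t'_YX = (t_XY + t_YX)/2,
    reflecting the reciprocity of cross-group ties, before row-normalizing.
    """
    cats = _categories(view, trait)
    k = len(cats)
    codebook = {c: i for i, c in enumerate(cats)}
    own = view.trait_values(trait)
    rec = view.recruiter_traits[trait]
    ok = own.notna() & rec.notna()
    if not ok.any():
        raise EstimationError(
            f"no recruiter-recruit pair with both {trait!r} values observed"
        )
    x = rec[ok].astype(str).map(codebook).to_numpy(dtype=np.int64)
    y = own[ok].astype(str).map(codebook).to_numpy(dtype=np.int64)
    counts = np.zeros((k, k))
    np.add.at(counts, (x, y), 1.0)

    work = counts.copy()
    if smoothing:
        sym = (work + work.T) / 2.0
        off = ~np.eye(k, dtype=bool)
        work[off] = sym[off]

    notes: list[str] = []
    row_sums = work.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        for i in np.flatnonzero(zero_rows):
            notes.append(
                f"category {cats[i]!r} recruited nobody; its transition row set to uniform"
            )
            warnings.warn(notes[-1], stacklevel=2)
        work[zero_rows] = 1.0 / k
        row_sums = work.sum(axis=1)
    matrix = work / row_sums[:, None]

    reducible = _is_reducible(matrix)
    if reducible:
        obs = own[own.notna()].astype(str).map(codebook).to_numpy(dtype=np.int64)
        fallback = np.bincount(obs, minlength=k).astype(float)
        fallback /= fallback.sum()
        notes.append(
            "transition matrix is reducible; equilibrium is not unique - "
            "falling back to the observed recruit-category mixture"
        )
        warnings.warn(notes[-1], stacklevel=2)
        eq, source = fallback, "fallback"
    else:
        eq, source = stationary_distribution(matrix), "power_iteration"

    return TransitionMatrix(
        trait=trait, categories=cats, counts=counts, matrix=matrix,
        equilibrium=eq, smoothed=smoothing, reducible=reducible,
        equilibrium_source=source, warnings=notes,
    )


def multiplicity_mean_degrees(codes: np.ndarray, degs: np.ndarray, k: int) -> np.ndarray:
    """Per-category multiplicity (harmonic) mean degree n_X / sum_{i in X} 1/d_i."""
    out = np.full(k, np.nan)
    for c in range(k):
        sel = codes == c
        if sel.any():
            out[c] = sel.sum() / (1.0 / degs[sel]).sum()
    return out


def rds_i(
    view: AnalysisView,
    trait: str,
    degrees: DegreeVector,
    tmatrix: TransitionMatrix | None = None,
) -> EstimateResult:
    """Salganik-Heckathorn estimator for K categories.

    theta_X proportional to e_X / Dhat_X, where e is the equilibrium of the
    recruitment transition matrix and Dhat_X the multiplicity mean degree of
    category X.  For two groups this reduces to the familiar
    C_BA * Dhat_B / (C_AB * Dhat_A + C_BA * Dhat_B).
    """
    if tmatrix is None:
        tmatrix = transition_matrix(view, trait)
    if tmatrix.reducible:
        raise EstimationError(
            f"transition matrix for {trait!r} is reducible; RDS-I equilibrium undefined "
            f"({'; '.join(tmatrix.warnings)})"
        )
    idx, cats, codes, degs = _aligned(view, trait, degrees)
    if cats != tmatrix.categories:
        raise ValueError("transition matrix categories disagree with the schema")
    k = len(cats)
    dhat = multiplicity_mean_degrees(codes, degs, k)
    e = tmatrix.equilibrium
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(np.isnan(dhat), 0.0, e / dhat)
    if score.sum() <= 0:
        raise EstimationError(f"degenerate RDS-I weights for trait {trait!r}")
    theta = score / score.sum()
    return EstimateResult(
        method="RDS-I", trait=trait,
        proportions={c: float(t) for c, t in zip(cats, theta)},
        n_used=len(idx),
        metadata={
            "equilibrium": tmatrix.equilibrium_dict(),
            "mean_degrees": {c: float(d) for c, d in zip(cats, dhat)},
            "smoothed": tmatrix.smoothed,
        },
    )


def rds_ss(
    view: AnalysisView,
    trait: str,
    degrees: DegreeVector,
    population_size: int,
) -> EstimateResult:
    """Gile's successive-sampling estimator at an assumed population size."""
    idx, cats, codes, degs = _aligned(view, trait, degrees)
    n = len(idx)
    if population_size < n:
        raise ValueError(
            f"population_size ({population_size}) smaller than analysis set ({n})"
        )
    grid, deg_codes = np.unique(degs, return_inverse=True)
    w, _, converged, last_rel = self_consistent_weights(
        deg_codes[None, :], grid, float(population_size)
    )
    if not converged[0]:
        raise EstimationError(
            "successive-sampling weights did not converge within 75 iterations; "
            f"last relative change {last_rel[0]:.3g}"
        )
    w = w[0]
    tot = w.sum()
    props = {c: float(w[codes == kk].sum() / tot) for kk, c in enumerate(cats)}
    return EstimateResult(
        method="RDS-SS", trait=trait, proportions=props, n_used=n,
        population_size_assumed=int(population_size),
        metadata={"n_imputed": degrees.n_imputed, "degree_policy": degrees.policy},
    )


def estimate(
    view: AnalysisView,
    trait: str,
    method: str,
    degrees: DegreeVector | None = None,
    population_size: int | None = None,
    smoothing: bool = True,
) -> EstimateResult:
    """Dispatch to one estimator by method tag (``SP``/``RDS-I``/``RDS-II``/``RDS-SS``)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "SP":
        return sample_proportion(view, trait)
    if degrees is None:
        degrees = prepare_degrees(view)
    if method == "RDS-II":
        return rds_ii(view, trait, degrees)
    if method == "RDS-I":
        return rds_i(view, trait, degrees, transition_matrix(view, trait, smoothing))
    if population_size is None:
        raise ValueError("RDS-SS requires population_size")
    return rds_ss(view, trait, degrees, population_size)


def ss_population_bracket(
    adult_population: int, fractions: tuple[float, float] = (0.01, 0.03)
) -> tuple[int, ...]:
    """Bracketing population sizes for RDS-SS when the hidden population is unknown.

    The convention for unknown MSM population sizes is to assume they make up
    1-3% of the adult male general population; both endpoints are returned so
    the estimator can be run at each.
    """
    return tuple(int(round(adult_population * f)) for f in fractions)
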
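"""Chain-bootstrap confidence intervals for all estimators.

Each bootstrap replicate regenerates a pseudo-chain of the observed size by
recruiter-conditional resampling: start from a uniformly drawn observed
recruit; given the current individual's trait category X, draw the next
individual uniformly with replacement from the observed recruits whose
*recruiter* belonged to X (falling back to all recruits when category X
recruited nobody).  This mirrors the Markov recruitment process the
estimators assume, so the same scheme is applied to every estimator (sample
proportion included) for comparability.  Intervals are percentile intervals
of the replicate distribution; the point estimate is always the full-sample
estimate.

Replicates are generated once as an index matrix and all estimators are
evaluated on it in vectorized batch passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ss import bincount_rows, self_consistent_weights
from .data import AnalysisView, EstimationError, RecruitmentSample, exclude_seeds, restrict_to_depth
from .estimators import (
    DegreeVector,
    EstimateResult,
    _aligned,
    estimate,
    prepare_degrees,
)

__all__ = ["BootstrapSpec", "chain_bootstrap", "bootstrap_many", "ci_width_by_depth"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Number of replicates, RNG seed, and percentile levels of the interval."""

    iterations: int = 1_000
    rng_seed: int = 0
    levels: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        lo, hi = self.levels
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("percentile levels must satisfy 0 < lower < upper < 100")


class _ReplicateSet:
    """Aligned arrays for one (view, trait, degrees) and a (B, n) index matrix."""

    def __init__(self, view: AnalysisView, trait: str, degrees: DegreeVector, spec: BootstrapSpec):
        idx, cats, codes, degs = _aligned(view, trait, degrees)
        self.cats = cats
        self.codes = codes
        self.degs = degs
        self.n = len(idx)
        k = len(cats)
        codebook = {c: i for i, c in enumerate(cats)}
        rec = view.recruiter_traits[trait].loc[idx]
        rec_codes = rec.astype("object").map(codebook).fillna(-1).to_numpy(dtype=np.int64)

        # group g holds the positions drawable after a category-g individual;
        # empty groups fall back to the full recruit pool
        all_pos = np.arange(self.n)
        groups = []
        for g in range(k):
            members = np.flatnonzero(rec_codes == g)
            groups.append(members if len(members) else all_pos)
        flat = np.concatenate(groups)
        sizes = np.array([len(g) for g in groups])
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

        rng = np.random.default_rng(spec.rng_seed)
        B = spec.iterations
        out = np.empty((B, self.n), dtype=np.int64)
        out[:, 0] = rng.integers(self.n, size=B)
        for t in range(1, self.n):
            g = self.codes[out[:, t - 1]]
            j = (rng.random(B) * sizes[g]).astype(np.int64)
            out[:, t] = flat[offsets[g] + j]
        self.indices = out

    # -- batched estimator evaluations (each returns (B, K) proportions) --
    def sp(self) -> np.ndarray:
        cm = self.codes[self.indices]
        return bincount_rows(cm, len(self.cats)) / self.n

    def rds_ii(self) -> np.ndarray:
        cm = self.codes[self.indices]
        inv = (1.0 / self.degs)[self.indices]
        sums = bincount_rows(cm, len(self.cats), weights=inv)
        return sums / sums.sum(axis=1, keepdims=True)

    def rds_i(self, smoothing: bool = True) -> np.ndarray:
        k = len(self.cats)
        cm = self.codes[self.indices]
        a, b = cm[:, :-1], cm[:, 1:]
        counts = bincount_rows(a * k + b, k * k).reshape(-1, k, k)
        if smoothing:
            sym = (counts + counts.transpose(0, 2, 1)) / 2.0
            off = ~np.eye(k, dtype=bool)
            counts = np.where(off[None, :, :], sym, counts)
        rows = counts.sum(axis=2, keepdims=True)
        mat = np.where(rows > 0, counts / np.where(rows > 0, rows, 1.0), 1.0 / k)
        # damped power iteration: (I + S)/2 shares S's stationary distribution
        # and is aperiodic, so replicates with periodic chains still converge
        damped = 0.5 * (np.eye(k)[None, :, :] + mat)
        e = np.full((len(mat), k), 1.0 / k)
        for _ in range(2_000):
            nxt = np.einsum("bk,bkj->bj", e, damped)
            nxt /= nxt.sum(axis=1, keepdims=True)
            if np.max(np.abs(nxt - e)) < 1e-12:
                e = nxt
                break
            e = nxt
        inv = (1.0 / self.degs)[self.indices]
        n_c = bincount_rows(cm, k)
        invsum_c = bincount_rows(cm, k, weights=inv)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(n_c > 0, e * invsum_c / n_c, 0.0)
        tot = score.sum(axis=1, keepdims=True)
        return np.where(tot > 0, score / np.where(tot > 0, tot, 1.0), np.nan)

    def rds_ss(self, population_size: int) -> tuple[np.ndarray, np.ndarray]:
        grid, pos_codes = np.unique(self.degs, return_inverse=True)
        dc = pos_codes[self.indices]
        w, _, converged, _ = self_consistent_weights(dc, grid, float(population_size))
        cm = self.codes[self.indices]
        sums = bincount_rows(cm, len(self.cats), weights=w)
        props = sums / sums.sum(axis=1, keepdims=True)
        return props, converged


def _percentile_ci(props: np.ndarray, cats, levels) -> dict[str, tuple[float, float]]:
    ok = ~np.isnan(props).any(axis=1)
    lo, hi = np.percentile(props[ok], levels, axis=0)
    return {
        c: (float(np.clip(l, 0, 1)), float(np.clip(h, 0, 1)))
        for c, l, h in zip(cats, lo, hi)
    }


def _replicate_props(reps: _ReplicateSet, method: str, population_size, smoothing) -> np.ndarray:
    if method == "SP":
        return reps.sp()
    if method == "RDS-II":
        return reps.rds_ii()
    if method == "RDS-I":
        return reps.rds_i(smoothing=smoothing)
    if method == "RDS-SS":
        if population_size is None:
            raise ValueError("RDS-SS bootstrap requires population_size")
        props, converged = reps.rds_ss(population_size)
        props = props.copy()
        props[~converged] = np.nan
        return props
    raise ValueError(f"unknown method {method!r}")


def bootstrap_many(
    view: AnalysisView,
    trait: str,
    methods,
    spec: BootstrapSpec,
    degrees: DegreeVector | None = None,
    population_size: int | None = None,
    smoothing: bool = True,
    max_failure_rate: float = 0.10,
) -> dict[str, EstimateResult]:
    """Bootstrap several estimators on one shared set of pseudo-chains.

    Sharing the replicate chains across estimators removes resampling noise
    from between-estimator comparisons and costs one chain generation.
    """
    if degrees is None:
        degrees = prepare_degrees(view)
    reps = _ReplicateSet(view, trait, degrees, spec)
    out: dict[str, EstimateResult] = {}
    for method in methods:
        point = estimate(
            view, trait, method, degrees=degrees, population_size=population_size,
            smoothing=smoothing,
        )
        props = _replicate_props(reps, method, population_size, smoothing)
        failed = np.isnan(props).any(axis=1)
        if failed.mean() > max_failure_rate:
            raise EstimationError(
                f"{method} failed on {int(failed.sum())}/{len(failed)} bootstrap "
                f"replicates (> {max_failure_rate:.0%})"
            )
        point.ci = _percentile_ci(props, reps.cats, spec.levels)
        point.metadata["bootstrap_iterations"] = spec.iterations
        point.metadata["bootstrap_failures"] = int(failed.sum())
        out[method] = point
    return out


def chain_bootstrap(
    view: AnalysisView,
    trait: str,
    estimator: str,
    spec: BootstrapSpec,
    degrees: DegreeVector | None = None,
    population_size: int | None = None,
    smoothing: bool = True,
) -> EstimateResult:
    """Full-sample point estimate with a recruiter-conditional bootstrap CI."""
    return bootstrap_many(
        view, trait, [estimator], spec, degrees=degrees,
        population_size=population_size, smoothing=smoothing,
    )[estimator]


def ci_width_by_depth(
    sample: RecruitmentSample,
    trait: str,
    estimator: str,
    depths,
    spec: BootstrapSpec,
    focal_category: str | None = None,
    population_size: int | None = None,
    degree_policy: str = "impute_median",
) -> pd.DataFrame:
    """CI width of one estimator's focal-category estimate per depth cut."""
    if sorted(depths) != list(depths):
        raise ValueError("depths must be sorted ascending")
    rows = []
    for d in depths:
        sub = restrict_to_depth(sample, int(d))
        view = exclude_seeds(sub)
        degrees = prepare_degrees(view, degree_policy)
        res = chain_bootstrap(
            view, trait, estimator, spec, degrees=degrees,
            population_size=population_size,
        )
        cats = [focal_category] if focal_category else list(res.proportions)
        for c in cats:
            lo, hi = res.ci[c]
            rows.append(
                {
                    "depth": d,
                    "category": c,
                    "estimate": res.proportions[c],
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "width": hi - lo,
                    "n_used": res.n_used,
                }
            )
    return pd.DataFrame(rows)
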
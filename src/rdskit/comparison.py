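"""Estimator-comparison grid and coefficient-of-variation summaries.

The headline analysis: estimate every trait with every method (SP, RDS-I,
RDS-II, RDS-SS) at every recruitment-depth cut, then quantify variability
with the coefficient of variation (CV = sample standard deviation / mean of
the focal-category estimates) in its two forms:

* *across depths* — one CV per (trait, method), over the depth series
  (sample proportion included);
* *across methods* — one CV per (trait, depth), over the three RDS
  estimators (sample proportion excluded).

Small CVs across methods at deep cuts, and larger ones at shallow cuts,
indicate that the estimators disagree mostly while seed bias is still
washing out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSpec, bootstrap_many
from .data import RecruitmentSample, exclude_seeds, restrict_to_depth
from .estimators import METHODS, estimate, prepare_degrees
from .simulate import recruitment_summary

__all__ = [
    "DEFAULT_DEPTHS",
    "ComparisonGrid",
    "build_grid",
    "cv",
    "cv_across_depths",
    "cv_across_methods",
    "report",
]

DEFAULT_DEPTHS = (5, 10, 15, 20, "full")
RDS_METHODS = ("RDS-I", "RDS-II", "RDS-SS")


@dataclass
class ComparisonGrid:
    """Estimates for every (trait, method, depth) cell plus cell failures."""

    traits: tuple[str, ...]
    methods: tuple[str, ...]
    depths: tuple
    focal_categories: dict[str, str]
    results: dict = field(default_factory=dict)  # (trait, method, depth) -> EstimateResult
    failures: dict = field(default_factory=dict)  # (trait, method, depth) -> str
    population_size: int | None = None
    sample: RecruitmentSample | None = None

    def focal_estimate(self, trait: str, method: str, depth) -> float:
        res = self.results.get((trait, method, depth))
        if res is None:
            return float("nan")
        return res.proportions[self.focal_categories[trait]]


def build_grid(
    sample: RecruitmentSample,
    traits,
    methods=METHODS,
    depths=DEFAULT_DEPTHS,
    focal_categories: dict[str, str] | None = None,
    population_size: int | None = None,
    degree_policy: str = "impute_median",
    bootstrap: BootstrapSpec | None = None,
    smoothing: bool = True,
) -> ComparisonGrid:
    """Estimate each trait with each method at each depth restriction.

    Each cell runs restrict-to-depth, then seed exclusion, then the
    estimator.  Cell-level failures (e.g. a reducible transition matrix in a
    shallow cut) are recorded in ``grid.failures`` rather than aborting the
    grid.  The focal category defaults to the last declared category of each
    trait (by convention the "positive" one in binary traits).
    """
    traits = tuple(traits)
    methods = tuple(methods)
    depths = tuple(depths)
    if focal_categories is None:
        focal_categories = {t: sample.trait_schema[t][-1] for t in traits}
    grid = ComparisonGrid(
        traits=traits, methods=methods, depths=depths,
        focal_categories=dict(focal_categories),
        population_size=population_size, sample=sample,
    )
    for depth in depths:
        cut = sample if depth == "full" else restrict_to_depth(sample, int(depth))
        view = exclude_seeds(cut)
        try:
            degrees = prepare_degrees(view, degree_policy)
        except Exception as err:  # no usable degrees at this cut
            for trait in traits:
                for method in methods:
                    if method != "SP":
                        grid.failures[(trait, method, depth)] = str(err)
            degrees = None
        for trait in traits:
            if bootstrap is not None:
                try:
                    fits = bootstrap_many(
                        view, trait, methods, bootstrap, degrees=degrees,
                        population_size=population_size, smoothing=smoothing,
                    )
                    for method, res in fits.items():
                        res.depth = depth
                        grid.results[(trait, method, depth)] = res
                except Exception as err:
                    for method in methods:
                        grid.failures.setdefault((trait, method, depth), str(err))
                continue
            for method in methods:
                if method != "SP" and degrees is None:
                    continue
                try:
                    res = estimate(
                        view, trait, method, degrees=degrees,
                        population_size=population_size, smoothing=smoothing,
                    )
                    res.depth = depth
                    grid.results[(trait, method, depth)] = res
                except Exception as err:
                    grid.failures[(trait, method, depth)] = str(err)
    return grid


def cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if len(arr) < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def cv_across_depths(grid: ComparisonGrid, trait: str, method: str) -> float:
    """CV of one method's focal-category estimates over the depth series."""
    vals = [grid.focal_estimate(trait, method, d) for d in grid.depths]
    return cv(vals)


def cv_across_methods(grid: ComparisonGrid, trait: str, depth) -> float:
    """CV of the three RDS estimators' focal estimates at one depth
    (the unweighted sample proportion is excluded by construction)."""
    vals = [grid.focal_estimate(trait, m, depth) for m in RDS_METHODS if m in grid.methods]
    return cv(vals)


def cv_table(grid: ComparisonGrid) -> pd.DataFrame:
    """Both CV blocks as one tidy table."""
    rows = []
    for trait in grid.traits:
        for method in grid.methods:
            rows.append(
                {
                    "block": "across_depths",
                    "trait": trait,
                    "method": method,
                    "depth": "",
                    "cv": cv_across_depths(grid, trait, method),
                }
            )
        for depth in grid.depths:
            rows.append(
                {
                    "block": "across_methods",
                    "trait": trait,
                    "method": "",
                    "depth": str(depth),
                    "cv": cv_across_methods(grid, trait, depth),
                }
            )
    return pd.DataFrame(rows, columns=["block", "trait", "method", "depth", "cv"])


def estimates_table(grid: ComparisonGrid) -> pd.DataFrame:
    """Every cell's per-category estimate (and CI when bootstrapped)."""
    rows = []
    for trait in grid.traits:
        for method in grid.methods:
            for depth in grid.depths:
                key = (trait, method, depth)
                if key in grid.failures:
                    rows.append(
                        {
                            "trait": trait, "method": method, "depth": str(depth),
                            "category": "", "estimate": np.nan,
                            "ci_lower": np.nan, "ci_upper": np.nan,
                            "n_used": 0, "status": grid.failures[key],
                        }
                    )
                    continue
                res = grid.results.get(key)
                if res is None:
                    continue
                for c, p in res.proportions.items():
                    lo, hi = res.ci[c] if res.ci else (np.nan, np.nan)
                    rows.append(
                        {
                            "trait": trait, "method": method, "depth": str(depth),
                            "category": c, "estimate": p,
                            "ci_lower": lo, "ci_upper": hi,
                            "n_used": res.n_used, "status": "ok",
                        }
                    )
    cols = ["trait", "method", "depth", "category", "estimate",
            "ci_lower", "ci_upper", "n_used", "status"]
    return pd.DataFrame(rows, columns=cols)


def report(grid: ComparisonGrid, destination) -> dict[str, Path]:
    """Write the comparison outputs as CSV plus a human-readable summary.

    Files: ``cv_table.csv`` (both CV blocks), ``estimates_by_depth.csv``
    (per-cell estimates with CIs), ``process_indicators.csv`` (per-seed
    recruitment indicators), ``summary.txt``.  Regenerating from the same
    grid is byte-identical.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {}

    cvt = cv_table(grid)
    paths["cv_table"] = dest / "cv_table.csv"
    cvt.to_csv(paths["cv_table"], index=False, float_format="%.6g")

    est = estimates_table(grid)
    paths["estimates"] = dest / "estimates_by_depth.csv"
    est.to_csv(paths["estimates"], index=False, float_format="%.6g")

    paths["process"] = dest / "process_indicators.csv"
    if grid.sample is not None and len(grid.sample):
        recruitment_summary(grid.sample).to_csv(
            paths["process"], index=False, float_format="%.6g"
        )
    else:
        pd.DataFrame(
            columns=["seed_id", "waves", "n_recruited", "n_eligible",
                     "coupons_distributed", "coupon_return_rate"]
        ).to_csv(paths["process"], index=False)

    lines = ["Estimator comparison summary", "=" * 28, ""]
    for trait in grid.traits:
        lines.append(f"trait: {trait} (focal category: {grid.focal_categories[trait]})")
        for method in grid.methods:
            v = cv_across_depths(grid, trait, method)
            lines.append(f"  CV across depths, {method:7s}: {v:.4f}" if np.isfinite(v)
                         else f"  CV across depths, {method:7s}: undefined")
        for depth in grid.depths:
            v = cv_across_methods(grid, trait, depth)
            lines.append(f"  CV across RDS methods, depth {depth}: {v:.4f}"
                         if np.isfinite(v)
                         else f"  CV across RDS methods, depth {depth}: undefined")
        lines.append("")
    if grid.failures:
        lines.append("cell failures:")
        for key in sorted(grid.failures, key=str):
            lines.append(f"  {key}: {grid.failures[key]}")
        lines.append("")
    paths["summary"] = dest / "summary.txt"
    paths["summary"].write_text("\n".join(lines), encoding="utf-8")
    return paths
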
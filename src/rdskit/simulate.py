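"""Synthetic finite populations and coupon-based recruitment chains.

The generator emulates the structure of a large urban MSM survey recruited
by respondent-driven sampling: a finite population (tens of thousands) with
trait-dependent mean network sizes, ~14 well-networked seeds holding 4
coupons each, 3 coupons per later recruit, a coupon return probability
around 0.36, recruitment without replacement, and chains allowed to run to
31 waves.  Ground truth (true category proportions and degrees) is retained
so estimator bias and interval coverage can be measured exactly.

Recruitment mixing is a *category-preference* model rather than an explicit
sociogram: with probability equal to the trait's homophily strength a
returned coupon is restricted to unsampled peers of the recruiter's own
category, otherwise it goes to any unsampled unit; in both cases the peer is
chosen probability-proportional-to-degree, emulating the traversal of a
random network tie.  An optional explicit-network mode (configuration-model
graph, recruitment among unsampled neighbors) is available for sensitivity
work.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import RecruitmentSample

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "GroundTruth",
    "study_config",
    "generate_population",
    "simulate_recruitment",
    "recruitment_summary",
    "coupon_return_rate",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class TraitSpec:
    """One categorical trait of the synthetic population.

    ``mean_degrees`` (optional) gives the expected network size per category;
    traits that omit it do not influence degrees.  ``homophily`` in [0, 1)
    is the probability that a recruitment event is restricted to the
    recruiter's own category.
    """

    categories: tuple[str, ...]
    prevalences: tuple[float, ...]
    mean_degrees: tuple[float, ...] | None = None
    homophily: float = 0.0

    def validate(self, name: str) -> None:
        if len(self.categories) != len(self.prevalences):
            raise ValueError(f"trait {name!r}: categories/prevalences length mismatch")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError(f"trait {name!r}: prevalences must sum to 1")
        if any(p < 0 for p in self.prevalences):
            raise ValueError(f"trait {name!r}: negative prevalence")
        if not (0.0 <= self.homophily < 1.0):
            raise ValueError(f"trait {name!r}: homophily must lie in [0, 1)")
        if self.mean_degrees is not None:
            if len(self.mean_degrees) != len(self.categories):
                raise ValueError(f"trait {name!r}: mean_degrees length mismatch")
            if any(m < 1 for m in self.mean_degrees):
                raise ValueError(f"trait {name!r}: mean degree below 1 is infeasible")


@dataclass(frozen=True)
class SimulationConfig:
    """Population, degree, homophily and coupon parameters of one scenario."""

    population_size: int = 34_678
    trait_specs: dict[str, TraitSpec] = field(
        default_factory=lambda: {
            "hiv": TraitSpec(
                categories=("negative", "positive"),
                prevalences=(0.848, 0.152),
                mean_degrees=(38.0, 52.0),
                homophily=0.10,
            )
        }
    )
    mean_degree: float = 40.0  # fallback when no trait specifies degrees
    degree_dispersion: float = 2.0  # negative-binomial size parameter
    n_seeds: int = 14
    seed_coupons: int = 4
    recruit_coupons: int = 3
    coupon_return_prob: float = 0.36
    target_n: int = 1_376  # total enrolment, seeds included
    max_waves: int = 31
    rng_seed: int = 0
    degree_reporting_error: float = 0.0  # sd of multiplicative log-normal noise
    seed_selection: str = "degree"  # or "uniform"
    seed_trait_bias: dict[str, str] | None = None
    seed_batches: tuple[int, ...] | None = None  # staggered introduction
    explicit_network: bool = False

    def validate(self) -> None:
        if self.population_size < self.target_n:
            raise ValueError("population_size must be at least target_n")
        if self.seed_coupons < 1 or self.recruit_coupons < 1:
            raise ValueError("coupon counts must be >= 1")
        if not (0.0 <= self.coupon_return_prob <= 1.0):
            raise ValueError("coupon_return_prob must lie in [0, 1]")
        if self.mean_degree < 1:
            raise ValueError("mean_degree below 1 is infeasible")
        if self.degree_reporting_error < 0:
            raise ValueError("degree_reporting_error must be >= 0")
        if self.seed_selection not in ("degree", "uniform"):
            raise ValueError("seed_selection must be 'degree' or 'uniform'")
        if self.seed_batches is not None and sum(self.seed_batches) != self.n_seeds:
            raise ValueError("seed_batches must sum to n_seeds")
        for name, spec in self.trait_specs.items():
            spec.validate(name)


def study_config(**overrides) -> SimulationConfig:
    """The default Moscow-style scenario with all four analysis traits.

    HIV status carries the degree contrast (means 38 vs 52) and low
    homophily; country of birth and sexual identity carry moderate homophily;
    condom use is near-neutral.  Prevalences follow the study sample's
    demographic table.
    """
    cfg = SimulationConfig(
        trait_specs={
            "hiv": TraitSpec(
                ("negative", "positive"), (0.848, 0.152), (38.0, 52.0), 0.10
            ),
            "born_in_russia": TraitSpec(("no", "yes"), (0.154, 0.846), None, 0.35),
            "identity": TraitSpec(
                ("homosexual", "bisexual", "other"), (0.55, 0.429, 0.021), None, 0.30
            ),
            "condom_use": TraitSpec(
                ("consistent", "inconsistent"), (0.5, 0.5), None, 0.05
            ),
        }
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """The generated population table with its exact summaries."""

    population: pd.DataFrame  # unit_id, degree, one column per trait
    proportions: dict[str, dict[str, float]]
    mean_degree_by_category: dict[str, dict[str, float]]
    config: SimulationConfig


def _truncated_negbin(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Zero-truncated negative binomial draws with per-unit means ``mu``."""
    p = size_param / (size_param + mu)
    draws = rng.negative_binomial(size_param, p)
    # resample zeros so every unit has at least one tie
    for _ in range(1_000):
        zero = draws == 0
        if not zero.any():
            break
        draws[zero] = rng.negative_binomial(size_param, p[zero])
    draws[draws == 0] = 1
    return draws.astype(np.int64)


def generate_population(config: SimulationConfig) -> GroundTruth:
    """Draw N units with categories from the prevalences and degrees from a
    zero-truncated negative binomial whose mean depends on the unit's
    categories (geometric mean across the traits that specify degrees)."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 0])
    n = config.population_size
    cols: dict[str, np.ndarray] = {}
    log_mu = np.zeros(n)
    n_deg_traits = 0
    for name, spec in config.trait_specs.items():
        codes = rng.choice(len(spec.categories), size=n, p=np.asarray(spec.prevalences))
        cols[name] = codes
        if spec.mean_degrees is not None:
            log_mu += np.log(np.asarray(spec.mean_degrees))[codes]
            n_deg_traits += 1
    mu = np.exp(log_mu / n_deg_traits) if n_deg_traits else np.full(n, config.mean_degree)
    degree = _truncated_negbin(rng, mu, config.degree_dispersion)

    table = pd.DataFrame({"unit_id": [f"u{i}" for i in range(n)], "degree": degree})
    proportions: dict[str, dict[str, float]] = {}
    mean_deg: dict[str, dict[str, float]] = {}
    for name, spec in config.trait_specs.items():
        labels = np.asarray(spec.categories)[cols[name]]
        table[name] = labels
        proportions[name] = {
            c: float(np.mean(labels == c)) for c in spec.categories
        }
        mean_deg[name] = {
            c: float(degree[labels == c].mean()) if (labels == c).any() else float("nan")
            for c in spec.categories
        }
    return GroundTruth(table, proportions, mean_deg, config)


class _PPSSampler:
    """Degree-proportional draws from a fixed index list, with rejection of
    already-sampled units (cheap because the sampling fraction is small)."""

    def __init__(self, indices: np.ndarray, degrees: np.ndarray):
        self.indices = indices
        self.cum = np.cumsum(degrees[indices].astype(float))
        self.total = self.cum[-1] if len(indices) else 0.0

    def draw(self, rng: np.random.Generator) -> int:
        j = int(np.searchsorted(self.cum, rng.random() * self.total, side="right"))
        return int(self.indices[min(j, len(self.indices) - 1)])


def _draw_recruit(
    rng: np.random.Generator,
    sampled: np.ndarray,
    samplers: dict,
    constraints: list[tuple[str, int]],
    trait_codes: dict[str, np.ndarray],
    degrees: np.ndarray,
    max_tries: int = 200,
) -> int | None:
    """One PPS-without-replacement draw honouring same-category constraints."""
    if constraints:
        # draw from the tightest constrained pool, reject on the others
        key = min(constraints, key=lambda c: samplers[c].total)
        pool = samplers[key]
        others = [c for c in constraints if c != key]
    else:
        pool = samplers["__all__"]
        others = []
    if pool.total <= 0:
        return _fallback_draw(rng, sampled, trait_codes, degrees, constraints)
    for _ in range(max_tries):
        u = pool.draw(rng)
        if sampled[u]:
            continue
        if all(trait_codes[t][u] == c for t, c in others):
            return u
    return _fallback_draw(rng, sampled, trait_codes, degrees, constraints)


def _fallback_draw(rng, sampled, trait_codes, degrees, constraints):
    """Exact masked draw used when rejection sampling keeps missing (pool
    nearly exhausted); relaxes constraints before giving up entirely."""
    mask = ~sampled
    for t, c in constraints:
        mask = mask & (trait_codes[t] == c)
    if not mask.any():
        mask = ~sampled
        if not mask.any():
            return None
    idx = np.flatnonzero(mask)
    w = degrees[idx].astype(float)
    return int(rng.choice(idx, p=w / w.sum()))


def simulate_recruitment(truth: GroundTruth, config: SimulationConfig) -> RecruitmentSample:
    """Run the coupon process on a generated population.

    Coupons are processed in enrolment (wave) order; each processed coupon is
    returned independently with ``coupon_return_prob`` and, when returned,
    recruits an unsampled peer (category-preferential, degree-proportional).
    Enrolment stops at ``target_n`` total participants (seeds included) or
    when every chain is extinct and no seed batch remains.  A participant's
    ``coupons_issued`` counts the coupons that had the chance to be returned
    before the study window closed.
    """
    config.validate()
    if config.explicit_network:
        return _simulate_on_network(truth, config)
    rng = np.random.default_rng([config.rng_seed, 1])
    pop = truth.population
    n_pop = len(pop)
    degrees = pop["degree"].to_numpy()
    trait_codes = {
        name: pd.Categorical(pop[name], categories=spec.categories).codes.copy()
        for name, spec in config.trait_specs.items()
    }
    sampled = np.zeros(n_pop, dtype=bool)

    samplers: dict = {"__all__": _PPSSampler(np.arange(n_pop), degrees)}
    for name, spec in config.trait_specs.items():
        for ci in range(len(spec.categories)):
            idx = np.flatnonzero(trait_codes[name] == ci)
            samplers[(name, ci)] = _PPSSampler(idx, degrees)

    seed_units = _select_seeds(rng, config, degrees, trait_codes)
    batches = config.seed_batches or (config.n_seeds,)
    batch_iter = iter(np.split(seed_units, np.cumsum(batches)[:-1]))

    rows: list[dict] = []
    queue: deque[int] = deque()  # row numbers awaiting coupon processing
    coupons_issued: list[int] = []

    def enroll(unit: int, recruiter_row: int | None, wave: int) -> int:
        sampled[unit] = True
        reported = degrees[unit]
        if config.degree_reporting_error > 0:
            noise = np.exp(rng.normal(0.0, config.degree_reporting_error))
            reported = max(1, int(round(reported * noise)))
        row = {
            "participant_id": pop["unit_id"].iat[unit],
            "recruiter_id": None if recruiter_row is None else rows[recruiter_row]["participant_id"],
            "seed_id": None,
            "wave": wave,
            "coupons_issued": 0,
            "degree": int(reported),
            "_unit": unit,
        }
        for name in config.trait_specs:
            row[name] = pop[name].iat[unit]
        rows.append(row)
        coupons_issued.append(0)
        return len(rows) - 1

    def activate_next_batch() -> bool:
        batch = next(batch_iter, None)
        if batch is None or len(batch) == 0:
            return False
        for u in batch:
            if not sampled[u] and len(rows) < config.target_n:
                queue.append(enroll(int(u), None, 0))
        return True

    activate_next_batch()
    done = len(rows) >= config.target_n
    while not done:
        if not queue:
            if not activate_next_batch():
                break
            continue
        r = queue.popleft()
        wave = rows[r]["wave"]
        if wave >= config.max_waves:
            continue
        quota = config.seed_coupons if wave == 0 else config.recruit_coupons
        for _ in range(quota):
            if len(rows) >= config.target_n:
                done = True
                break
            coupons_issued[r] += 1
            if rng.random() >= config.coupon_return_prob:
                continue
            constraints = []
            for name, spec in config.trait_specs.items():
                if spec.homophily > 0 and rng.random() < spec.homophily:
                    code = trait_codes[name][rows[r]["_unit"]]
                    constraints.append((name, int(code)))
            unit = _draw_recruit(rng, sampled, samplers, constraints, trait_codes, degrees)
            if unit is None:
                continue
            queue.append(enroll(unit, r, wave + 1))

    if len(rows) < config.target_n:
        warnings.warn(
            f"recruitment extinct at n={len(rows)} before reaching target "
            f"{config.target_n}",
            stacklevel=2,
        )
    return _finish_sample(rows, coupons_issued, config)


def _select_seeds(rng, config, degrees, trait_codes) -> np.ndarray:
    n_pop = len(degrees)
    eligible = np.ones(n_pop, dtype=bool)
    if config.seed_trait_bias:
        for name, cat in config.seed_trait_bias.items():
            spec = config.trait_specs[name]
            eligible &= trait_codes[name] == spec.categories.index(cat)
    idx = np.flatnonzero(eligible)
    if len(idx) < config.n_seeds:
        raise ValueError("not enough eligible units to draw the requested seeds")
    if config.seed_selection == "degree":
        w = degrees[idx].astype(float)
        return rng.choice(idx, size=config.n_seeds, replace=False, p=w / w.sum())
    return rng.choice(idx, size=config.n_seeds, replace=False)


def _finish_sample(rows, coupons_issued, config) -> RecruitmentSample:
    for r, c in zip(rows, coupons_issued):
        r["coupons_issued"] = c
        r.pop("_unit", None)
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "recruiter_id", "seed_id", "wave",
                 "coupons_issued", "degree"] + list(config.trait_specs),
    )
    schema = {name: spec.categories for name, spec in config.trait_specs.items()}
    return RecruitmentSample(df, schema)


def _simulate_on_network(truth: GroundTruth, config: SimulationConfig) -> RecruitmentSample:
    """Sensitivity mode: build a configuration-model graph (optionally
    assortative on the highest-homophily trait) and recruit uniformly among a
    recruiter's unsampled neighbours."""
    rng = np.random.default_rng([config.rng_seed, 2])
    pop = truth.population
    n_pop = len(pop)
    degrees = pop["degree"].to_numpy()
    # pick the trait that shapes the graph
    h_trait = max(config.trait_specs, key=lambda t: config.trait_specs[t].homophily)
    h = config.trait_specs[h_trait].homophily
    codes = pd.Categorical(pop[h_trait], categories=config.trait_specs[h_trait].categories).codes

    stubs = np.repeat(np.arange(n_pop), degrees)
    within = rng.random(len(stubs)) < h
    neighbors: list[list[int]] = [[] for _ in range(n_pop)]

    def pair(stub_pool: np.ndarray) -> None:
        perm = rng.permutation(stub_pool)
        for a, b in zip(perm[0::2], perm[1::2]):
            if a != b:
                neighbors[a].append(int(b))
                neighbors[b].append(int(a))

    for ci in np.unique(codes):
        pair(stubs[within & (codes[stubs] == ci)])
    pair(stubs[~within])

    trait_codes = {
        name: pd.Categorical(pop[name], categories=spec.categories).codes.copy()
        for name, spec in config.trait_specs.items()
    }
    sampled = np.zeros(n_pop, dtype=bool)
    seed_units = _select_seeds(rng, config, degrees, trait_codes)

    rows: list[dict] = []
    coupons_issued: list[int] = []
    queue: deque[int] = deque()

    def enroll(unit: int, recruiter_row: int | None, wave: int) -> int:
        sampled[unit] = True
        row = {
            "participant_id": pop["unit_id"].iat[unit],
            "recruiter_id": None if recruiter_row is None else rows[recruiter_row]["participant_id"],
            "seed_id": None,
            "wave": wave,
            "coupons_issued": 0,
            "degree": int(degrees[unit]),
            "_unit": unit,
        }
        for name in config.trait_specs:
            row[name] = pop[name].iat[unit]
        rows.append(row)
        coupons_issued.append(0)
        return len(rows) - 1

    for u in seed_units[: config.target_n]:
        queue.append(enroll(int(u), None, 0))
    done = len(rows) >= config.target_n
    while queue and not done:
        r = queue.popleft()
        wave = rows[r]["wave"]
        if wave >= config.max_waves:
            continue
        quota = config.seed_coupons if wave == 0 else config.recruit_coupons
        for _ in range(quota):
            if len(rows) >= config.target_n:
                done = True
                break
            coupons_issued[r] += 1
            if rng.random() >= config.coupon_return_prob:
                continue
            nbrs = [v for v in neighbors[rows[r]["_unit"]] if not sampled[v]]
            if not nbrs:
                continue
            queue.append(enroll(nbrs[int(rng.integers(len(nbrs)))], r, wave + 1))
    if len(rows) < config.target_n:
        warnings.warn(
            f"recruitment extinct at n={len(rows)} before reaching target "
            f"{config.target_n}",
            stacklevel=2,
        )
    return _finish_sample(rows, coupons_issued, config)


# ---------------------------------------------------------------------------
# process indicators
# ---------------------------------------------------------------------------

def coupon_return_rate(n_recruits: int, coupons_distributed: int) -> float:
    """Returned (participating) coupons over coupons distributed."""
    if coupons_distributed <= 0:
        return 0.0
    return n_recruits / coupons_distributed


def recruitment_summary(sample: RecruitmentSample) -> pd.DataFrame:
    """Per-seed process indicators plus a totals row.

    Columns: seed id, deepest wave reached, persons recruited, eligible
    participants (all recruits here; no eligibility screening is modelled),
    coupons distributed within the chain, and the chain's coupon return
    rate.  The totals row reproduces the overall coupon return rate.
    """
    df = sample.df
    is_seed = sample.is_seed
    out = []
    for seed_id, grp in df.groupby("seed_id", sort=False):
        n_rec = int((grp["recruiter_id"].notna() & (grp["recruiter_id"] != "")).sum())
        coupons = int(grp["coupons_issued"].sum())
        out.append(
            {
                "seed_id": seed_id,
                "waves": int(grp["wave"].max()),
                "n_recruited": n_rec,
                "n_eligible": n_rec,
                "coupons_distributed": coupons,
                "coupon_return_rate": coupon_return_rate(n_rec, coupons),
            }
        )
    out.sort(key=lambda r: -r["n_recruited"])
    total_rec = sample.n_recruits
    total_coupons = sample.coupons_distributed
    out.append(
        {
            "seed_id": "total",
            "waves": sample.max_wave,
            "n_recruited": total_rec,
            "n_eligible": total_rec,
            "coupons_distributed": total_coupons,
            "coupon_return_rate": coupon_return_rate(total_rec, total_coupons),
        }
    )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def config_from_yaml(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    specs = {}
    for name, spec in (raw.pop("trait_specs", None) or {}).items():
        specs[name] = TraitSpec(
            categories=tuple(spec["categories"]),
            prevalences=tuple(spec["prevalences"]),
            mean_degrees=tuple(spec["mean_degrees"]) if spec.get("mean_degrees") else None,
            homophily=float(spec.get("homophily", 0.0)),
        )
    if "seed_batches" in raw and raw["seed_batches"] is not None:
        raw["seed_batches"] = tuple(raw["seed_batches"])
    cfg = SimulationConfig(**raw, trait_specs=specs) if specs else SimulationConfig(**raw)
    cfg.validate()
    return cfg


def config_to_yaml(config: SimulationConfig, path) -> None:
    raw = {
        "population_size": config.population_size,
        "mean_degree": config.mean_degree,
        "degree_dispersion": config.degree_dispersion,
        "n_seeds": config.n_seeds,
        "seed_coupons": config.seed_coupons,
        "recruit_coupons": config.recruit_coupons,
        "coupon_return_prob": config.coupon_return_prob,
        "target_n": config.target_n,
        "max_waves": config.max_waves,
        "rng_seed": config.rng_seed,
        "degree_reporting_error": config.degree_reporting_error,
        "seed_selection": config.seed_selection,
        "seed_trait_bias": config.seed_trait_bias,
        "seed_batches": list(config.seed_batches) if config.seed_batches else None,
        "explicit_network": config.explicit_network,
        "trait_specs": {
            name: {
                "categories": list(spec.categories),
                "prevalences": list(spec.prevalences),
                "mean_degrees": list(spec.mean_degrees) if spec.mean_degrees else None,
                "homophily": spec.homophily,
            }
            for name, spec in config.trait_specs.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
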
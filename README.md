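# rdskit

Estimation and estimator comparison for **respondent-driven sampling (RDS)**
surveys of hidden populations (MSM, people who inject drugs, sex workers, …)
where no sampling frame exists and recruitment proceeds through peer
coupons: a few purposively chosen, well-networked *seeds* (wave 0) each
receive a handful of coupons; recruited peers become recruiters in turn,
producing recruitment chains tens of waves deep.

Because recruitment flows along the social network, raw sample proportions
over-represent well-connected people. `rdskit` implements the unweighted
sample proportion alongside the three standard population-proportion
estimators, so their agreement (or disagreement) can be examined directly:

* **SP** — unweighted sample proportion, with a Wilson binomial interval;
* **RDS-I** (Salganik–Heckathorn) — combines the equilibrium **e** of the
  cross-group recruitment transition matrix *S* with per-group multiplicity
  (harmonic) mean degrees *D̂*:
  θ̂_X ∝ e_X / D̂_X, which for two groups reduces to
  θ̂_A = C_BA·D̂_B / (C_AB·D̂_A + C_BA·D̂_B);
* **RDS-II** (Volz–Heckathorn) — inverse-degree weighting,
  θ̂_A = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹, where d_i is the self-reported network
  size;
* **RDS-SS** (Gile's successive-sampling estimator) — models recruitment as
  probability-proportional-to-degree sampling **without replacement** from a
  finite population of assumed size N; inclusion probabilities π(d) are
  found by a self-consistent expected-depletion recursion and units are
  weighted 1/π(d_i). Requires N (for unknown MSM populations the 1–3%-of-
  adult-men convention is provided via `ss_population_bracket`).

Around the estimators the package provides:

* a validated recruitment-chain container with CSV readers/writers,
  depth restriction (`restrict_to_depth`) and seed exclusion;
* recruitment diagnostics: piecewise homophily in [−1, 1], convergence
  depth of the seed mixture toward sampling equilibrium, per-subgroup mean
  network sizes, seed-propagation counts;
* recruiter-conditional **chain-bootstrap** 95% confidence intervals,
  applied uniformly to all four estimators;
* the **comparison framework**: estimate every trait × method × depth cell
  and summarize variability with the coefficient of variation (CV), both
  *across depths* within a method and *across the RDS methods* at each
  depth;
* a **recruitment simulator** that emulates a large urban RDS study
  (finite population, trait-dependent degrees, homophilous
  degree-proportional recruitment without replacement, 14 seeds with 4
  coupons, 3 coupons per recruit, coupon return probability 0.36) with
  exact ground truth for bias and coverage studies.

## Worked example

```python
import rdskit as rk

cfg = rk.SimulationConfig(rng_seed=42)          # study-style scenario
truth = rk.generate_population(cfg)
sample = rk.simulate_recruitment(truth, cfg)

view = rk.exclude_seeds(sample)                 # seeds never enter estimates
degrees = rk.prepare_degrees(view)
spec = rk.BootstrapSpec(iterations=1000, rng_seed=0)
fits = rk.bootstrap_many(view, "hiv", rk.METHODS, spec,
                         degrees=degrees, population_size=cfg.population_size)
```

Output:

```
n = 1376 (14 seeds), max wave = 18, coupon return rate = 0.372
true HIV prevalence in population: 0.1502
SP      16.67%  (95% CI 14.61-19.02)
RDS-I   12.51%  (95% CI 10.29-15.52)
RDS-II  12.65%  (95% CI 10.28-15.54)
RDS-SS  12.73%  (95% CI 10.38-15.57)
homophily (positive): +0.085
convergence depth: 1 waves
```

Reading: the simulated HIV-positive group has the larger mean network size
(52 vs 38), so it is over-recruited and the raw sample proportion (16.7%)
overshoots the true prevalence (15.0%); the three degree-weighted
estimators agree closely with each other (12.5–12.7%) and their intervals
cover the truth. Homophily for HIV status is low and the seed mixture
reaches sampling equilibrium within a wave.

The same analyses are available from the shell:

```bash
rdskit simulate --seed 42 --out sample.csv
rdskit estimate --input sample.csv --trait hiv --method all \
    --population-size 34678 --bootstrap-iterations 1000
rdskit diagnose --input sample.csv --trait hiv --depth 5 --depth full
rdskit compare --input sample.csv --trait hiv --focal-category hiv=positive \
    --population-size 34678 --out-dir report/
```

`rdskit compare` writes `cv_table.csv`, `estimates_by_depth.csv`,
`process_indicators.csv` and a text summary.

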
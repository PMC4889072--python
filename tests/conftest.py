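import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rdskit as rk
from rdskit.simulate import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_sample(rows, schema):
    """rows: (pid, recruiter_id_or_None, degree_or_None, {trait: value})"""
    recs = []
    for pid, rid, degree, traits in rows:
        recs.append(
            rk.ParticipantRecord(
                participant_id=pid,
                recruiter_id=rid,
                seed_id="",  # recomputed from linkage
                wave=0,  # recomputed from linkage
                degree=degree,
                traits=traits,
            )
        )
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "recruiter_id": r.recruiter_id,
                "seed_id": None,
                "wave": None,
                "coupons_issued": 0,
                "degree": np.nan if r.degree is None else float(r.degree),
                **{t: r.traits.get(t) for t in schema},
            }
            for r in recs
        ]
    )
    return rk.RecruitmentSample(df, schema)


@pytest.fixture
def ab_schema():
    return {"grp": ("A", "B")}


@pytest.fixture
def mixing_sample(ab_schema):
    """One seed plus six recruits giving recruiter->recruit category counts
    A->A=2, A->B=2, B->A=1, B->B=1 (raw transition matrix [[.5,.5],[.5,.5]],
    equilibrium (0.5, 0.5)); category-A recruits all have degree 20 and
    category-B recruits degree 10."""
    rows = [
        ("s0", None, 30, {"grp": "A"}),
        ("a1", "s0", 20, {"grp": "A"}),
        ("b1", "s0", 10, {"grp": "B"}),
        ("a2", "a1", 20, {"grp": "A"}),
        ("b2", "a1", 10, {"grp": "B"}),
        ("a3", "b1", 20, {"grp": "A"}),
        ("b3", "b1", 10, {"grp": "B"}),
    ]
    return build_sample(rows, ab_schema)


@pytest.fixture
def equal_degree_mixing_sample(ab_schema):
    """Same mixing pattern but all degrees equal (symmetric in every way)."""
    rows = [
        ("s0", None, 10, {"grp": "A"}),
        ("a1", "s0", 10, {"grp": "A"}),
        ("b1", "s0", 10, {"grp": "B"}),
        ("a2", "a1", 10, {"grp": "A"}),
        ("b2", "a1", 10, {"grp": "B"}),
        ("a3", "b1", 10, {"grp": "A"}),
        ("b3", "b1", 10, {"grp": "B"}),
    ]
    return build_sample(rows, ab_schema)


@pytest.fixture(scope="session")
def study_sim():
    """One study-style simulated chain (single HIV-like trait) with its truth."""
    cfg = SimulationConfig(rng_seed=1)
    truth = rk.generate_population(cfg)
    sample = rk.simulate_recruitment(truth, cfg)
    return cfg, truth, sample
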
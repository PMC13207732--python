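import numpy as np
import pandas as pd
import pytest

from panstrat import SimulationParams, assemble_cohort, simulate_cohort


def make_cohort(
    expression: dict,
    mutated: dict | None = None,
    metrics: dict | None = None,
    clinical: dict | None = None,
    cohort_id: str = "TOY",
):
    """Assemble a toy cohort from plain dicts keyed by gene / sample."""
    expr = pd.DataFrame(expression).T  # genes x samples
    samples = list(expr.columns)
    mut = (
        pd.DataFrame(mutated).T
        if mutated
        else pd.DataFrame(np.zeros((0, len(samples)), dtype=int), columns=samples)
    )
    met = pd.DataFrame(metrics if metrics else {}, index=samples)
    clin = pd.DataFrame(clinical if clinical else {}, index=samples)
    return assemble_cohort(expr, mut, met, clin, cohort_id)


@pytest.fixture
def toy_cohort():
    samples = [f"s{i}" for i in range(8)]
    rng = np.random.default_rng(7)
    expression = {
        "FOCAL": dict(zip(samples, [1.0, 2, 3, 4, 5, 6, 7, 8])),
        "OTHER": dict(zip(samples, rng.uniform(1, 10, 8))),
    }
    mutated = {
        "TP53": dict(zip(samples, [1, 0, 0, 0, 0, 0, 1, 1])),
        "KRAS": dict(zip(samples, [0, 1, 1, 0, 0, 0, 0, 0])),
    }
    metrics = {
        "mutation_count": list(range(8)),
        "fga": list(np.linspace(0.0, 0.9, 8)),
    }
    clinical = {
        "t_stage": ["T1", "T1", "T2", "T2", "T3", "T3", "T4", "T4"],
        "grade": ["low", "low", "mid", "mid", "mid", "high", "high", "high"],
        "os_time": [10.0, 20, 30, 40, 50, 60, 70, 80],
        "os_event": [1, 1, 0, 1, 0, 1, 1, 0],
        "pfs_time": [5.0, 15, 25, 35, 45, 55, 65, 75],
        "pfs_event": [1, 0, 1, 1, 1, 0, 1, 1],
    }
    return make_cohort(expression, mutated, metrics, clinical)


@pytest.fixture(scope="session")
def small_sim_cohort():
    params = SimulationParams(
        n_cohorts=1,
        n_samples_per_cohort=120,
        n_genes=60,
        n_planted_coexpressed=8,
        n_g2m_genes=12,
        seed=11,
    )
    return simulate_cohort(params, 0)
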
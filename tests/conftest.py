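import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import preterm_amygdala as pa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def null_cohort():
    """Study-sized cohort with no planted brain-behavior association."""
    cfg = pa.SimulationConfig(seed=0, latent_strength=0.0)
    cohort, volumes, behavior = pa.generate_cohort(cfg)
    scores = pa.prepare_behavior_scores(behavior, cohort)
    return cfg, cohort, volumes, scores


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a strong rank-1 planted association (SNR 5)."""
    cfg = pa.SimulationConfig(seed=2, latent_strength=5.0)
    cohort, volumes, behavior = pa.generate_cohort(cfg)
    scores = pa.prepare_behavior_scores(behavior, cohort)
    return cfg, cohort, volumes, scores


@pytest.fixture(scope="session")
def null_pvalues_lc1():
    """LC1 permutation p-values over 200 replicate null cohorts.

    Study-scale conditions: n = 75 + 41 subjects, 20 volumetric
    measures, 4 behavior scores, 2 groups, 200 permutations, no
    planted association.  Shared by the calibration and uniformity
    checks.
    """
    pvals = []
    for rep in range(200):
        cfg = pa.SimulationConfig(seed=20_000 + rep, latent_strength=0.0)
        cohort, volumes, behavior = pa.generate_cohort(cfg)
        scores = pa.prepare_behavior_scores(behavior, cohort)
        p = pa.permutation_test(
            volumes[list(pa.MEASURES)].to_numpy(),
            scores[list(pa.BEHAVIOR_SCORE_COLUMNS)].to_numpy(),
            cohort["group"].to_numpy(),
            n_perm=200,
            seed=rep,
            group_order=["VPT", "FT"],
        )
        pvals.append(p[0])
    return np.asarray(pvals)


def assert_energy_conserved(result):
    """Sum of squared singular values equals ||R||_F^2 (relative 1e-8)."""
    total = np.sum(result.singular_values**2)
    assert total == pytest.approx(result.frobenius_sq, rel=1e-8)
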
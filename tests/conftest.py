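import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viromarker import simulate
from viromarker.io import AbundanceMatrix, SampleMetadata

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_metadata(site_counts, total_bp=10**9):
    """Deterministic metadata: site_counts maps body_site -> n."""
    records = []
    for site, n in site_counts.items():
        for j in range(n):
            records.append(SampleMetadata(f"{site}_{j + 1:03d}", site, total_bp))
    return records


def make_matrix(target_ids, metadata, values):
    return AbundanceMatrix(target_ids, [m.sample_id for m in metadata],
                           np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def cohort50():
    """Default class catalogue at 50 samples/site (fidelity-scale cohort)."""
    config = simulate.CohortConfig(
        n_samples={s: 50 for s in simulate.BODY_SITES}, seed=0)
    meta, matrix, truth = simulate.generate_cohort(config)
    return config, meta, matrix, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for grid-level tests: 12 samples/site, fewer vOTUs."""
    config = simulate.CohortConfig(
        n_samples={s: 12 for s in simulate.BODY_SITES},
        n_votus={"oral_marker": 3, "nasal_marker": 2, "nasal_oral_marker": 2,
                 "skin_assoc": 2, "stool_assoc": 2, "nonspecific": 3,
                 "rare_respiratory": 2, "background": 5},
        seed=11)
    meta, matrix, truth = simulate.generate_cohort(config)
    return config, meta, matrix, truth
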
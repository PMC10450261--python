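import numpy as np
import pytest

from csfflow import CohortSpec, generate_cohort, synchronize_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the study's group sizes and amplitude table."""
    spec = CohortSpec(seed=11)
    sessions, truth = generate_cohort(spec)
    return spec, sessions, truth


@pytest.fixture(scope="session")
def synced_study_cohort(study_cohort):
    spec, sessions, truth = study_cohort
    return spec, synchronize_cohort(sessions), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def noiseless_spec(**kwargs) -> CohortSpec:
    """A degenerate spec: zero noise, zero amplitude spread, zero jitter."""
    base = CohortSpec(seed=0)
    table = {k: (m, 0.0) for k, (m, _) in base.amplitude_table.items()}
    rostral = {k: (m, 0.0) for k, (m, _) in base.cord_rostral_table.items()}
    defaults = dict(
        noise_sd=0.0,
        latency_jitter_sd=0.0,
        amplitude_table=table,
        cord_rostral_table=rostral,
        raw_bins_choices=(25,),
        seed=0,
    )
    defaults.update(kwargs)
    return CohortSpec(**defaults)
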
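import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reosig import (
    ClinicalRecord,
    Cohort,
    ExpressionMatrix,
    SyntheticConfig,
    Treatment,
    generate_study,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_cohort(
    values,
    times,
    events,
    ages=None,
    treatments=None,
    gene_ids=None,
    name="toy",
):
    """Assemble a small cohort from raw arrays (ages default to EOCRC)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    ages = ages if ages is not None else [40.0] * n_samples
    treatments = treatments or [Treatment.SURGERY_ONLY] * n_samples
    clinical = [
        ClinicalRecord(
            sample_id=s,
            age_years=float(a),
            endpoint_time=float(t),
            endpoint_event=int(e),
            treatment=tr,
        )
        for s, a, t, e, tr in zip(sample_ids, ages, times, events, treatments)
    ]
    return Cohort(ExpressionMatrix(gene_ids, sample_ids, values), clinical, name)


def random_surv(rng, n, censor_frac=0.3, tie_free=True):
    """Random survival data; tie-free by construction when requested."""
    if tie_free:
        times = rng.permutation(np.linspace(1.0, 10.0, n)) + rng.uniform(0, 1e-3, n)
    else:
        times = rng.integers(1, 6, size=n).astype(float)
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return times, events


@pytest.fixture(scope="session")
def reference_study():
    """Small dual-training + validation study with planted signal."""
    config = SyntheticConfig(
        seed=7,
        n_samples_per_cohort=160,
        n_genes=80,
        n_age_de_genes=16,
        n_planted_pairs=3,
    )
    return config, generate_study(config)
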
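import pytest

import ewasmeta as em


@pytest.fixture(scope="session")
def reference_2000():
    return em.generate_cell_reference(2000, 7, seed=5)


@pytest.fixture(scope="session")
def small_null_consortium(reference_2000):
    """3 cohorts x 250 samples x 2000 probes, no injected effects."""
    cfg = em.SimulationConfig(
        n_cohorts=3, cohort_sizes=(250, 250, 250), n_probes=2000, seed=42)
    datasets, _ = em.generate_consortium(cfg, reference=reference_2000)
    return cfg, datasets


@pytest.fixture(scope="session")
def clean_annotation():
    ids = [f"cg{i:08d}" for i in range(2000)]
    return em.generate_annotation(ids, seed=0)
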